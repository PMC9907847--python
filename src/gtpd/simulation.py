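"""Monte-Carlo benchmarking of the ten estimation methods on GD samples.

The harness draws M replicate samples per (theta, k, n) cell, fits every
requested method to the *same* replicates, and aggregates three accuracy
metrics per parameter:

    BIAS = mean |est - true|        (mean absolute deviation)
    MSE  = mean (est - true)^2
    MRE  = mean |est - true| / true

Within a scenario-n block the methods are ranked per metric row (average
ranks on ties), rank sums are accumulated over the six rows, and an
overall table ranks the rank sums across all scenarios and sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .distribution import GTPD
from .estimators import METHODS, canonical_method, fit, moment_init

__all__ = [
    "DEFAULT_SIZES",
    "DEFAULT_SCENARIOS",
    "ScenarioSpec",
    "ScenarioReport",
    "OverallRankTable",
    "replicate_rng",
    "simulate_cell",
    "run_scenario",
    "rank_rows",
    "rank_metric_frame",
    "overall_rank_table",
    "export_tables",
]

DEFAULT_SIZES: tuple[int, ...] = (30, 75, 150, 250, 400, 600)
DEFAULT_SCENARIOS: tuple[tuple[float, float], ...] = (
    (0.25, 0.5), (0.5, 1.5), (2.5, 0.5), (1.5, 2.5), (2.0, 4.0),
)
METRICS = ("bias", "mse", "mre")
PARAMETERS = ("theta", "k")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: true parameters, sizes, replicate count."""

    theta: float
    k: float
    sizes: tuple[int, ...] = DEFAULT_SIZES
    replicates: int = 10000
    methods: tuple[str, ...] = METHODS
    base_seed: int = 0
    n_starts: int = 3

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 3 for n in self.sizes):
            raise ValueError("all sample sizes must be >= 3")
        object.__setattr__(self, "methods", tuple(canonical_method(m) for m in self.methods))
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))

    @property
    def label(self) -> str:
        return f"theta={self.theta:g},k={self.k:g}"


@dataclass
class ScenarioReport:
    """Metrics (and, after ranking, ranks and rank sums) for one scenario."""

    spec: ScenarioSpec
    metrics: pd.DataFrame          # columns: scenario, n, method, parameter, metric, value
    n_failed: pd.DataFrame         # columns: scenario, n, method, n_failed
    rank_sums: Optional[pd.DataFrame] = None  # columns: scenario, n, method, rank_sum


@dataclass
class OverallRankTable:
    """Ranks of rank sums per (scenario, n), with totals and final order."""

    body: pd.DataFrame             # index (scenario, n), columns methods
    totals: pd.Series              # per-method column totals
    overall_rank: pd.Series        # rank of totals, ties averaged


def replicate_rng(base_seed: int, theta: float, k: float, n: int, r: int) -> np.random.Generator:
    """Deterministic per-replicate generator from the run's base seed.

    The seed stream depends on (base_seed, scenario, n, replicate) only, so
    all methods see identical samples and any cell can be recomputed in
    isolation.
    """
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(theta * 1e6)), int(round(k * 1e6)), int(n), int(r)]
    )
    return np.random.default_rng(ss)


def simulate_cell(
    theta: float,
    k: float,
    n: int,
    replicates: int,
    methods: Sequence[str] = METHODS,
    base_seed: int = 0,
    n_starts: int = 3,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Fit ``methods`` to ``replicates`` common GD samples of size ``n``.

    Returns per-method (M, 2) arrays of (theta_hat, k_hat) -- NaN rows for
    unconverged fits -- plus failure counts.
    """
    methods = [canonical_method(m) for m in methods]
    law = GTPD(theta, k, "gd")
    estimates = {m: np.full((replicates, 2), np.nan) for m in methods}
    failures = {m: 0 for m in methods}
    for r in range(replicates):
        rng = replicate_rng(base_seed, theta, k, n, r)
        x = np.sort(law.rvs(n, seed=rng))
        init = moment_init(x)
        for m in methods:
            res = fit(x, m, init=init, n_starts=n_starts, seed=base_seed + r)
            if res.converged:
                estimates[m][r] = (res.theta, res.k)
            else:
                failures[m] += 1
    return estimates, failures


def _cell_metrics(est: np.ndarray, theta: float, k: float) -> dict[tuple[str, str], float]:
    """BIAS/MSE/MRE per parameter over the completed replicates."""
    out = {}
    for j, (pname, truth) in enumerate(zip(PARAMETERS, (theta, k))):
        col = est[:, j]
        col = col[np.isfinite(col)]
        d = col - truth
        out[("bias", pname)] = float(np.mean(np.abs(d)))
        out[("mse", pname)] = float(np.mean(d * d))
        out[("mre", pname)] = float(np.mean(np.abs(d)) / truth)
    return out


def run_scenario(spec: ScenarioSpec) -> ScenarioReport:
    """Run the full Monte-Carlo design for one (theta, k) scenario."""
    rows, fail_rows = [], []
    for n in spec.sizes:
        estimates, failures = simulate_cell(
            spec.theta, spec.k, n, spec.replicates, spec.methods, spec.base_seed, spec.n_starts
        )
        for m in spec.methods:
            cell = _cell_metrics(estimates[m], spec.theta, spec.k)
            for (metric, pname), value in cell.items():
                rows.append(
                    {"scenario": spec.label, "n": n, "method": m,
                     "parameter": pname, "metric": metric, "value": value}
                )
            fail_rows.append(
                {"scenario": spec.label, "n": n, "method": m, "n_failed": failures[m]}
            )
            if failures[m] > 0.05 * spec.replicates:
                import warnings

                warnings.warn(
                    f"method {m} failed on {failures[m]}/{spec.replicates} replicates "
                    f"at n={n} ({spec.label})",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return ScenarioReport(
        spec=spec, metrics=pd.DataFrame(rows), n_failed=pd.DataFrame(fail_rows)
    )


def rank_metric_frame(metrics: pd.DataFrame) -> pd.DataFrame:
    """Add average-tie ranks per (scenario, n, parameter, metric) row."""
    out = metrics.copy()
    out["rank"] = (
        out.groupby(["scenario", "n", "parameter", "metric"])["value"]
        .transform(lambda v: stats.rankdata(v, method="average"))
    )
    return out


def rank_rows(report: ScenarioReport) -> ScenarioReport:
    """Fill per-row ranks and per-method rank sums into the report."""
    ranked = rank_metric_frame(report.metrics)
    sums = (
        ranked.groupby(["scenario", "n", "method"], sort=False)["rank"]
        .sum()
        .reset_index()
        .rename(columns={"rank": "rank_sum"})
    )
    report.metrics = ranked
    report.rank_sums = sums
    return report


def overall_rank_table(rank_sums: pd.DataFrame, method_order: Sequence[str] = METHODS) -> OverallRankTable:
    """Aggregate rank sums over all scenarios and sizes into a final order.

    Within each (scenario, n) block the methods' rank sums are ranked
    (ties averaged); column totals over all blocks are ranked again for the
    overall ordering.
    """
    required = {"scenario", "n", "method", "rank_sum"}
    if not required.issubset(rank_sums.columns):
        raise ValueError(f"rank-sum table needs columns {sorted(required)}")
    wide = rank_sums.pivot_table(
        index=["scenario", "n"], columns="method", values="rank_sum", sort=False, dropna=False
    )
    if wide.isna().any().any():
        raise ValueError("missing (scenario, n, method) cells in the rank-sum table")
    order = [m for m in method_order if m in wide.columns]
    order += [m for m in wide.columns if m not in order]
    wide = wide[order]
    body = wide.apply(lambda row: pd.Series(stats.rankdata(row, method="average"), index=row.index), axis=1)
    totals = body.sum(axis=0)
    overall = pd.Series(stats.rankdata(totals, method="average"), index=totals.index)
    return OverallRankTable(body=body, totals=totals, overall_rank=overall)


def export_tables(report: ScenarioReport, outdir) -> dict[str, str]:
    """Write the long-format metric table, rank sums, and a run manifest."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    metrics_path = outdir / "metrics.csv"
    report.metrics.to_csv(metrics_path, index=False, float_format="%.17g")
    paths["metrics"] = str(metrics_path)
    if report.rank_sums is not None:
        rs_path = outdir / "rank_sums.csv"
        report.rank_sums.to_csv(rs_path, index=False, float_format="%.17g")
        paths["rank_sums"] = str(rs_path)
    failed_path = outdir / "failures.csv"
    report.n_failed.to_csv(failed_path, index=False)
    paths["failures"] = str(failed_path)
    manifest = {
        "theta": report.spec.theta,
        "k": report.spec.k,
        "sizes": list(report.spec.sizes),
        "replicates": report.spec.replicates,
        "methods": list(report.spec.methods),
        "base_seed": report.spec.base_seed,
        "n_starts": report.spec.n_starts,
        "version": _pkg_version,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = str(manifest_path)
    return paths
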