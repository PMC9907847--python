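"""Hand-entered reference rank sums from the original GD simulation study.

The introducing study of the Gemeay distribution benchmarked the ten
estimation methods over five (theta, k) scenarios and six sample sizes and
reported, per scenario-size block, the sum of the methods' per-row ranks
across the six metric rows (BIAS/MSE/MRE for each parameter).  Those
published rank sums are transcribed here so the rank-aggregation pipeline
can be driven with them directly (e.g. via ``gtpd rank``) and its output
checked against the published overall ordering.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["TABLE_METHOD_ORDER", "REPORTED_RANK_SUMS", "rank_sums_frame"]

TABLE_METHOD_ORDER = (
    "MLE", "ADE", "CVME", "MPSE", "LSE", "RTADE", "WLSE", "LTADE", "MSADE", "MSALDE",
)

# {(theta, k): {n: (rank sums in TABLE_METHOD_ORDER)}}
REPORTED_RANK_SUMS: dict[tuple[float, float], dict[int, tuple[float, ...]]] = {
    (0.25, 0.5): {
        30: (41, 25, 58, 16, 52, 39, 37, 42, 12, 8),
        75: (31, 42, 57, 6, 51, 31, 25, 54, 21, 12),
        150: (23, 40, 57, 6, 44, 46, 32, 49, 18, 15),
        250: (12, 31, 60, 6, 51, 20, 41, 48, 39, 22),
        400: (36, 34, 57, 6, 38, 21, 16, 56, 47, 19),
        600: (18, 26, 47, 6, 57, 34, 12, 57, 41, 32),
    },
    (0.5, 1.5): {
        30: (24, 31, 48, 31, 54, 25, 48, 44, 10, 15),
        75: (6, 30, 54, 32, 54, 15, 45, 43, 18, 33),
        150: (6, 29, 56, 21, 54, 13, 38, 45, 29, 39),
        250: (6, 22, 52, 20, 54, 12, 32, 56, 41, 35),
        400: (6, 26, 48, 18, 57, 12, 28, 57, 42, 36),
        600: (6, 24, 58, 13, 51, 17, 31, 53, 38, 39),
    },
    (2.5, 0.5): {
        30: (54, 16, 41, 39, 35, 58, 12, 27, 20, 28),
        75: (39, 12, 54, 12, 46, 37, 29, 20, 31, 50),
        150: (25, 10, 42, 26, 43, 45, 20, 14, 60, 45),
        250: (26, 26, 56, 9, 36, 46, 17, 23, 56, 35),
        400: (26, 11, 51, 7, 33, 19, 36, 43, 56, 48),
        600: (12, 20, 29, 6, 48, 29, 30, 53, 55, 48),
    },
    (1.5, 2.5): {
        30: (12, 40, 60, 6, 51, 29, 36, 51, 20, 25),
        75: (10, 26, 58, 8, 33, 18, 37, 56, 39, 45),
        150: (12, 18, 53, 6, 39, 27, 27, 59, 50, 39),
        250: (6, 30, 40, 12, 44, 18, 24, 60, 54, 42),
        400: (8, 26, 39, 10, 51, 18, 28, 60, 51, 39),
        600: (12, 24, 39, 6, 48, 18, 30, 60, 54, 39),
    },
    (2.0, 4.0): {
        30: (12, 27, 56, 6, 48, 39, 29, 58, 33, 22),
        75: (12, 21, 57, 6, 35, 36, 21, 57, 40, 45),
        150: (18, 12, 42, 6, 46, 24, 30, 56, 58, 38),
        250: (9, 18, 40, 9, 39, 35, 24, 59, 55, 42),
        400: (11, 27, 42, 7, 27, 36, 18, 57, 57, 48),
        600: (12, 27, 45, 6, 38, 21, 24, 54, 60, 43),
    },
}


def rank_sums_frame() -> pd.DataFrame:
    """The reference rank sums as a long table (scenario, n, method, rank_sum)."""
    rows = []
    for (theta, k), blocks in REPORTED_RANK_SUMS.items():
        label = f"theta={theta:g},k={k:g}"
        for n, sums in blocks.items():
            for method, value in zip(TABLE_METHOD_ORDER, sums):
                rows.append(
                    {"scenario": label, "n": n, "method": method, "rank_sum": float(value)}
                )
    return pd.DataFrame(rows)
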