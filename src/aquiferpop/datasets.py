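"""Bundled reference tables from the published North Pond crustal-aquifer
metagenome time series (borehole U1382A, ten samples over ~825 days).

These small printed tables let the selection and report-arithmetic stages be
exercised end to end without the multi-gigabyte sequencing data they were
derived from.
"""

from __future__ import annotations

import pandas as pd

from .tables_io import AbundanceMatrix

TIME_POINTS = [f"TP{i}" for i in range(10)]

# RPKM (reads per kbp MAG per Mbp sample) per MAG per time point.
_RPKM_ROWS = {
    "NORP83":  [0.02, 16.62, 0.23, 13.69, 11.27, 2.73, 9.95, 1.04, 0.38, 0.00],
    "NORP139": [2.13, 6.84, 6.90, 4.37, 9.78, 8.50, 6.97, 1.27, 1.21, 0.01],
    "NORP147": [0.00, 36.41, 0.08, 20.33, 12.36, 0.11, 0.30, 0.02, 0.02, 0.03],
    "NORP163": [20.86, 16.51, 48.66, 3.43, 2.92, 1.12, 0.24, 19.77, 20.95, 2.97],
    "NORP169": [2.12, 6.53, 5.09, 0.82, 0.52, 1.43, 8.38, 4.84, 4.14, 0.08],
    "NORP246": [0.02, 11.60, 0.10, 8.34, 5.24, 1.74, 0.12, 0.10, 0.13, 0.00],
    "NORP6":   [0.00, 0.00, 0.00, 0.00, 88.61, 0.00, 0.02, 0.00, 0.00, 0.00],
    "NORP57":  [0.04, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 38.25],
    "NORP100": [1.05, 0.10, 1.97, 0.08, 0.16, 0.11, 0.01, 2.46, 2.77, 38.98],
    "NORP167": [0.03, 30.13, 0.07, 0.13, 0.01, 0.00, 0.00, 0.01, 0.00, 0.00],
}


def north_pond_rpkm() -> AbundanceMatrix:
    """RPKM abundance matrix for the ten focal MAGs (already normalized)."""
    values = pd.DataFrame.from_dict(_RPKM_ROWS, orient="index", columns=TIME_POINTS)
    return AbundanceMatrix(values)


# Published per-MAG sweep-scan counts: total coding sequences, coding
# sequences flagged for significantly decreased nucleotide diversity, and —
# among the flagged set — counts per pairwise dN/dS category, the longest
# consecutive flagged run, and elevated-differentiation region counts at the
# one- and two-standard-deviation thresholds.
_SWEEP_ROWS = [
    # mag, n_cds, n_low_pi, n_low_dnds, n_relaxed, n_no_dnds, longest_run, fst_1sd, fst_2sd
    ("NORP83", 2657, 60, 4, 9, 43, 4, 8, 0),
    ("NORP139", 1538, 32, 6, 12, 10, 1, 0, 0),
    ("NORP147", 2650, 0, 0, 0, 0, 0, 0, 0),
    ("NORP163", 2182, 190, 37, 11, 117, 5, 14, 1),
    ("NORP169", 2842, 238, 19, 19, 175, 3, 3, 0),
    ("NORP246", 3851, 22, 5, 3, 12, 2, 0, 0),
]


def north_pond_sweep_counts() -> pd.DataFrame:
    """Raw per-MAG sweep-scan counts (inputs to the report arithmetic)."""
    return pd.DataFrame(
        _SWEEP_ROWS,
        columns=[
            "mag", "n_cds", "n_low_pi", "n_low_dnds", "n_relaxed",
            "n_no_dnds", "longest_run", "fst_regions_1sd", "fst_regions_2sd",
        ],
    ).set_index("mag")
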