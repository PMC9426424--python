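"""RPKM normalization and focal-population / time-point-of-interest selection.

A MAG is *persistent* when it reaches the working-abundance floor
(``min_rpkm_toi``, default 5 RPKM) in at least ``min_toi_count`` samples;
otherwise it is a *spike* MAG if any single sample reaches ``rpkm_spike``
(default 30 RPKM).  Both comparisons are inclusive.  Time points of interest
for a MAG are the chronologically ordered samples at or above the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tables_io import AbundanceMatrix, RunConfig, ValidationError


def compute_rpkm(mapped_reads: float, mag_length: int, sample_size: int) -> float:
    """Reads per kilobase pair of MAG per megabase pair of sample.

    ``sample_size`` is total base pairs sequenced in the sample.
    """
    if mag_length <= 0:
        raise ValidationError("mag_length must be positive")
    if sample_size <= 0:
        raise ValidationError("sample_size must be positive")
    if mapped_reads < 0:
        raise ValidationError("mapped_reads must be non-negative")
    return mapped_reads / ((mag_length / 1e3) * (sample_size / 1e6))


def rpkm_matrix(counts: AbundanceMatrix) -> AbundanceMatrix:
    """Normalize a raw mapped-read-count matrix to RPKM using the attached
    MAG lengths and per-sample sequencing depths."""
    if not counts.mag_lengths or not counts.sample_sizes:
        raise ValidationError("rpkm_matrix requires mag_lengths and sample_sizes")
    out = counts.values.copy()
    for mag in out.index:
        for sample in out.columns:
            out.loc[mag, sample] = compute_rpkm(
                counts.values.loc[mag, sample],
                counts.mag_lengths[mag],
                counts.sample_sizes[sample],
            )
    return AbundanceMatrix(out, counts.mag_lengths, counts.sample_sizes)


@dataclass
class FocalSelection:
    """Result of the focal-MAG screen."""

    persistent_mags: set[str] = field(default_factory=set)
    spike_mags: set[str] = field(default_factory=set)
    toi: dict[str, list[str]] = field(default_factory=dict)

    @property
    def focal_mags(self) -> set[str]:
        return self.persistent_mags | self.spike_mags


def time_points_of_interest(
    abundance: AbundanceMatrix, mag: str, cfg: RunConfig | None = None
) -> list[str]:
    """Chronological samples where ``mag`` meets the abundance floor."""
    cfg = cfg or RunConfig()
    row = abundance.row(mag)
    return [s for s in abundance.samples if row[s] >= cfg.min_rpkm_toi]


def select_focal_mags(abundance: AbundanceMatrix, cfg: RunConfig | None = None) -> FocalSelection:
    cfg = cfg or RunConfig()
    if abundance.values.empty:
        raise ValidationError("empty abundance matrix")
    selection = FocalSelection()
    for mag in abundance.mags:
        toi = time_points_of_interest(abundance, mag, cfg)
        if len(toi) >= cfg.min_toi_count:
            selection.persistent_mags.add(mag)
            selection.toi[mag] = toi
        elif (abundance.row(mag) >= cfg.rpkm_spike).any():
            selection.spike_mags.add(mag)
            selection.toi[mag] = toi
    return selection


def selection_table(selection: FocalSelection) -> pd.DataFrame:
    rows = []
    for mag in sorted(selection.focal_mags):
        rows.append(
            {
                "mag": mag,
                "criterion": "persistent" if mag in selection.persistent_mags else "spike",
                "time_points_of_interest": ",".join(selection.toi.get(mag, [])),
            }
        )
    return pd.DataFrame(rows, columns=["mag", "criterion", "time_points_of_interest"])
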