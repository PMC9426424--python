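"""SNV calling, major-allele-frequency matrices, SNV density, and nucleotide
diversity.

A site is called an SNV when its count entropy is strictly positive, its
coverage is at least ``min_coverage`` (20x) and the departure from consensus
(1 - major allele frequency) is at least ``min_departure`` (10%).  The
consensus is the count-maximal nucleotide of the aligned reads; the reference
base plays no role.  Per-site nucleotide diversity is the unbiased two-read
mismatch probability; gene and genome diversity average it over all covered
positions, invariant sites contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .tables_io import (
    NUCLEOTIDES,
    AlleleCountSite,
    GeneModel,
    RunConfig,
    SnvRecord,
    ValidationError,
    shannon_entropy,
)


def major_allele(site: AlleleCountSite) -> str:
    """Count-maximal nucleotide; ties broken in A<C<G<T order."""
    if site.coverage == 0:
        raise ValidationError(f"zero coverage at {site.contig}:{site.position}")
    return max(NUCLEOTIDES, key=lambda n: (site.counts.get(n, 0), -NUCLEOTIDES.index(n)))


def major_allele_frequency(site: AlleleCountSite) -> float:
    return site.count(major_allele(site)) / site.coverage


def call_snvs(sites: Iterable[AlleleCountSite], cfg: RunConfig | None = None) -> list[SnvRecord]:
    cfg = cfg or RunConfig()
    records = []
    for site in sites:
        cov = site.coverage
        if cov == 0 or cov < cfg.min_coverage:
            continue
        entropy = shannon_entropy(site.count_vector)
        if entropy <= 0.0:
            continue
        maf = major_allele_frequency(site)
        departure = 1.0 - maf
        if departure < cfg.min_departure:
            continue
        records.append(
            SnvRecord(
                site=site,
                major_allele=major_allele(site),
                major_allele_frequency=maf,
                departure_from_consensus=departure,
                entropy=entropy,
            )
        )
    return records


def snv_density(snv_count: int, mag_length: int) -> float:
    """SNVs per kilobase pair over the full MAG length."""
    if mag_length <= 0:
        raise ValidationError("mag_length must be positive")
    return snv_count / (mag_length / 1000.0)


def site_pi(site: AlleleCountSite) -> float:
    """Unbiased probability that two reads drawn without replacement differ."""
    n = site.coverage
    if n < 2:
        raise ValidationError(f"site_pi undefined below 2x coverage ({site.contig}:{site.position})")
    counts = site.count_vector
    return float(1.0 - (counts * (counts - 1)).sum() / (n * (n - 1)))


def per_site_pi(sites: Sequence[AlleleCountSite], cfg: RunConfig | None = None) -> np.ndarray:
    """site_pi over every site meeting the coverage floor, in input order."""
    cfg = cfg or RunConfig()
    return np.array([site_pi(s) for s in sites if s.coverage >= cfg.min_coverage])


def gene_pi(sites: Sequence[AlleleCountSite], cfg: RunConfig | None = None) -> float:
    """Mean site_pi over covered sites in a gene; NaN if none are covered."""
    values = per_site_pi(sites, cfg)
    return float(values.mean()) if values.size else float("nan")


def genome_pi(sites: Sequence[AlleleCountSite], cfg: RunConfig | None = None) -> float:
    return gene_pi(sites, cfg)


@dataclass
class DiversitySummary:
    mag: str
    sample: str
    snv_count: int
    snv_density: float
    mean_major_allele_frequency: float
    mean_major_allele_frequency_snv_only: float
    genome_pi: float


def summarize_diversity(
    mag: str,
    sample: str,
    sites: Sequence[AlleleCountSite],
    mag_length: int,
    cfg: RunConfig | None = None,
) -> DiversitySummary:
    """Per-sample diversity summary for one MAG.

    Two mean major-allele frequencies are reported: over SNV sites only, and
    over all covered sites (non-SNV covered sites counted as fixed at 1.0).
    """
    cfg = cfg or RunConfig()
    snvs = call_snvs(sites, cfg)
    covered = [s for s in sites if s.coverage >= cfg.min_coverage]
    snv_positions = {(r.site.contig, r.site.position) for r in snvs}
    freqs_all = [
        major_allele_frequency(s)
        if (s.contig, s.position) in snv_positions
        else 1.0
        for s in covered
    ]
    return DiversitySummary(
        mag=mag,
        sample=sample,
        snv_count=len(snvs),
        snv_density=snv_density(len(snvs), mag_length),
        mean_major_allele_frequency=float(np.mean(freqs_all)) if freqs_all else float("nan"),
        mean_major_allele_frequency_snv_only=(
            float(np.mean([r.major_allele_frequency for r in snvs])) if snvs else float("nan")
        ),
        genome_pi=genome_pi(sites, cfg),
    )


@dataclass
class AlleleMatrix:
    """Major-allele-frequency trajectories across time points of interest.

    ``values`` holds the frequency of each row's tracked allele (NaN where
    masked); ``mask`` is True where coverage fell below the floor; ``row_order``
    is a hierarchical-clustering (average linkage, Euclidean) display order.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    tracked_alleles: dict[tuple[str, int], str]
    row_order: list[tuple[str, int]]


def build_allele_matrix(
    sites_by_sample: Mapping[str, Sequence[AlleleCountSite]],
    toi: Sequence[str],
    cfg: RunConfig | None = None,
) -> AlleleMatrix:
    """Union-of-SNV-positions frequency matrix over the time points of interest.

    A position that is an SNV in any time point of interest gets a row.  The
    tracked allele is the consensus at the first time point where the site is
    an SNV.  In a sample where the site passed no SNV filter but is covered at
    >= min_coverage the cell is 1.0 (fixed at consensus); below the floor it
    is masked.
    """
    cfg = cfg or RunConfig()
    if not toi:
        raise ValidationError("at least one time point of interest required")

    snvs_by_sample = {tp: call_snvs(sites_by_sample.get(tp, []), cfg) for tp in toi}
    site_lookup: dict[str, dict[tuple[str, int], AlleleCountSite]] = {
        tp: {(s.contig, s.position): s for s in sites_by_sample.get(tp, [])} for tp in toi
    }

    tracked: dict[tuple[str, int], str] = {}
    for tp in toi:
        for rec in snvs_by_sample[tp]:
            key = (rec.site.contig, rec.site.position)
            tracked.setdefault(key, rec.major_allele)
    positions = sorted(tracked)

    values = pd.DataFrame(index=pd.MultiIndex.from_tuples(positions) if positions else None,
                          columns=list(toi), dtype=float)
    mask = pd.DataFrame(False, index=values.index, columns=list(toi))
    snv_keys = {tp: {(r.site.contig, r.site.position) for r in snvs_by_sample[tp]} for tp in toi}

    for key in positions:
        for tp in toi:
            site = site_lookup[tp].get(key)
            if site is None or site.coverage < cfg.min_coverage:
                mask.loc[key, tp] = True
                values.loc[key, tp] = np.nan
            elif key in snv_keys[tp]:
                values.loc[key, tp] = site.count(tracked[key]) / site.coverage
            else:
                values.loc[key, tp] = 1.0

    row_order = list(positions)
    if len(positions) > 2:
        filled = values.to_numpy(dtype=float)
        filled = np.where(np.isnan(filled), 1.0, filled)
        order = leaves_list(average(pdist(filled, metric="euclidean")))
        row_order = [positions[i] for i in order]

    return AlleleMatrix(values=values, mask=mask, tracked_alleles=tracked, row_order=row_order)


def sites_in_gene(sites: Iterable[AlleleCountSite], gene: GeneModel) -> list[AlleleCountSite]:
    return [s for s in sites if s.contig == gene.contig and gene.contains(s.position)]
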