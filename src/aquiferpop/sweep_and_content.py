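"""Gene-specific sweep scan, Hudson F_ST window scan, gene-frequency
copy-number variation, and the per-MAG summary report.

The sweep scan runs a one-sided Welch t-test per gene and time point of
interest (gene per-site diversity lower than the genome-wide per-site
diversity), corrects with Benjamini-Hochberg across genes within each time
point, and flags genes significant in every time point.  Differentiation
between time points uses the Hudson F_ST estimator aggregated as a ratio of
sums, screened in sliding five-gene windows against the genome mean +/- k
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import false_discovery_control, ttest_ind

from .site_diversity import call_snvs, major_allele, per_site_pi, sites_in_gene
from .tables_io import (
    AlleleCountSite,
    GeneModel,
    RunConfig,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Low-diversity (sweep) scan
# ---------------------------------------------------------------------------


@dataclass
class SweepCall:
    gene_id: str
    gene_pi: dict[str, float]
    p_values: dict[str, float]
    tested: bool
    flagged: bool
    run_id: int | None = None


def _welch_lower_p(gene_values: np.ndarray, genome_values: np.ndarray) -> float:
    """One-sided Welch p-value that the gene mean is lower than the genome mean."""
    if gene_values.std(ddof=1) == 0 and genome_values.std(ddof=1) == 0:
        return 1.0
    result = ttest_ind(gene_values, genome_values, equal_var=False, alternative="less")
    return float(result.pvalue)


def low_diversity_genes(
    site_pi_by_gene: Mapping[str, Mapping[str, np.ndarray]],
    genome_site_pi: Mapping[str, np.ndarray],
    toi: Sequence[str],
    gene_order: Sequence[str],
    cfg: RunConfig | None = None,
    correct: bool = True,
) -> list[SweepCall]:
    """Flag genes with significantly reduced per-site diversity in every time
    point of interest.

    ``site_pi_by_gene[gene][tp]`` holds per-site diversity values (zeros for
    invariant covered sites included); ``genome_site_pi[tp]`` the genome-wide
    distribution.  Genes with fewer than ``min_sites_per_gene`` covered sites
    in any time point are recorded untested.  With ``correct=True`` (default)
    p-values are Benjamini-Hochberg adjusted across genes within each time
    point before thresholding at ``alpha``.
    """
    cfg = cfg or RunConfig()
    if not toi:
        raise ValidationError("at least one time point of interest required")

    calls: dict[str, SweepCall] = {}
    raw_p: dict[str, dict[str, float]] = {tp: {} for tp in toi}
    for gene_id in gene_order:
        per_tp = site_pi_by_gene.get(gene_id, {})
        pis = {}
        testable = True
        for tp in toi:
            values = np.asarray(per_tp.get(tp, []), dtype=float)
            pis[tp] = float(values.mean()) if values.size else float("nan")
            if values.size < cfg.min_sites_per_gene:
                testable = False
        if not testable:
            calls[gene_id] = SweepCall(gene_id, pis, {}, tested=False, flagged=False)
            continue
        p_values = {
            tp: _welch_lower_p(
                np.asarray(per_tp[tp], dtype=float),
                np.asarray(genome_site_pi[tp], dtype=float),
            )
            for tp in toi
        }
        for tp in toi:
            raw_p[tp][gene_id] = p_values[tp]
        calls[gene_id] = SweepCall(gene_id, pis, p_values, tested=True, flagged=False)

    # Per-time-point BH adjustment across tested genes, then intersect.
    significant: dict[str, set[str]] = {}
    for tp in toi:
        gene_ids = list(raw_p[tp])
        if not gene_ids:
            significant[tp] = set()
            continue
        pvals = np.array([raw_p[tp][g] for g in gene_ids])
        adjusted = false_discovery_control(pvals, method="bh") if correct else pvals
        significant[tp] = {g for g, p in zip(gene_ids, adjusted) if p <= cfg.alpha}

    for gene_id, call in calls.items():
        call.flagged = call.tested and all(gene_id in significant[tp] for tp in toi)

    # Group consecutive flagged genes (in gene order) into runs.
    run_id = 0
    previous_flagged = False
    for gene_id in gene_order:
        call = calls[gene_id]
        if call.flagged:
            if not previous_flagged:
                run_id += 1
            call.run_id = run_id
            previous_flagged = True
        else:
            previous_flagged = False
    return [calls[g] for g in gene_order]


def longest_flagged_run(calls: Sequence[SweepCall]) -> int:
    best = current = 0
    for call in calls:
        current = current + 1 if call.flagged else 0
        best = max(best, current)
    return best


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------


def hudson_fst_site(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Per-site Hudson F_ST numerator and denominator.

    p1/p2 are frequencies of the same tracked allele in the two populations,
    n1/n2 the sample sizes (read depths).  Aggregate across sites as the ratio
    of summed numerators to summed denominators.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("hudson_fst_site requires n >= 2 in both populations")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValidationError("allele frequencies must be in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_ratio_of_sums(site_terms: Sequence[tuple[float, float]]) -> float:
    """Hudson F_ST over multiple sites; sites with zero denominator are
    skipped; NaN if nothing remains."""
    nums = [n for n, d in site_terms if d != 0.0]
    dens = [d for _, d in site_terms if d != 0.0]
    if not dens:
        return float("nan")
    return float(sum(nums) / sum(dens))


def gene_fst(
    sites_tp1: Sequence[AlleleCountSite],
    sites_tp2: Sequence[AlleleCountSite],
    cfg: RunConfig | None = None,
) -> float:
    """Hudson F_ST for one gene between two time points.

    Uses sites that are biallelic SNVs in at least one of the two time points
    and covered in both; the tracked allele is the major allele of the first
    time point; n is the read depth at the site.
    """
    cfg = cfg or RunConfig()
    lookup1 = {(s.contig, s.position): s for s in sites_tp1}
    lookup2 = {(s.contig, s.position): s for s in sites_tp2}
    snv_keys = {
        (r.site.contig, r.site.position)
        for r in call_snvs(list(sites_tp1) + list(sites_tp2), cfg)
        if r.site.n_alleles == 2
    }
    terms = []
    for key in sorted(snv_keys):
        s1, s2 = lookup1.get(key), lookup2.get(key)
        if s1 is None or s2 is None:
            continue
        if s1.coverage < cfg.min_coverage or s2.coverage < cfg.min_coverage:
            continue
        tracked = major_allele(s1)
        p1 = s1.count(tracked) / s1.coverage
        p2 = s2.count(tracked) / s2.coverage
        terms.append(hudson_fst_site(p1, s1.coverage, p2, s2.coverage))
    return fst_ratio_of_sums(terms)


@dataclass
class FstWindow:
    contig: str
    gene_ids: tuple[str, ...]
    mean_fst: float
    elevation: str  # none | >1sd | >2sd


@dataclass
class FstScanResult:
    windows: list[FstWindow]
    region_counts: dict[int, int]
    genome_mean: float
    genome_sd: float


def window_fst_scan(
    per_gene_fst: Mapping[str, float],
    genes: Sequence[GeneModel],
    cfg: RunConfig | None = None,
) -> FstScanResult:
    """Slide a window of ``fst_window`` consecutive eligible genes per contig
    and call windows whose mean F_ST exceeds the genome mean by k standard
    deviations (k in ``fst_sd_levels``); overlapping elevated windows merge
    into regions, counted per k.

    ``per_gene_fst`` should already be restricted to eligible genes (complete
    start/stop codon, coverage within bounds, shared biallelic sites); genes
    without a value are skipped.
    """
    cfg = cfg or RunConfig()
    values = np.array([v for v in per_gene_fst.values() if np.isfinite(v)])
    if values.size == 0:
        return FstScanResult([], {k: 0 for k in cfg.fst_sd_levels}, float("nan"), float("nan"))
    genome_mean = float(values.mean())
    genome_sd = float(values.std(ddof=1)) if values.size > 1 else 0.0

    by_contig: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        if g.gene_id in per_gene_fst and np.isfinite(per_gene_fst[g.gene_id]):
            by_contig.setdefault(g.contig, []).append(g)

    windows: list[FstWindow] = []
    elevated_spans: dict[int, list[tuple[str, int, int]]] = {k: [] for k in cfg.fst_sd_levels}
    w = cfg.fst_window
    for contig, contig_genes in by_contig.items():
        if len(contig_genes) < w:
            continue
        for i in range(len(contig_genes) - w + 1):
            chunk = contig_genes[i : i + w]
            mean_fst = float(np.mean([per_gene_fst[g.gene_id] for g in chunk]))
            elevation = "none"
            for k in sorted(cfg.fst_sd_levels):
                if mean_fst > genome_mean + k * genome_sd:
                    elevation = f">{k}sd"
                    elevated_spans[k].append((contig, i, i + w))
            windows.append(
                FstWindow(contig, tuple(g.gene_id for g in chunk), mean_fst, elevation)
            )

    region_counts = {}
    for k, spans in elevated_spans.items():
        merged = 0
        spans.sort()
        current_end: dict[str, int] = {}
        for contig, start, end in spans:
            if contig in current_end and start < current_end[contig]:
                current_end[contig] = max(current_end[contig], end)
            else:
                merged += 1
                current_end[contig] = end
        region_counts[k] = merged
    return FstScanResult(windows, region_counts, genome_mean, genome_sd)


def eligible_fst_genes(
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    gene_coverage: Mapping[str, float],
    cfg: RunConfig | None = None,
) -> list[GeneModel]:
    """Genes eligible for the F_ST scan: complete start and stop codon and
    coverage within two standard deviations of the genome mean."""
    cfg = cfg or RunConfig()
    start_codons = {"ATG", "GTG", "TTG"}
    stop_codons = {"TAA", "TAG", "TGA"}
    cov = np.array([gene_coverage[g.gene_id] for g in genes if g.gene_id in gene_coverage])
    if cov.size == 0:
        return []
    mean, sd = float(cov.mean()), float(cov.std(ddof=1)) if cov.size > 1 else 0.0
    eligible = []
    for g in genes:
        if g.gene_id not in gene_coverage or g.length % 3 != 0:
            continue
        seq = sequences[g.contig][g.start : g.end]
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        if seq[:3] not in start_codons or seq[-3:] not in stop_codons:
            continue
        if abs(gene_coverage[g.gene_id] - mean) > 2 * sd:
            continue
        eligible.append(g)
    return eligible


# ---------------------------------------------------------------------------
# Gene frequency (copy-number variation)
# ---------------------------------------------------------------------------


@dataclass
class GeneFrequencyTable:
    frequencies: pd.DataFrame  # gene x sample
    variable_genes: set[str]
    row_order: list[str]


def gene_frequency(
    coverage: pd.DataFrame,
    toi: Sequence[str],
    genes: Sequence[GeneModel] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    cfg: RunConfig | None = None,
) -> GeneFrequencyTable:
    """Per-sample gene coverage divided by the sample's median gene coverage.

    Genes on contigs shorter than ``min_contig_len`` are excluded when gene
    models and contig lengths are supplied.  Variable genes are those whose
    frequency range (max - min) across the time points of interest is at
    least ``genefreq_delta``.
    """
    cfg = cfg or RunConfig()
    table = coverage.copy().astype(float)
    if genes is not None and contig_lengths is not None:
        keep = [
            g.gene_id
            for g in genes
            if contig_lengths.get(g.contig, 0) >= cfg.min_contig_len
        ]
        table = table.loc[[g for g in table.index if g in set(keep)]]
    medians = table.median(axis=0)
    if (medians <= 0).any():
        bad = [s for s in table.columns if medians[s] <= 0]
        raise ValidationError(f"zero median gene coverage in sample(s): {', '.join(bad)}")
    freq = table / medians

    missing_toi = [tp for tp in toi if tp not in freq.columns]
    if missing_toi:
        raise ValidationError(f"unknown time point(s): {', '.join(missing_toi)}")
    ranges = freq[list(toi)].max(axis=1) - freq[list(toi)].min(axis=1)
    variable = set(freq.index[ranges >= cfg.genefreq_delta])

    row_order = list(freq.index)
    if len(freq) > 2:
        order = leaves_list(average(pdist(freq.to_numpy(), metric="euclidean")))
        row_order = [freq.index[i] for i in order]
    return GeneFrequencyTable(frequencies=freq, variable_genes=variable, row_order=row_order)


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------


def percent_half_up(numerator: int, denominator: int) -> int:
    """Integer percent with half-up rounding; 0 when the denominator is 0."""
    if denominator == 0:
        return 0
    fraction = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    return int(fraction.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class SweepReportRow:
    mag: str
    n_cds: int
    n_low_pi: int
    pct_low_pi: int
    n_low_dnds: int
    pct_low_dnds: int
    n_relaxed: int
    pct_relaxed: int
    n_no_dnds: int
    pct_no_dnds: int
    longest_run: int
    fst_regions: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        mag: str,
        n_cds: int,
        n_low_pi: int,
        n_low_dnds: int,
        n_relaxed: int,
        n_no_dnds: int,
        longest_run: int,
        fst_regions: Mapping[int, int],
    ) -> "SweepReportRow":
        return cls(
            mag=mag,
            n_cds=n_cds,
            n_low_pi=n_low_pi,
            pct_low_pi=percent_half_up(n_low_pi, n_cds),
            n_low_dnds=n_low_dnds,
            pct_low_dnds=percent_half_up(n_low_dnds, n_low_pi),
            n_relaxed=n_relaxed,
            pct_relaxed=percent_half_up(n_relaxed, n_low_pi),
            n_no_dnds=n_no_dnds,
            pct_no_dnds=percent_half_up(n_no_dnds, n_low_pi),
            longest_run=longest_run,
            fst_regions=dict(fst_regions),
        )


def summarize_sweep_report(
    mag: str,
    sweep_calls: Sequence[SweepCall],
    dnds_categories: Mapping[str, str],
    fst_regions: Mapping[int, int],
    total_cds: int,
) -> SweepReportRow:
    """Assemble one report row from pipeline outputs.

    dN/dS categories are tallied over the flagged (low-diversity) genes only:
    ``below_genome_mean``, ``relaxed`` (mean dN/dS > 1), and ``none`` (no pair
    survived the filters).
    """
    flagged = [c.gene_id for c in sweep_calls if c.flagged]
    categories = [dnds_categories.get(g, "none") for g in flagged]
    return SweepReportRow.from_counts(
        mag=mag,
        n_cds=total_cds,
        n_low_pi=len(flagged),
        n_low_dnds=categories.count("below_genome_mean"),
        n_relaxed=categories.count("relaxed"),
        n_no_dnds=categories.count("none"),
        longest_run=longest_flagged_run(sweep_calls),
        fst_regions=fst_regions,
    )


def site_pi_by_gene(
    sites_by_sample: Mapping[str, Sequence[AlleleCountSite]],
    genes: Sequence[GeneModel],
    toi: Sequence[str],
    cfg: RunConfig | None = None,
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """Convenience: per-gene and genome-wide per-site diversity arrays per
    time point of interest, ready for :func:`low_diversity_genes`."""
    cfg = cfg or RunConfig()
    gene_arrays: dict[str, dict[str, np.ndarray]] = {g.gene_id: {} for g in genes}
    genome_arrays: dict[str, np.ndarray] = {}
    for tp in toi:
        sites = list(sites_by_sample.get(tp, []))
        genome_arrays[tp] = per_site_pi(sites, cfg)
        for g in genes:
            gene_arrays[g.gene_id][tp] = per_site_pi(sites_in_gene(sites, g), cfg)
    return gene_arrays, genome_arrays
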