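"""Linkage disequilibrium (r^2) with distance-binned decay curves, and the
four-gamete test.

Two biallelic sites observed on the same read pair carry one of four two-locus
haplotypes (AB, Ab, aB, ab).  Under infinite sites, observing all four (H4)
requires at least one recombination event.  r^2 decaying with inter-site
distance is the complementary population-level signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .tables_io import (
    HAPLOTYPE_KEYS,
    GeneModel,
    LinkedPair,
    RunConfig,
    ValidationError,
)


class MonomorphicPairError(ValueError):
    """r^2 is undefined when a site is monomorphic within the pair sample."""


def pair_r2(pair: LinkedPair) -> float:
    """Squared allele-frequency correlation from two-locus haplotype counts."""
    n = pair.total
    f_AB = pair.count("AB") / n
    f_A = (pair.count("AB") + pair.count("Ab")) / n
    f_B = (pair.count("AB") + pair.count("aB")) / n
    if f_A in (0.0, 1.0) or f_B in (0.0, 1.0):
        raise MonomorphicPairError(
            f"pair {pair.contig}:{pair.pos_a}/{pair.pos_b}: monomorphic site in sample"
        )
    d = f_AB - f_A * f_B
    return float(d * d / (f_A * (1 - f_A) * f_B * (1 - f_B)))


def classify_gametes(pair: LinkedPair, presence_threshold: int = 1) -> str:
    """H1..H4 by the number of haplotypes at or above the presence threshold."""
    present = sum(1 for k in HAPLOTYPE_KEYS if pair.count(k) >= presence_threshold)
    if present == 0:
        raise ValidationError("no haplotype reaches the presence threshold")
    return f"H{present}"


@dataclass
class GameteSummary:
    """Four-gamete class percentages (H1-H4) and mean biallelic site count."""

    percentages: dict[str, float]
    mean_biallelic_sites: float
    per_sample: pd.DataFrame


def gamete_frequencies(
    pairs: Iterable[LinkedPair],
    presence_threshold: int = 1,
    pooled: bool = False,
) -> GameteSummary:
    """Per-sample H1-H4 percentages, averaged across samples.

    ``pooled=True`` instead pools all pairs before computing percentages.
    The biallelic site count per sample is the number of distinct positions
    participating in any pair.
    """
    by_sample: dict[str, list[LinkedPair]] = {}
    for p in pairs:
        by_sample.setdefault(p.sample, []).append(p)
    if not by_sample:
        raise ValidationError("no classifiable pairs")

    rows = []
    for sample, sample_pairs in sorted(by_sample.items()):
        classes = [classify_gametes(p, presence_threshold) for p in sample_pairs]
        n = len(classes)
        sites = {(p.contig, p.pos_a) for p in sample_pairs} | {
            (p.contig, p.pos_b) for p in sample_pairs
        }
        row = {"sample": sample, "n_pairs": n, "n_biallelic_sites": len(sites)}
        for h in ("H1", "H2", "H3", "H4"):
            row[h] = 100.0 * classes.count(h) / n
        rows.append(row)
    per_sample = pd.DataFrame(rows).set_index("sample")

    if pooled:
        total = per_sample["n_pairs"].sum()
        percentages = {
            h: float((per_sample[h] * per_sample["n_pairs"]).sum() / total)
            for h in ("H1", "H2", "H3", "H4")
        }
    else:
        percentages = {h: float(per_sample[h].mean()) for h in ("H1", "H2", "H3", "H4")}
    return GameteSummary(
        percentages=percentages,
        mean_biallelic_sites=float(per_sample["n_biallelic_sites"].mean()),
        per_sample=per_sample,
    )


# ---------------------------------------------------------------------------
# Mutation typing and decay curves
# ---------------------------------------------------------------------------


def _codon_context(
    position: int, gene: GeneModel, sequence: str
) -> tuple[str, int] | None:
    """Return (codon on coding strand, within-codon index) for a site, or None
    if the gene length is not a codon multiple."""
    if gene.length % 3 != 0:
        return None
    if gene.strand == "+":
        offset = position - gene.start
    else:
        offset = gene.end - 1 - position
    codon_index, codon_pos = divmod(offset, 3)
    if gene.strand == "+":
        codon = sequence[gene.start + 3 * codon_index : gene.start + 3 * codon_index + 3]
    else:
        chunk = sequence[gene.end - 3 * codon_index - 3 : gene.end - 3 * codon_index]
        codon = str(Seq(chunk).reverse_complement())
    return codon, codon_pos


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_site_mutation(
    contig: str,
    position: int,
    alleles: tuple[str, str],
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
) -> str:
    """Type a biallelic site as 'S' (synonymous), 'N' (nonsynonymous) or
    'noncoding'.

    The two alleles are substituted into the codon of the containing gene (in
    the reference context) and the translations compared; identical amino
    acids make the site synonymous-typed.
    """
    gene = next(
        (g for g in genes if g.contig == contig and g.contains(position)), None
    )
    if gene is None:
        return "noncoding"
    context = _codon_context(position, gene, sequences[contig])
    if context is None:
        return "noncoding"
    codon, codon_pos = context
    a1, a2 = alleles
    if gene.strand == "-":
        a1, a2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
    variant1 = codon[:codon_pos] + a1 + codon[codon_pos + 1 :]
    variant2 = codon[:codon_pos] + a2 + codon[codon_pos + 1 :]
    aa1 = str(Seq(variant1).translate())
    aa2 = str(Seq(variant2).translate())
    return "S" if aa1 == aa2 else "N"


def classify_pair_mutation(
    pair: LinkedPair,
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
) -> str:
    """Pair mutation class: S-S, N-S, N-N, or noncoding."""
    type_a = classify_site_mutation(pair.contig, pair.pos_a, pair.alleles_a, genes, sequences)
    type_b = classify_site_mutation(pair.contig, pair.pos_b, pair.alleles_b, genes, sequences)
    if "noncoding" in (type_a, type_b):
        return "noncoding"
    if type_a == type_b:
        return f"{type_a}-{type_a}"
    return "N-S"


@dataclass
class DecayCurve:
    """Mean r^2 per 10-bp distance bin per mutation class.

    ``table`` columns: mutation_class, bin_start, bin_end (closed, 1-aligned),
    mean_r2, n_pairs.  Empty bins are omitted.
    """

    table: pd.DataFrame
    bin_width: int

    def class_curve(self, mutation_class: str) -> pd.DataFrame:
        return self.table[self.table["mutation_class"] == mutation_class].reset_index(drop=True)


def ld_decay_curve(
    pairs: Sequence[LinkedPair],
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    cfg: RunConfig | None = None,
) -> DecayCurve:
    """Bin pair r^2 by distance (1-10, 11-20, ...) and mutation class.

    Pairs with a monomorphic site are skipped; noncoding pairs are binned under
    their own class and excluded from the three coding classes.
    """
    cfg = cfg or RunConfig()
    width = cfg.ld_bin
    records = []
    for pair in pairs:
        try:
            r2 = pair_r2(pair)
        except MonomorphicPairError:
            continue
        mclass = pair.mutation_class or classify_pair_mutation(pair, genes, sequences)
        bin_index = (pair.distance - 1) // width
        records.append(
            {
                "mutation_class": mclass,
                "bin_start": bin_index * width + 1,
                "bin_end": (bin_index + 1) * width,
                "r2": r2,
            }
        )
    if not records:
        return DecayCurve(
            table=pd.DataFrame(
                columns=["mutation_class", "bin_start", "bin_end", "mean_r2", "n_pairs"]
            ),
            bin_width=width,
        )
    df = pd.DataFrame(records)
    grouped = (
        df.groupby(["mutation_class", "bin_start", "bin_end"])["r2"]
        .agg(mean_r2="mean", n_pairs="count")
        .reset_index()
        .sort_values(["mutation_class", "bin_start"])
        .reset_index(drop=True)
    )
    return DecayCurve(table=grouped, bin_width=width)
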