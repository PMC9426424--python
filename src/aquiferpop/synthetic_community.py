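"""Ground-truthed synthetic strain-mixture communities.

The simulator builds a single contig of protein-coding genes, places
biallelic strain-discriminating sites under an infinite-sites discipline
(each site's derived allele arises on exactly one clade of a random strain
tree, so four-gamete violations can only come from recombination), mixes
strains with user-supplied per-time-point fractions, and emits exactly the
tables the analysis pipeline consumes: per-site allele counts with Poisson
coverage, read-pair linkage counts, per-gene coverage, gene models and
contig sequences.

No generative model is claimed to match the field data; every choice here is
a stand-in whose purpose is to carry a known, recoverable signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .tables_io import (
    AlleleCountSite,
    GeneModel,
    LinkedPair,
    ValidationError,
    write_allele_counts,
    write_coverage_table,
    write_fasta,
    write_gff3,
    write_linkage_table,
)

_BASES = "ACGT"
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS
]


@dataclass
class SimConfig:
    """Sequencing-process knobs for the simulator."""

    genome_length: int = 20_000
    n_genes: int = 20
    coverage: float = 100.0  # Poisson mean read depth per site
    fragment_length: int = 200  # max span of a read pair linking two sites
    error_rate: float = 0.0  # per-base miscall probability
    pair_depth: float | None = None  # Poisson mean linking fragments; default coverage
    emit_invariant_sites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValidationError("coverage must be positive")
        if not (0.0 <= self.error_rate <= 0.01):
            raise ValidationError("error_rate must lie in [0, 0.01]")


@dataclass
class TruthSpec:
    """What community to build: strains, fractions, variation and CNV."""

    n_strains: int
    fractions: Sequence[Sequence[float]]  # time point x strain
    snv_density: float  # discriminating sites per kbp
    recomb_rate: float = 0.0
    gene_copy: Mapping[int, Sequence[float]] | None = None  # gene index -> per-strain copies
    swept_genes: Sequence[int] = ()  # gene indices forced monomorphic
    samples: Sequence[str] | None = None
    distance_scale: int | None = None  # bp over which recomb_rate reaches full strength

    def __post_init__(self) -> None:
        if not (1 <= self.n_strains <= 8):
            raise ValidationError("n_strains must be between 1 and 8")
        for row in self.fractions:
            if len(row) != self.n_strains:
                raise ValidationError("each fractions row needs one entry per strain")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValidationError("fractions rows must sum to 1")
            if any(f < 0 for f in row):
                raise ValidationError("fractions must be non-negative")
        if not (0.0 <= self.recomb_rate <= 1.0):
            raise ValidationError("recomb_rate must lie in [0, 1]")


@dataclass
class StrainTruth:
    """Ground truth of a generated community."""

    n_strains: int
    haplotypes: np.ndarray  # strain x site, 0 = ancestral, 1 = derived
    site_positions: list[tuple[str, int]]
    site_alleles: list[tuple[str, str]]  # (ancestral, derived) base per site
    gene_copy: np.ndarray  # strain x gene
    fractions: np.ndarray  # time point x strain
    recomb_rate: float
    swept_genes: set[str]
    samples: list[str]
    contig: str = "c1"
    distance_scale: int = 200

    def derived_frequency(self, sample_index: int) -> np.ndarray:
        """Mixture-weighted derived-allele frequency per site."""
        return self.fractions[sample_index] @ self.haplotypes

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_strains": self.n_strains,
                "haplotypes": self.haplotypes.tolist(),
                "site_positions": self.site_positions,
                "site_alleles": self.site_alleles,
                "gene_copy": self.gene_copy.tolist(),
                "fractions": self.fractions.tolist(),
                "recomb_rate": self.recomb_rate,
                "swept_genes": sorted(self.swept_genes),
                "samples": self.samples,
                "contig": self.contig,
                "distance_scale": self.distance_scale,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StrainTruth":
        data = json.loads(text)
        return cls(
            n_strains=data["n_strains"],
            haplotypes=np.array(data["haplotypes"], dtype=int),
            site_positions=[tuple(p) for p in data["site_positions"]],
            site_alleles=[tuple(a) for a in data["site_alleles"]],
            gene_copy=np.array(data["gene_copy"], dtype=float),
            fractions=np.array(data["fractions"], dtype=float),
            recomb_rate=data["recomb_rate"],
            swept_genes=set(data["swept_genes"]),
            samples=data["samples"],
            contig=data["contig"],
            distance_scale=data["distance_scale"],
        )


@dataclass
class CommunityBundle:
    """A complete synthetic input bundle plus its generating truth."""

    truth: StrainTruth
    contigs: dict[str, str]
    genes: list[GeneModel]
    sites_by_sample: dict[str, list[AlleleCountSite]]
    pairs_by_sample: dict[str, list[LinkedPair]]
    coverage: pd.DataFrame  # gene x sample mean coverage

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, out / "contigs.fasta")
        write_gff3(self.genes, out / "genes.gff3")
        all_sites = [s for tp in self.truth.samples for s in self.sites_by_sample[tp]]
        write_allele_counts(all_sites, out / "allele_counts.tsv")
        all_pairs = [p for tp in self.truth.samples for p in self.pairs_by_sample[tp]]
        write_linkage_table(all_pairs, out / "linkage.tsv")
        write_coverage_table(self.coverage, out / "coverage.tsv")
        (out / "truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# Genome and truth construction
# ---------------------------------------------------------------------------


def _random_clades(n_strains: int, rng: np.random.Generator) -> list[frozenset[int]]:
    """All proper clades of a random bifurcating strain tree (built by random
    sequential joins); leaves count as clades."""
    nodes = [frozenset([i]) for i in range(n_strains)]
    clades = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        if len(merged) < n_strains:
            clades.append(merged)
    return clades


def _build_genome(
    sim: SimConfig, rng: np.random.Generator
) -> tuple[str, list[GeneModel]]:
    """One contig tiled with complete ORFs separated by intergenic spacers."""
    slot = sim.genome_length // sim.n_genes
    gene_len = 3 * ((slot - 60) // 3)
    if gene_len < 33:
        raise ValidationError("genome_length too small for n_genes")
    seq = list(rng.choice(list(_BASES), size=sim.genome_length))
    genes = []
    for i in range(sim.n_genes):
        start = i * slot + 30
        end = start + gene_len
        n_codons = gene_len // 3
        body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
        orf = "ATG" + "".join(body) + "TAA"
        seq[start:end] = list(orf)
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                contig="c1",
                start=start,
                end=end,
                strand="+",
                contig_length=sim.genome_length,
            )
        )
    return "".join(seq), genes


def _safe_derived_base(
    position: int, sequence: str, genes: Sequence[GeneModel], rng: np.random.Generator
) -> str | None:
    """Pick a derived base that never creates a stop codon in a gene context."""
    ref = sequence[position]
    gene = next((g for g in genes if g.contains(position)), None)
    candidates = [str(b) for b in rng.permutation([b for b in _BASES if b != ref])]
    if gene is None:
        return candidates[0]
    offset = position - gene.start
    codon_start = gene.start + 3 * (offset // 3)
    codon = sequence[codon_start : codon_start + 3]
    within = position - codon_start
    for base in candidates:
        mutant = codon[:within] + base + codon[within + 1 :]
        if mutant not in _STOP_CODONS:
            return base
    return None


def simulate_truth(spec: TruthSpec, sim: SimConfig) -> tuple[StrainTruth, str, list[GeneModel]]:
    """Build the genome, the discriminating sites and the strain haplotypes."""
    rng = np.random.default_rng(sim.seed)
    sequence, genes = _build_genome(sim, rng)
    samples = list(spec.samples) if spec.samples else [
        f"TP{i}" for i in range(len(spec.fractions))
    ]

    swept_ids = {genes[i].gene_id for i in spec.swept_genes}
    for i in spec.swept_genes:
        if not (0 <= i < len(genes)):
            raise ValidationError(f"swept gene index {i} out of range")

    n_sites = int(round(spec.snv_density * sim.genome_length / 1000.0))
    positions: list[int] = []
    site_alleles: list[tuple[str, str]] = []
    if spec.n_strains >= 2 and n_sites > 0:
        blocked_codons: set[tuple[str, int]] = set()
        forbidden: set[int] = set()
        for g in genes:
            if g.gene_id in swept_ids:
                forbidden.update(range(g.start, g.end))
            else:  # keep start/stop codons intact
                forbidden.update(range(g.start, g.start + 3))
                forbidden.update(range(g.end - 3, g.end))
        candidates = np.array(
            [p for p in range(sim.genome_length) if p not in forbidden]
        )
        rng.shuffle(candidates)
        for p in candidates:
            if len(positions) == n_sites:
                break
            gene = next((g for g in genes if g.contains(p)), None)
            codon_key = None
            if gene is not None:
                codon_key = (gene.gene_id, (p - gene.start) // 3)
                if codon_key in blocked_codons:
                    continue
            derived = _safe_derived_base(int(p), sequence, genes, rng)
            if derived is None:
                continue
            positions.append(int(p))
            site_alleles.append((sequence[p], derived))
            if codon_key is not None:
                blocked_codons.add(codon_key)
        order = np.argsort(positions)
        positions = [positions[i] for i in order]
        site_alleles = [site_alleles[i] for i in order]

    haplotypes = np.zeros((spec.n_strains, len(positions)), dtype=int)
    if spec.n_strains >= 2 and positions:
        clades = _random_clades(spec.n_strains, rng)
        for j in range(len(positions)):
            clade = clades[rng.integers(len(clades))]
            haplotypes[list(clade), j] = 1

    gene_copy = np.ones((spec.n_strains, len(genes)))
    if spec.gene_copy:
        for gene_index, copies in spec.gene_copy.items():
            if len(copies) != spec.n_strains:
                raise ValidationError("gene_copy rows need one value per strain")
            gene_copy[:, gene_index] = np.asarray(copies, dtype=float)

    truth = StrainTruth(
        n_strains=spec.n_strains,
        haplotypes=haplotypes,
        site_positions=[("c1", p) for p in positions],
        site_alleles=site_alleles,
        gene_copy=gene_copy,
        fractions=np.asarray(spec.fractions, dtype=float),
        recomb_rate=spec.recomb_rate,
        swept_genes=swept_ids,
        samples=samples,
        contig="c1",
        distance_scale=spec.distance_scale or sim.fragment_length,
    )
    return truth, sequence, genes


# ---------------------------------------------------------------------------
# Observation layers
# ---------------------------------------------------------------------------


def _error_mix(prob4: np.ndarray, error_rate: float) -> np.ndarray:
    """Apply a symmetric per-base miscall to base-probability rows."""
    if error_rate == 0.0:
        return prob4
    return prob4 * (1.0 - error_rate) + (1.0 - prob4) * (error_rate / 3.0)


def _gene_index_per_position(genome_length: int, genes: Sequence[GeneModel]) -> np.ndarray:
    index = np.full(genome_length, -1, dtype=int)
    for i, g in enumerate(genes):
        index[g.start : g.end] = i
    return index


def simulate_allele_counts(
    truth: StrainTruth,
    sim: SimConfig,
    sample: str,
    sequence: str,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> list[AlleleCountSite]:
    """Poisson-coverage per-site nucleotide counts for one sample.

    Coverage at a position scales with the mixture-weighted copy number of
    its gene; allele frequencies are weighted the same way.  With
    ``emit_invariant_sites`` disabled only discriminating sites are emitted.
    """
    t = truth.samples.index(sample)
    w = truth.fractions[t]
    gene_index = _gene_index_per_position(sim.genome_length, genes)

    if sim.emit_invariant_sites:
        emit_positions = np.arange(sim.genome_length)
    else:
        emit_positions = np.array([p for _, p in truth.site_positions], dtype=int)

    # per-position coverage multiplier and strain weights from gene copy numbers
    copy_by_gene = truth.gene_copy  # strain x gene
    multipliers = np.ones(len(emit_positions))
    site_lookup = {p: j for j, (_, p) in enumerate(truth.site_positions)}

    base_index = {b: i for i, b in enumerate(_BASES)}
    probs = np.zeros((len(emit_positions), 4))
    for row, p in enumerate(emit_positions):
        gi = gene_index[p]
        if gi >= 0:
            strain_cov = w * copy_by_gene[:, gi]
        else:
            strain_cov = w
        total = strain_cov.sum()
        multipliers[row] = total
        j = site_lookup.get(int(p))
        if j is None or total == 0:
            probs[row, base_index[sequence[p]]] = 1.0
        else:
            weights = strain_cov / total
            p_derived = float(weights @ truth.haplotypes[:, j])
            anc, der = truth.site_alleles[j]
            probs[row, base_index[anc]] = 1.0 - p_derived
            probs[row, base_index[der]] += p_derived
    probs = _error_mix(probs, sim.error_rate)

    depth = rng.poisson(sim.coverage * multipliers)
    counts = rng.multinomial(depth, probs)

    sites = []
    for row, p in enumerate(emit_positions):
        if depth[row] == 0:
            continue
        sites.append(
            AlleleCountSite(
                contig=truth.contig,
                position=int(p),
                sample=sample,
                reference_base=sequence[p],
                counts={b: int(counts[row, i]) for i, b in enumerate(_BASES)},
            )
        )
    return sites


def simulate_linked_pairs(
    truth: StrainTruth,
    sim: SimConfig,
    sample: str,
    rng: np.random.Generator,
) -> list[LinkedPair]:
    """Two-locus haplotype counts for site pairs within the fragment length.

    Each linking fragment carries the two alleles of one strain drawn by
    mixture weight; with probability ``recomb_rate * min(1, d/distance_scale)``
    the second allele is re-drawn from an independently chosen strain
    (re-assortment), which is the only mechanism that can produce a fourth
    haplotype when sequencing error is off.
    """
    t = truth.samples.index(sample)
    w = truth.fractions[t]
    positions = [p for _, p in truth.site_positions]
    n_sites = len(positions)
    pair_depth = sim.pair_depth if sim.pair_depth is not None else sim.coverage
    pairs: list[LinkedPair] = []

    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            d = positions[j] - positions[i]
            if d >= sim.fragment_length:
                break
            p_anc_a = 1.0 - float(w @ truth.haplotypes[:, i])
            p_anc_b = 1.0 - float(w @ truth.haplotypes[:, j])
            joint = np.zeros((2, 2))
            for s in range(truth.n_strains):
                joint[truth.haplotypes[s, i], truth.haplotypes[s, j]] += w[s]
            marginal = np.outer(
                [p_anc_a, 1.0 - p_anc_a], [p_anc_b, 1.0 - p_anc_b]
            )
            r_eff = truth.recomb_rate * min(1.0, d / truth.distance_scale)
            hap_probs = (1.0 - r_eff) * joint + r_eff * marginal
            if sim.error_rate > 0.0:
                flip = np.array(
                    [[1.0 - sim.error_rate, sim.error_rate],
                     [sim.error_rate, 1.0 - sim.error_rate]]
                )
                hap_probs = flip @ hap_probs @ flip.T
            n = rng.poisson(pair_depth * (1.0 - d / sim.fragment_length))
            if n == 0:
                continue
            draw = rng.multinomial(n, hap_probs.reshape(-1))
            anc_a, der_a = truth.site_alleles[i]
            anc_b, der_b = truth.site_alleles[j]
            pairs.append(
                LinkedPair(
                    contig=truth.contig,
                    pos_a=positions[i],
                    pos_b=positions[j],
                    sample=sample,
                    alleles_a=(anc_a, der_a),
                    alleles_b=(anc_b, der_b),
                    hap_counts={
                        "AB": int(draw[0]),
                        "Ab": int(draw[1]),
                        "aB": int(draw[2]),
                        "ab": int(draw[3]),
                    },
                )
            )
    return pairs


def simulate_gene_coverage(
    truth: StrainTruth,
    sim: SimConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mean per-gene coverage table (gene x sample) with Poisson noise."""
    table = pd.DataFrame(index=[g.gene_id for g in genes], columns=truth.samples, dtype=float)
    table.index.name = "gene_id"
    for t, sample in enumerate(truth.samples):
        w = truth.fractions[t]
        for gi, g in enumerate(genes):
            lam = sim.coverage * float(w @ truth.gene_copy[:, gi])
            total_bases = rng.poisson(lam * g.length)
            table.loc[g.gene_id, sample] = total_bases / g.length
    return table


def generate_community(sim: SimConfig, spec: TruthSpec) -> CommunityBundle:
    """Build the full synthetic input bundle; deterministic for a given seed."""
    truth, sequence, genes = simulate_truth(spec, sim)
    rng = np.random.default_rng(sim.seed + 1)  # independent of genome construction
    sites_by_sample = {}
    pairs_by_sample = {}
    for sample in truth.samples:
        sites_by_sample[sample] = simulate_allele_counts(
            truth, sim, sample, sequence, genes, rng
        )
        pairs_by_sample[sample] = simulate_linked_pairs(truth, sim, sample, rng)
    coverage = simulate_gene_coverage(truth, sim, genes, rng)
    return CommunityBundle(
        truth=truth,
        contigs={truth.contig: sequence},
        genes=genes,
        sites_by_sample=sites_by_sample,
        pairs_by_sample=pairs_by_sample,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Strain-fraction recovery
# ---------------------------------------------------------------------------


def estimate_strain_fractions(
    observed_frequencies: Sequence[float],
    haplotypes: np.ndarray,
) -> np.ndarray:
    """Recover mixture fractions from derived-allele frequencies by
    non-negative least squares on the simplex.

    Solves ``min || H^T w - f ||`` subject to ``w >= 0`` and ``sum(w) = 1``
    (enforced with a heavily weighted penalty row, then renormalized).
    Strains with identical haplotype rows are indistinguishable; they are
    merged for the solve, a warning is emitted, and the merged weight is
    split equally among the duplicates.
    """
    H = np.asarray(haplotypes, dtype=float)
    f = np.asarray(observed_frequencies, dtype=float)
    n_strains, n_sites = H.shape
    if f.shape != (n_sites,):
        raise ValidationError("frequency vector length must match haplotype sites")

    # group identical strains
    groups: dict[bytes, list[int]] = {}
    for s in range(n_strains):
        groups.setdefault(H[s].tobytes(), []).append(s)
    group_list = list(groups.values())
    if len(group_list) < n_strains:
        merged = [g for g in group_list if len(g) > 1]
        warnings.warn(
            f"indistinguishable strains merged: {merged}",
            UserWarning,
            stacklevel=2,
        )
    H_unique = np.array([H[g[0]] for g in group_list])

    rho = 1e4
    A = np.vstack([H_unique.T, rho * np.ones((1, len(group_list)))])
    b = np.concatenate([f, [rho]])
    w_unique, _ = nnls(A, b)
    total = w_unique.sum()
    if total > 0:
        w_unique = w_unique / total
    w = np.zeros(n_strains)
    for group, weight in zip(group_list, w_unique):
        for s in group:
            w[s] = weight / len(group)
    return w
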