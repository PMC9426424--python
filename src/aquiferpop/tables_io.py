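"""Shared domain types, readers/writers for the project table formats, and run
configuration.

Coordinates are 0-based half-open internally; human-facing report output is
1-based.  All tabular formats are plain TSV with a header row so that a full
input bundle survives text-only archiving.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = ("A", "C", "G", "T")

HAPLOTYPE_KEYS = ("AB", "Ab", "aB", "ab")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleCountSite:
    """Per-position nucleotide counts for one sample (time point).

    ``position`` is a 0-based offset on ``contig``.  ``counts`` maps each of
    A/C/G/T to a non-negative read count; missing nucleotides are treated as
    zero.
    """

    contig: str
    position: int
    sample: str
    reference_base: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for nuc, c in self.counts.items():
            if nuc not in NUCLEOTIDES:
                raise ValidationError(f"unknown nucleotide {nuc!r} at {self.contig}:{self.position}")
            if c < 0:
                raise ValidationError(
                    f"negative count for {nuc} at {self.contig}:{self.position} ({self.sample})"
                )
        if self.position < 0:
            raise ValidationError(f"negative position {self.position} on {self.contig}")

    @property
    def coverage(self) -> int:
        return int(sum(self.counts.get(n, 0) for n in NUCLEOTIDES))

    def count(self, nuc: str) -> int:
        return int(self.counts.get(nuc, 0))

    @property
    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(n, 0) for n in NUCLEOTIDES], dtype=float)

    @property
    def n_alleles(self) -> int:
        return int(sum(1 for n in NUCLEOTIDES if self.counts.get(n, 0) > 0))


@dataclass(frozen=True)
class SnvRecord:
    """A site that passed the variant filters, with its summary statistics."""

    site: AlleleCountSite
    major_allele: str
    major_allele_frequency: float
    departure_from_consensus: float
    entropy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.major_allele_frequency <= 1.0):
            raise ValidationError("major_allele_frequency outside [0, 1]")
        if self.entropy < 0:
            raise ValidationError("entropy must be non-negative")


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene: 0-based half-open interval on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    contig_length: int | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.contig_length is not None and self.end > self.contig_length:
            raise ValidationError(f"gene {self.gene_id} overruns contig end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class LinkedPair:
    """Two-locus haplotype counts for a pair of biallelic sites observed on
    the same read or read pair.

    ``alleles_a`` is the (A, a) allele pair at the first site, ``alleles_b``
    the (B, b) pair at the second; ``hap_counts`` maps AB/Ab/aB/ab to read
    counts.
    """

    contig: str
    pos_a: int
    pos_b: int
    sample: str
    alleles_a: tuple[str, str]
    alleles_b: tuple[str, str]
    hap_counts: Mapping[str, int]
    mutation_class: str | None = None

    def __post_init__(self) -> None:
        if self.pos_a == self.pos_b:
            raise ValidationError("linked pair requires two distinct positions")
        for key in HAPLOTYPE_KEYS:
            if self.hap_counts.get(key, 0) < 0:
                raise ValidationError(f"negative haplotype count {key}")
        if self.total == 0:
            raise ValidationError(
                f"linked pair {self.contig}:{self.pos_a}/{self.pos_b} has no observations"
            )

    @property
    def distance(self) -> int:
        return abs(self.pos_b - self.pos_a)

    @property
    def total(self) -> int:
        return int(sum(self.hap_counts.get(k, 0) for k in HAPLOTYPE_KEYS))

    def count(self, key: str) -> int:
        return int(self.hap_counts.get(key, 0))


class AbundanceMatrix:
    """MAG x time-point RPKM table, columns in chronological order."""

    def __init__(
        self,
        values: pd.DataFrame,
        mag_lengths: Mapping[str, int] | None = None,
        sample_sizes: Mapping[str, int] | None = None,
    ) -> None:
        if (values.to_numpy() < 0).any():
            raise ValidationError("abundance values must be non-negative")
        self.values = values.astype(float)
        self.mag_lengths = dict(mag_lengths) if mag_lengths else {}
        self.sample_sizes = dict(sample_sizes) if sample_sizes else {}

    @property
    def mags(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, mag: str) -> pd.Series:
        if mag not in self.values.index:
            raise KeyError(f"unknown MAG {mag!r}")
        return self.values.loc[mag]


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults follow the study's published filters."""

    min_coverage: int = 20
    min_departure: float = 0.10
    min_rpkm_toi: float = 5.0
    rpkm_spike: float = 30.0
    min_toi_count: int = 3
    ld_bin: int = 10
    fst_window: int = 5
    fst_sd_levels: tuple[int, ...] = (1, 2)
    genefreq_delta: float = 1.0
    min_contig_len: int = 2500
    dn_min: float = 0.0
    ds_range: tuple[float, float] = (0.01, 1.0)
    dnds_max: float = 5.0
    alpha: float = 0.05
    min_sites_per_gene: int = 10
    presence_threshold: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_rpkm_toi", "rpkm_spike", "min_toi_count",
                     "ld_bin", "fst_window", "genefreq_delta", "min_contig_len",
                     "dnds_max", "alpha", "min_departure"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        lo, hi = self.ds_range
        if not (0 <= lo < hi):
            raise ValidationError("ds_range must be an increasing positive interval")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key = value`` text config; unknown keys are an error."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            ftype = known[key].type
            if "tuple" in str(ftype):
                parts = [p for p in value.replace(",", " ").split() if p]
                kwargs[key] = tuple(float(p) if "." in p else int(p) for p in parts)
            elif "float" in str(ftype):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ALLELE_COLUMNS = ["contig", "position", "sample", "ref", "A", "C", "G", "T"]
_LINKAGE_COLUMNS = [
    "contig", "pos_a", "pos_b", "sample",
    "allele_A", "allele_a", "allele_B", "allele_b",
    "n_AB", "n_Ab", "n_aB", "n_ab", "mutation_class",
]
_COVERAGE_COLUMNS = ["gene_id", "sample", "mean_coverage"]
_ABUNDANCE_COLUMNS = ["mag", "sample", "mapped_reads"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_allele_counts(path: str | Path) -> list[AlleleCountSite]:
    df = _read_tsv(path, _ALLELE_COLUMNS)
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        counts = {}
        for nuc in NUCLEOTIDES:
            c = int(getattr(row, nuc))
            if c < 0:
                raise ValidationError(f"{path}: negative count in row {i}")
            counts[nuc] = c
        sites.append(
            AlleleCountSite(
                contig=row.contig,
                position=int(row.position),
                sample=row.sample,
                reference_base=row.ref,
                counts=counts,
            )
        )
    return sites


def write_allele_counts(sites: Iterable[AlleleCountSite], path: str | Path) -> None:
    rows = [
        {
            "contig": s.contig,
            "position": s.position,
            "sample": s.sample,
            "ref": s.reference_base,
            **{n: s.counts.get(n, 0) for n in NUCLEOTIDES},
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_ALLELE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_linkage_table(path: str | Path) -> list[LinkedPair]:
    df = _read_tsv(path, _LINKAGE_COLUMNS)
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        haps = {
            "AB": int(row.n_AB),
            "Ab": int(row.n_Ab),
            "aB": int(row.n_aB),
            "ab": int(row.n_ab),
        }
        if any(v < 0 for v in haps.values()):
            raise ValidationError(f"{path}: negative haplotype count in row {i}")
        pairs.append(
            LinkedPair(
                contig=row.contig,
                pos_a=int(row.pos_a),
                pos_b=int(row.pos_b),
                sample=row.sample,
                alleles_a=(row.allele_A, row.allele_a),
                alleles_b=(row.allele_B, row.allele_b),
                hap_counts=haps,
                mutation_class=row.mutation_class or None,
            )
        )
    return pairs


def write_linkage_table(pairs: Iterable[LinkedPair], path: str | Path) -> None:
    rows = [
        {
            "contig": p.contig,
            "pos_a": p.pos_a,
            "pos_b": p.pos_b,
            "sample": p.sample,
            "allele_A": p.alleles_a[0],
            "allele_a": p.alleles_a[1],
            "allele_B": p.alleles_b[0],
            "allele_b": p.alleles_b[1],
            "n_AB": p.count("AB"),
            "n_Ab": p.count("Ab"),
            "n_aB": p.count("aB"),
            "n_ab": p.count("ab"),
            "mutation_class": p.mutation_class or "",
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_LINKAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Long-format (gene_id, sample, mean_coverage) TSV -> gene x sample frame."""
    df = _read_tsv(path, _COVERAGE_COLUMNS)
    df["mean_coverage"] = df["mean_coverage"].astype(float)
    if (df["mean_coverage"] < 0).any():
        raise ValidationError(f"{path}: negative coverage value")
    wide = df.pivot(index="gene_id", columns="sample", values="mean_coverage")
    wide.columns.name = None
    wide.index.name = "gene_id"
    return wide


def write_coverage_table(table: pd.DataFrame, path: str | Path) -> None:
    long = table.stack().rename("mean_coverage").reset_index()
    long.columns = _COVERAGE_COLUMNS
    long.to_csv(path, sep="\t", index=False)


def read_abundance_table(
    path: str | Path,
    mag_lengths: Mapping[str, int] | None = None,
    sample_sizes: Mapping[str, int] | None = None,
) -> AbundanceMatrix:
    """Long-format (mag, sample, mapped_reads) read counts; values stay raw
    counts — use :func:`aquiferpop.abundance_selection.rpkm_matrix` to
    normalize."""
    df = _read_tsv(path, _ABUNDANCE_COLUMNS)
    df["mapped_reads"] = df["mapped_reads"].astype(float)
    wide = df.pivot(index="mag", columns="sample", values="mapped_reads").fillna(0.0)
    wide.columns.name = None
    return AbundanceMatrix(wide, mag_lengths=mag_lengths, sample_sizes=sample_sizes)


def read_gff3(path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Parse gene features from a GFF3 file (1-based inclusive on disk,
    converted to 0-based half-open)."""
    genes = []
    contig_lengths = contig_lengths or {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _source, _ftype, start, end, _score, strand, _frame, attrs = fields
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID", f"{contig}_{lineno}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=contig,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    contig_length=contig_lengths.get(contig),
                    annotation=attr_map.get("product"),
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write(
                "\t".join(
                    [g.contig, "aquiferpop", "CDS", str(g.start + 1), str(g.end),
                     ".", g.strand, "0", attrs]
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate identifier {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)


def validate_bundle(
    sites: Sequence[AlleleCountSite] | None = None,
    genes: Sequence[GeneModel] | None = None,
    pairs: Sequence[LinkedPair] | None = None,
    sequences: Mapping[str, str] | None = None,
) -> ValidationReport:
    """Cross-check any subset of an input bundle; an empty report is valid."""
    report = ValidationReport()
    sites = sites or []
    genes = genes or []
    pairs = pairs or []

    site_index = {(s.contig, s.position, s.sample) for s in sites}
    site_positions = {(s.contig, s.position) for s in sites}

    if sequences is not None:
        for s in sites:
            if s.contig not in sequences:
                report.add(f"site {s.contig}:{s.position}: unknown contig")
            elif s.position >= len(sequences[s.contig]):
                report.add(f"site {s.contig}:{s.position}: beyond contig end")
        for g in genes:
            if g.contig not in sequences:
                report.add(f"gene {g.gene_id}: unknown contig {g.contig}")
            elif g.end > len(sequences[g.contig]):
                report.add(f"gene {g.gene_id}: interval overruns contig end")

    if sites:
        for p in pairs:
            for pos in (p.pos_a, p.pos_b):
                if (p.contig, pos, p.sample) not in site_index and (
                    p.contig, pos
                ) not in site_positions:
                    report.add(
                        f"pair {p.contig}:{p.pos_a}/{p.pos_b} ({p.sample}): "
                        f"position {pos} not among allele-count sites"
                    )
    for s in sites:
        if s.n_alleles > 2:
            report.add(
                f"site {s.contig}:{s.position} ({s.sample}): more than two alleles "
                "(excluded from linkage analyses)"
            )
    return report


def shannon_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy (bits) of a count vector; 0 iff one class has all mass."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        return 0.0
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum()) if p.size > 1 else 0.0
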