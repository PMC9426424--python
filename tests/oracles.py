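"""Independent brute-force oracles used to cross-check the main
implementations.  These are deliberately written in the most literal way
possible (enumeration, rational arithmetic) and share no code with the
package."""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

_BASES = "ACGT"

# standard genetic code, written out independently of the package
_CODE = {}
_bases_ordered = "TCAG"
_aas = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_bases_ordered):
    for _j, _b in enumerate(_bases_ordered):
        for _k, _c in enumerate(_bases_ordered):
            _CODE[_a + _b + _c] = _aas[16 * _i + 4 * _j + _k]


def snv_filter_oracle(counts: dict, min_coverage: int, min_departure: float) -> bool:
    """Literal application of the three SNV filters to a count mapping."""
    values = [counts.get(n, 0) for n in _BASES]
    coverage = sum(values)
    if coverage == 0 or coverage < min_coverage:
        return False
    entropy = -sum(
        (c / coverage) * math.log2(c / coverage) for c in values if c > 0
    )
    if entropy <= 0.0:
        return False
    departure = 1.0 - max(values) / coverage
    return departure >= min_departure


def site_pi_oracle(counts: dict) -> float:
    """Mismatch probability by enumerating every unordered read pair."""
    reads = []
    for nuc in _BASES:
        reads.extend([nuc] * counts.get(nuc, 0))
    pairs = list(combinations(reads, 2))
    mismatches = sum(1 for a, b in pairs if a != b)
    return mismatches / len(pairs)


def r2_oracle(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> float:
    """Squared Pearson correlation over the expanded per-read allele arrays."""
    x = [1] * (n_AB + n_Ab) + [0] * (n_aB + n_ab)
    y = [1] * n_AB + [0] * n_Ab + [1] * n_aB + [0] * n_ab
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def hudson_fst_oracle(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    numerator = (p1 - p2) ** 2 - (p1 * (1 - p1)) / (n1 - 1) - (p2 * (1 - p2)) / (n2 - 1)
    denominator = p1 * (1 - p2) + p2 * (1 - p1)
    return numerator, denominator


# ---------------------------------------------------------------------------
# NG86 oracle: exact rational arithmetic, recursive pathway enumeration
# ---------------------------------------------------------------------------


def _oracle_codon_sites(codon: str) -> tuple[Fraction, Fraction]:
    aa = _CODE[codon]
    syn = Fraction(0)
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODE[mutant] == aa and _CODE[mutant] != "*":
                syn += Fraction(1, 3)
    return syn, Fraction(3) - syn


def _enumerate_paths(current: str, target: str):
    """Yield (syn_steps, nonsyn_steps, passed_through_stop) for every complete
    mutational path from ``current`` to ``target``."""
    diffs = [i for i in range(3) if current[i] != target[i]]
    if not diffs:
        yield 0, 0, False
        return
    for pos in diffs:
        mutant = current[:pos] + target[pos] + current[pos + 1 :]
        step_syn = int(_CODE[mutant] == _CODE[current] and _CODE[mutant] != "*")
        hit_stop = _CODE[mutant] == "*"
        for syn, nonsyn, stopped in _enumerate_paths(mutant, target):
            yield step_syn + syn, (1 - step_syn) + nonsyn, hit_stop or stopped


def ng86_oracle(h1: str, h2: str) -> tuple[float, float]:
    codons1 = [h1[i : i + 3] for i in range(0, len(h1), 3)]
    codons2 = [h2[i : i + 3] for i in range(0, len(h2), 3)]
    syn_sites = nonsyn_sites = Fraction(0)
    syn_diffs = nonsyn_diffs = Fraction(0)
    for c1, c2 in zip(codons1, codons2):
        s1, n1 = _oracle_codon_sites(c1)
        s2, n2 = _oracle_codon_sites(c2)
        syn_sites += (s1 + s2) / 2
        nonsyn_sites += (n1 + n2) / 2
        paths = list(_enumerate_paths(c1, c2))
        valid = [p for p in paths if not p[2]]
        use = valid if valid else paths
        syn_diffs += Fraction(sum(p[0] for p in use), len(use))
        nonsyn_diffs += Fraction(sum(p[1] for p in use), len(use))
    ps = syn_diffs / syn_sites if syn_sites else Fraction(0)
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites else Fraction(0)

    def jc(p: Fraction) -> float:
        if p == 0:
            return 0.0
        return -0.75 * math.log(1.0 - 4.0 * float(p) / 3.0)

    return jc(pn), jc(ps)


def random_coding_pair(rng: np.random.Generator, n_codons: int, divergence: float):
    """A random stop-free coding sequence and a diverged copy (also stop-free)."""
    sense = [c for c in _CODE if _CODE[c] != "*"]
    seq1 = "".join(rng.choice(sense, size=n_codons))
    seq2 = list(seq1)
    n_mut = max(1, int(round(divergence * len(seq1))))
    mutated = 0
    while mutated < n_mut:
        pos = int(rng.integers(len(seq2)))
        base = _BASES[int(rng.integers(4))]
        if base == seq2[pos]:
            continue
        old = seq2[pos]
        seq2[pos] = base
        codon_start = 3 * (pos // 3)
        if _CODE["".join(seq2[codon_start : codon_start + 3])] == "*":
            seq2[pos] = old
            continue
        mutated += 1
    return seq1, "".join(seq2)
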