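import numpy as np
import pandas as pd
import pytest

from aquiferpop.datasets import north_pond_sweep_counts
from aquiferpop.sweep_and_content import (
    SweepCall,
    fst_ratio_of_sums,
    gene_fst,
    gene_frequency,
    hudson_fst_site,
    longest_flagged_run,
    low_diversity_genes,
    percent_half_up,
    site_pi_by_gene,
    summarize_sweep_report,
    SweepReportRow,
    window_fst_scan,
)
from aquiferpop.synthetic_community import SimConfig, TruthSpec, generate_community
from aquiferpop.tables_io import AlleleCountSite, GeneModel, RunConfig, ValidationError

from oracles import hudson_fst_oracle


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------


def test_fst_complete_differentiation():
    num, den = hudson_fst_site(1.0, 100, 0.0, 100)
    assert num == pytest.approx(1.0)
    assert den == pytest.approx(1.0)


def test_fst_equal_frequencies_negative():
    num, den = hudson_fst_site(0.5, 11, 0.5, 11)
    assert num == pytest.approx(-0.05)
    assert den == pytest.approx(0.5)
    assert num / den == pytest.approx(-0.1)


def test_fst_derived_example():
    num, den = hudson_fst_site(0.9, 10, 0.1, 10)
    assert num == pytest.approx(0.62)
    assert den == pytest.approx(0.82)
    assert num / den == pytest.approx(0.62 / 0.82)


def test_fst_matches_formula_oracle(rng):
    for _ in range(100):
        p1, p2 = rng.uniform(0, 1, size=2)
        n1, n2 = rng.integers(2, 200, size=2)
        assert hudson_fst_site(p1, int(n1), p2, int(n2)) == pytest.approx(
            hudson_fst_oracle(p1, int(n1), p2, int(n2)), abs=1e-12
        )


def test_fst_requires_two_samples():
    with pytest.raises(ValidationError):
        hudson_fst_site(0.5, 1, 0.5, 10)


def test_fst_ratio_of_sums_skips_zero_denominator():
    terms = [(0.5, 0.0), (0.3, 0.6)]
    assert fst_ratio_of_sums(terms) == pytest.approx(0.5)
    assert np.isnan(fst_ratio_of_sums([(0.1, 0.0)]))


def test_fst_negative_bias_on_identical_mixtures():
    """Ratio-of-sums F_ST between two samples of the same mixture is <= 0 in
    expectation (mean over seeds)."""
    values = []
    for seed in range(10):
        sim = SimConfig(genome_length=4000, n_genes=4, coverage=100.0, seed=seed)
        spec = TruthSpec(
            n_strains=2, fractions=[[0.6, 0.4], [0.6, 0.4]], snv_density=10.0
        )
        bundle = generate_community(sim, spec)
        fst = gene_fst(
            bundle.sites_by_sample["TP0"], bundle.sites_by_sample["TP1"]
        )
        if np.isfinite(fst):
            values.append(fst)
    assert np.mean(values) <= 0.005


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------


def _tiled_genes(n, contig="c1", length=300):
    return [
        GeneModel(f"g{i:03d}", contig, i * length, (i + 1) * length, "+")
        for i in range(n)
    ]


def test_window_scan_uniform_no_regions():
    genes = _tiled_genes(20)
    per_gene = {g.gene_id: 0.1 for g in genes}
    result = window_fst_scan(per_gene, genes)
    assert result.region_counts == {1: 0, 2: 0}


def test_window_scan_detects_elevated_block():
    rng = np.random.default_rng(0)
    genes = _tiled_genes(30)
    per_gene = {g.gene_id: float(v) for g, v in zip(genes, rng.normal(0.05, 0.01, 30))}
    for g in genes[10:15]:
        per_gene[g.gene_id] = 0.8
    result = window_fst_scan(per_gene, genes)
    assert result.region_counts[1] >= 1


def test_window_scan_threshold_monotone(rng):
    genes = _tiled_genes(40)
    per_gene = {g.gene_id: float(v) for g, v in zip(genes, rng.normal(0.1, 0.05, 40))}
    result = window_fst_scan(per_gene, genes)
    assert result.region_counts[2] <= result.region_counts[1]


def test_window_scan_short_contig_no_windows():
    genes = _tiled_genes(3)
    per_gene = {g.gene_id: 0.5 for g in genes}
    result = window_fst_scan(per_gene, genes)
    assert result.windows == []


def test_window_scan_merges_overlapping_windows():
    genes = _tiled_genes(30)
    per_gene = {g.gene_id: 0.0 for g in genes}
    for g in genes[10:17]:  # 7 consecutive high genes -> 3 overlapping windows
        per_gene[g.gene_id] = 1.0
    result = window_fst_scan(per_gene, genes)
    assert result.region_counts[1] == 1


# ---------------------------------------------------------------------------
# gene_fst on synthetic differentiation
# ---------------------------------------------------------------------------


def _differentiated_scenario(rng, n_genes=20, sites_per_gene=5, coverage=100):
    """Two samples; genes 8-12 strongly differentiated, others identical."""
    genes = _tiled_genes(n_genes, length=300)
    sites = {"TP0": [], "TP1": []}
    for gi, gene in enumerate(genes):
        differentiated = 8 <= gi <= 12
        for k in range(sites_per_gene):
            pos = gene.start + 30 * (k + 1)
            p0, p1 = (0.85, 0.15) if differentiated else (0.5, 0.5)
            for tp, p in (("TP0", p0), ("TP1", p1)):
                derived = rng.binomial(coverage, p)
                sites[tp].append(
                    AlleleCountSite(
                        "c1", pos, tp, "A",
                        {"A": coverage - derived, "C": derived, "G": 0, "T": 0},
                    )
                )
    return genes, sites


def test_gene_fst_and_scan_on_differentiated_block(rng):
    genes, sites = _differentiated_scenario(rng)
    per_gene = {
        g.gene_id: gene_fst(
            [s for s in sites["TP0"] if g.contains(s.position)],
            [s for s in sites["TP1"] if g.contains(s.position)],
        )
        for g in genes
    }
    block = [per_gene[g.gene_id] for g in genes[8:13]]
    background = [per_gene[g.gene_id] for g in genes[:8]]
    assert min(block) > max(background)
    result = window_fst_scan(per_gene, genes)
    assert result.region_counts[1] >= 1
    assert result.region_counts[2] <= result.region_counts[1]


# ---------------------------------------------------------------------------
# low-diversity scan
# ---------------------------------------------------------------------------


def test_gene_identical_to_genome_not_flagged(rng):
    toi = ["TP0", "TP1"]
    genome = {tp: rng.exponential(0.005, size=2000) for tp in toi}
    gene_arrays = {"g1": {tp: genome[tp][:100] for tp in toi}}
    calls = low_diversity_genes(gene_arrays, genome, toi, ["g1"])
    assert calls[0].tested
    assert not calls[0].flagged


def test_swept_gene_flagged_in_all_toi():
    sim = SimConfig(genome_length=8000, n_genes=8, coverage=60.0, seed=21)
    spec = TruthSpec(
        n_strains=2,
        fractions=[[0.6, 0.4], [0.5, 0.5], [0.45, 0.55]],
        snv_density=8.0,
        swept_genes=[3],
    )
    bundle = generate_community(sim, spec)
    toi = bundle.truth.samples
    gene_arrays, genome_arrays = site_pi_by_gene(
        bundle.sites_by_sample, bundle.genes, toi
    )
    calls = low_diversity_genes(
        gene_arrays, genome_arrays, toi, [g.gene_id for g in bundle.genes]
    )
    by_id = {c.gene_id: c for c in calls}
    assert by_id["gene0003"].flagged
    assert all(p <= 0.05 for p in by_id["gene0003"].p_values.values())


def test_consecutive_swept_genes_form_one_run():
    sim = SimConfig(genome_length=12_000, n_genes=12, coverage=60.0, seed=22)
    spec = TruthSpec(
        n_strains=2,
        fractions=[[0.6, 0.4], [0.5, 0.5]],
        snv_density=8.0,
        swept_genes=[4, 5, 6, 7, 8],
    )
    bundle = generate_community(sim, spec)
    toi = bundle.truth.samples
    gene_arrays, genome_arrays = site_pi_by_gene(
        bundle.sites_by_sample, bundle.genes, toi
    )
    calls = low_diversity_genes(
        gene_arrays, genome_arrays, toi, [g.gene_id for g in bundle.genes]
    )
    flagged_runs = {c.run_id for c in calls if c.flagged}
    assert longest_flagged_run(calls) == 5
    assert len(flagged_runs) == 1


def test_untested_gene_recorded():
    toi = ["TP0"]
    genome = {"TP0": np.full(500, 0.004)}
    gene_arrays = {"g1": {"TP0": np.array([0.0, 0.0])}}  # below site floor
    calls = low_diversity_genes(gene_arrays, genome, toi, ["g1"])
    assert not calls[0].tested
    assert not calls[0].flagged


# ---------------------------------------------------------------------------
# gene frequency
# ---------------------------------------------------------------------------


def test_gene_frequency_median_normalization():
    coverage = pd.DataFrame(
        {"TP0": [10.0, 10.0, 10.0, 20.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    result = gene_frequency(coverage, toi=["TP0"])
    assert list(result.frequencies["TP0"]) == [1.0, 1.0, 1.0, 2.0]


def test_gene_frequency_variable_rule():
    coverage = pd.DataFrame(
        {"TP0": [10.0, 2.0, 10.0], "TP1": [10.0, 15.0, 10.0]},
        index=["g1", "g2", "g3"],
    )
    result = gene_frequency(coverage, toi=["TP0", "TP1"])
    # g2 frequency: 0.2 -> 1.5, range 1.3 >= 1
    assert result.variable_genes == {"g2"}


def test_gene_frequency_scale_invariant():
    coverage = pd.DataFrame(
        {"TP0": [10.0, 30.0, 20.0], "TP1": [5.0, 10.0, 20.0]},
        index=["g1", "g2", "g3"],
    )
    base = gene_frequency(coverage, toi=["TP0", "TP1"])
    scaled = gene_frequency(coverage * [7.0, 3.0], toi=["TP0", "TP1"])
    pd.testing.assert_frame_equal(base.frequencies, scaled.frequencies)


def test_gene_frequency_zero_median_error():
    coverage = pd.DataFrame({"TP0": [0.0, 0.0, 1.0]}, index=["g1", "g2", "g3"])
    with pytest.raises(ValidationError, match="median"):
        gene_frequency(coverage, toi=["TP0"])


def test_gene_frequency_contig_length_filter():
    coverage = pd.DataFrame({"TP0": [10.0, 10.0]}, index=["g1", "g2"])
    genes = [
        GeneModel("g1", "long", 0, 300, "+"),
        GeneModel("g2", "short", 0, 300, "+"),
    ]
    lengths = {"long": 5000, "short": 1000}
    result = gene_frequency(coverage, toi=["TP0"], genes=genes, contig_lengths=lengths)
    assert list(result.frequencies.index) == ["g1"]


def test_multicopy_element_trajectory():
    """A 4-copy element in one strain tracks the mixture-weighted copy number
    as fractions shift 0.1 -> 0.9."""
    sim = SimConfig(genome_length=10_000, n_genes=10, coverage=100.0, seed=30)
    spec = TruthSpec(
        n_strains=2,
        fractions=[[0.1, 0.9], [0.9, 0.1]],
        snv_density=5.0,
        gene_copy={4: [4.0, 1.0]},
    )
    bundle = generate_community(sim, spec)
    result = gene_frequency(bundle.coverage, toi=["TP0", "TP1"])
    freq = result.frequencies.loc["gene0004"]
    assert freq["TP0"] == pytest.approx(0.1 * 4 + 0.9 * 1, rel=0.10)
    assert freq["TP1"] == pytest.approx(0.9 * 4 + 0.1 * 1, rel=0.10)
    assert "gene0004" in result.variable_genes


# ---------------------------------------------------------------------------
# report arithmetic
# ---------------------------------------------------------------------------


def test_percent_half_up():
    assert percent_half_up(190, 2182) == 9
    assert percent_half_up(22, 3851) == 1
    assert percent_half_up(1, 200) == 1  # 0.5 rounds up
    assert percent_half_up(0, 100) == 0
    assert percent_half_up(5, 0) == 0


def test_published_counts_reproduce_percentages():
    table = north_pond_sweep_counts()
    expected = {
        "NORP83": (2, 7, 15, 72),
        "NORP139": (2, 19, 38, 31),
        "NORP147": (0, 0, 0, 0),
        "NORP163": (9, 19, 6, 62),
        "NORP169": (8, 8, 8, 74),
        "NORP246": (1, 23, 14, 55),
    }
    for mag, row in table.iterrows():
        report = SweepReportRow.from_counts(
            mag, row.n_cds, row.n_low_pi, row.n_low_dnds, row.n_relaxed,
            row.n_no_dnds, row.longest_run,
            {1: row.fst_regions_1sd, 2: row.fst_regions_2sd},
        )
        assert (
            report.pct_low_pi, report.pct_low_dnds,
            report.pct_relaxed, report.pct_no_dnds,
        ) == expected[mag]


def test_summarize_sweep_report_from_calls():
    calls = [
        SweepCall("g1", {}, {}, tested=True, flagged=True, run_id=1),
        SweepCall("g2", {}, {}, tested=True, flagged=True, run_id=1),
        SweepCall("g3", {}, {}, tested=True, flagged=False),
        SweepCall("g4", {}, {}, tested=True, flagged=True, run_id=2),
    ]
    categories = {"g1": "below_genome_mean", "g2": "relaxed", "g4": "none"}
    row = summarize_sweep_report("m", calls, categories, {1: 2, 2: 0}, total_cds=4)
    assert row.n_low_pi == 3
    assert row.pct_low_pi == 75
    assert row.n_low_dnds == 1
    assert row.n_relaxed == 1
    assert row.n_no_dnds == 1
    assert row.longest_run == 2
    assert row.fst_regions == {1: 2, 2: 0}


def test_zero_flagged_gives_zero_percents():
    row = SweepReportRow.from_counts("m", 1000, 0, 0, 0, 0, 0, {1: 0, 2: 0})
    assert (row.pct_low_pi, row.pct_low_dnds, row.pct_relaxed, row.pct_no_dnds) == (
        0, 0, 0, 0,
    )
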