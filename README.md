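# aquiferpop

Population-genomic inference from metagenomic time series of
metagenome-assembled genomes (MAGs): focal-population selection from
abundance, SNV-level diversity, recombination signals, gene-specific sweep
and differentiation scans, gene copy-number variation, and pairwise codon
dN/dS — plus a ground-truthed synthetic strain-mixture community generator
used for validation.

## What it does

- **abundance_selection** — RPKM normalization; persistent-MAG criterion
  (≥5 RPKM in ≥3 samples) vs single-sample spike criterion (≥30 RPKM);
  time points of interest per MAG.
- **site_diversity** — SNV calling from per-site nucleotide counts
  (entropy > 0, coverage ≥ 20×, departure from consensus ≥ 10%); SNVs·kbp⁻¹;
  per-site/gene/genome nucleotide diversity π (unbiased two-read mismatch
  probability); major-allele-frequency matrices across time points with the
  fixed-at-consensus convention.
- **recombination_signals** — two-locus r² from read-linked SNV pairs,
  10-bp-binned decay curves split by mutation class (S-S / N-S / N-N),
  four-gamete test with H1–H4 frequency summaries.
- **sweep_and_content** — one-sided Welch scan for genes with reduced
  diversity in every time point of interest (BH-corrected); Hudson F_ST
  with five-gene sliding-window elevation calls at 1 and 2 SD; gene
  frequency (coverage / sample median) with the ≥1× change rule; per-MAG
  summary report arithmetic.
- **codon_selection** — haplotype QC (strand correction, internal-stop
  removal, 100 %-identity collapse) and Nei–Gojobori (1986) pairwise dN/dS
  with Jukes–Cantor correction and the dN > 0, 0.01 < dS < 1, dN/dS < 5
  retention filters.
- **synthetic_community** — strain mixtures (1–8 strains) over time with
  infinite-sites biallelic SNVs on a random strain tree, tunable
  distance-scaled recombination (the only source of four-gamete
  violations), per-strain gene presence/copy number, Poisson coverage,
  read-pair linkage, optional sequencing error; plus a constrained
  least-squares strain-fraction recovery estimator.
- **tables_io** — shared domain types, TSV/GFF3/FASTA readers and writers,
  bundle cross-validation, run configuration (all thresholds default to the
  published study values).
- **datasets** — the small published abundance and sweep-count tables used
  by the worked-example tests and the acceptance report.

All positions are 0-based half-open internally; 1-based in GFF3 and
human-facing reports.

## CLI

```sh
aquiferpop simulate --out bundle/ --seed 3 --n-strains 2 \
    --fractions "0.7,0.3;0.4,0.6" --snv-density 10
aquiferpop validate bundle/
aquiferpop abundance --rpkm rpkm.tsv --out selection.tsv
aquiferpop diversity --counts bundle/allele_counts.tsv --mag-length 20000 --out div.tsv
aquiferpop recombination --pairs bundle/linkage.tsv --genes bundle/genes.gff3 \
    --seqs bundle/contigs.fasta --out recomb/
aquiferpop sweeps --counts bundle/allele_counts.tsv --genes bundle/genes.gff3 \
    --toi TP0,TP1 --out sweeps.tsv
aquiferpop genefreq --coverage bundle/coverage.tsv --toi TP0,TP1 --out genefreq.tsv
aquiferpop dnds --haplotypes haps.fasta --genes bundle/genes.gff3 --out dnds.tsv
```

`simulate` writes a full plain-text input bundle (`allele_counts.tsv`,
`linkage.tsv`, `coverage.tsv`, `genes.gff3`, `contigs.fasta`) together with
a `truth.json` ground-truth file for test harnesses.

## Notes

- π is implemented as the probability that two reads drawn without
  replacement *differ* (the standard mismatch definition).
- dN/dS uses a counting estimator rather than the likelihood machinery used
  in the original study; it is exactly specifiable and verified against an
  independent pathway-enumeration implementation.
- The simulator is a stand-in, not a model of the field data: its job is to
  carry known, recoverable signals (mixture fractions, recombination,
  sweeps, copy number) into the exact table formats the pipeline consumes.
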