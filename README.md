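# ribevol

Cross-species translatome analysis: translational efficiency (TE) and its
between-species variance with resampling inference, species-specific
regulatory-mode classification (buffering / exclusive / intensified),
evolutionary age and de novo structure calls for genes and small ORFs from
homology evidence, tau tissue enrichment and Spearman co-regulation networks.
A synthetic-data package generates every input the pipeline consumes, with
recorded ground truth, so all of it is testable offline.

## Layout

| module | what it does |
| --- | --- |
| `ribevol.synthetic` | NB count simulator with a planted log2-TE variance decomposition, toy multi-species genomes with planted orthologous/young genes and intact/de-novo/orphan sORF counterparts, tissue atlas with planted specific genes |
| `ribevol.io` | TSV/FASTA/BED12/GTF/BLAST-tabular readers and writers, validation, flat config (all thresholds configurable, published values as defaults) |
| `ribevol.normalization` | median-of-ratios size factors (joint across species, per assay), CDS-length adjustment, FPKM |
| `ribevol.tevar` | TE per matched sample pair with the per-species zero-count filters; per-gene score `te_var = Var_species(mean TE) - mean(within-Var/n)`; whole-sample permutation p-values and downsampling CIs for gene-group medians |
| `ribevol.regulation` | DE significance rule (\|FC\| >= 1.5 and BH p < 0.05), stand-in DE engines (pluggable for external tables), mode and prenatal/postnatal classification |
| `ribevol.evoclass` | active-gene / replicated-ORF filters, in-frame ORF collapse (>= 90% shared positions, AUG-then-longest representative), homology resolution from mapping + BLAST evidence, age calls (species-specific / hominini-specific / preserved), intact-fraction walk and de novo / intact / orphan structure calls |
| `ribevol.enrichment` | tau index, recent tissue-enrichment calls, co-regulation edges at \|rho\| > 0.5 |
| `ribevol.pipeline` | end-to-end driver joining homology evidence to age/structure calls |

## CLI

```bash
ribevol simulate --outdir sim/ --seed 1            # paired RNA/Ribo counts + truth
ribevol validate sim/                              # parse + validate a directory
ribevol normalize --counts sim/rna_counts.tsv --outdir norm/
ribevol tevar --counts-rna sim/rna_counts.tsv --counts-ribo sim/ribo_counts.tsv \
    --samples sim/samples.tsv --groups groups.json --iterations 10000 \
    --seed 1 --outdir tevar/
ribevol regulation --rna-de rna.tsv --ribo-de ribo.tsv --te-de te.tsv \
    --focal-species human --out modes.tsv
ribevol simulate-genomes --outdir toy/ --seed 1    # toy genomes + evidence tables
ribevol evoclass --genomes toy/ --out calls.tsv    # age + structure calls
ribevol enrichment --atlas atlas.tsv --out tau.tsv
```

DE tables are plain TSV (`feature_id`, `log2_fold_change`, `adjusted_p`), so
externally produced tables (e.g., from a DESeq2 run) drop in wherever the
built-in stand-in tests are used.

## Conventions

* All genomic intervals are 0-based half-open internally; GTF is converted at
  the boundary, BED12 is native. Minus-strand sequence extraction
  reverse-complements.
* The negative binomial is parameterized by mean and dispersion with
  `variance = mu + mu^2 / dispersion`.
* `te_var` may be negative (subtraction estimator; clamping would bias group
  medians). The decomposition identity holds exactly for every reported row.
* Permutations reassign whole samples to species, preserving per-species
  sample counts and gene-gene correlation; one-sided p-values count strictly
  greater permuted medians (resolution floor `1/iterations`).
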