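# asrkit

Genome annotations are the only practical substrate for comparing
alternative-splicing complexity across hundreds of species — but they are
also a biased one: annotation pipelines report more isoforms for genomes
with richer experimental evidence. `asrkit` is a toolkit for researchers in
comparative transcriptomics that

1. computes the **alternative splicing ratio (ASR)** of a genome from its
   GFF3 or GTF annotation,
2. quantifies how 23 annotation-quality metrics (assembly contiguity,
   evidence volume, CDS support classes) associate with ASR, and
3. corrects the dominant bias — the percentage of CDSs fully supported by
   experimental evidence — producing the normalized metric **ASR\***.

## The metrics

For a gene with isoforms *T₁ … T_k* whose coding segments (CDS) cover a
genomic footprint *U* (the union of all CDS intervals),

```
ASR = ( Σᵢ coding_length(Tᵢ) ) / |U|        (ASR ≥ 1)
```

A single-isoform gene has ASR = 1; higher values mean greater reuse of
coding DNA across isoforms. At the genome level, per-gene numerators and
denominators are summed before dividing.

Because observed ASR tracks the fraction *x* ∈ [0, 1] of fully supported
CDSs, a fourth-degree polynomial expectation is fitted,

```
ASR_exp(x) = β₀ + β₁x + β₂x² + β₃x³ + β₄x⁴
```

and the bias-corrected metric is

```
ASR* = ASR_obs − ASR_exp(x) + σ_min ,   σ_min = 1 − minᵢ(ASR_obsᵢ − ASR_expᵢ)
```

so the smallest training-set ASR\* is exactly 1. Predictor relevance is
established with Spearman correlation matrices and LASSO regression
(seeded 80/20 train/test split, penalty chosen by 10-fold cross-validated
MSE).

## Worked example

The packaged toy gene (33 bp, three isoforms of coding lengths 16, 9 and
19 bp sharing a 25-bp coding footprint) gives ASR = (16+9+19)/25:

```sh
$ asrkit compute-asr --gff src/asrkit/data/toy_gene.gff3 --out toy
genome ASR = 1.76 (1 genes, 3 transcripts)
```

`toy.per_gene.tsv` lists the bookkeeping per gene
(`toy_gene  3  44  25  1.76`: 3 isoforms, 44 bp of summed coding length
over a 25-bp footprint), and `toy.genome.json` the genome-level summary.

A full synthetic analysis — simulate a 670-species panel, correlate,
select predictors, fit the quartic, normalize — runs in a few seconds:

```sh
$ asrkit run-pipeline --simulate --seed 3 --out run/panel
```

The printed summary for this seed includes
`"rho_asr_support_pct": 0.680` (the support–ASR association before
correction), `"fit_r2": 0.606` (variance explained by the quartic),
`"lasso_selected": ["cds_fully_supported_pct", "cds_from_model_pct"]`,
and an evaluation block with `"rho_asr_star_x": -0.0013` and
`"min_asr_star": 1.0` — i.e. after normalization the support correlation
is gone and the metric is anchored at 1.

Other subcommands: `simulate-gff`, `simulate-table`, `parse-report`,
`filter-assemblies`, `join`, `correlate`, `lasso`, `normalize`,
`evaluate`. See `docs/methods.md` for the model and its assumptions.

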