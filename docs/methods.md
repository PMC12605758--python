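# Methods

## The alternative splicing ratio

The ASR of a gene is the cumulative coding length of its transcript
isoforms divided by the size of its genomic coding footprint. Coordinates
are 1-based inclusive throughout (the GFF convention), so a segment's
length is `end − start + 1`; no half-open conversion is exposed. The
footprint is the union of all CDS intervals of all isoforms, computed
seqid-aware by sort-and-merge; strand is ignored because lengths are
strand-symmetric (a warning is emitted if one transcript mixes strands).
Every footprint base is covered by at least one isoform, so per-gene
ASR ≥ 1, with equality exactly for single-isoform genes (or identical
duplicated structures).

**Genome-level aggregation.** Genome ASR is defined as
Σ per-gene numerators / Σ per-gene denominators, each gene's footprint
counted within that gene. This is robust to overlapping genes (a base
shared by two genes counts once per gene, consistent with the per-gene
definition) and makes the genome value a coding-length-weighted summary.
The unweighted mean of per-gene ratios is exposed as `mean_gene_asr` for
users who prefer an equal-weight summary; the aggregate ratio is the
default everywhere.

**Parsing rules.** GFF3 files are resolved through the
gene → mRNA → CDS chain via `ID`/`Parent` attributes, in three passes so
record order never matters. Pseudogenes (feature type or biotype),
user-excluded genes, duplicate gene ids and genes whose transcripts all
lack CDS are excluded; every excluded or unresolvable record increments
a reason-keyed counter (`skipped_records`) rather than vanishing. A CDS
row listing several parents is attached to each (RefSeq semantics); CDS
rows sharing an ID are parts of one transcript's CDS and are summed.
GTF files (StringTie-style) are grouped by `gene_id`/`transcript_id`;
transcripts with CDS rows use them, transcripts with only exon rows use
exons as the splicing unit and the annotation set is flagged
accordingly — empirical long-read GTFs rarely carry CDS features, and
exon-level reuse is the analogous quantity there. No duplication
detection from sequence is attempted: only explicitly marked records are
excluded, plus an optional user-supplied exclusion list.

## Annotation metadata

Twenty-three metrics per species, in three blocks: assembly contiguity
(gap count/length/percent, scaffold and contig counts and N50s, all
lengths in bp), evidence volume (Entrez protein/transcript counts,
human-derived counts, RNA-seq reads, tissues, runs) and the CDS output
(total, model-derived, fully supported, known, >5% ab initio, as counts
and percentages of the total). Reports are parsed from key/value or
one-row-TSV files against a documented alias table; there is no single
published schema for these report files, so the canonical key set here
is the package's own, with NCBI-style phrasings accepted as aliases.
Missing metrics stay missing — never imputed — and any record with a
missing predictor is dropped listwise from correlation and LASSO.
Percentages reported inconsistently with their counts (beyond 0.5
points, the rounding tolerance) raise a warning. Derived percentages
(100·count/total) fill gaps but never overwrite reported values, making
the operation idempotent. Taxon groups are assigned only from an
explicit user-supplied mapping; no taxonomy inference is performed.

## Statistics

**Spearman matrices** use average-rank ties and asymptotic P-values,
starred at P < .05 (\*) and P < .001 (\*\*). Raw P-values are reported
by default; Benjamini–Hochberg adjustment is available as an option.
Pairs involving a constant variable are reported as missing with a
warning.

**LASSO selection** standardizes predictors to zero mean and unit
variance on the training split (coefficient magnitudes are then
comparable as importances), splits 80/20 with a seeded shuffle, and
picks the penalty minimizing 10-fold cross-validated MSE — not the
1-standard-error rule, which favors sparser but worse-MSE models.
Held-out R² is computed on the untouched 20%. The full coefficient path
is retained; at the largest penalty of the grid every slope is exactly
zero by construction of the path.

**Quartic expectation and ASR\*.** The support fraction is used as
x ∈ [0, 1] internally (inputs carry the percentage; the conversion is
one division) because a quartic in raw percentages spans eight orders of
magnitude across its monomials and is numerically ill-conditioned. The
fit runs on numpy's shifted-and-scaled polynomial basis and is reported
on both bases; predictions are basis-independent, raw-basis β₀…β₄ are
the interpretable form. Printed coefficient tables from orthogonal-basis
fits (recognizable by identical standard errors across degrees) are not
comparable to raw-basis β, which is why the package reports both and
treats predictions, not coefficients, as the exchangeable quantity.
Requirements: n ≥ degree + 2 and non-constant x; r² is defined as 0 for
a constant response. σ_min is computed with the same raw-basis
evaluation used for later normalization, so the training-set minimum of
ASR\* equals 1 to within one floating-point rounding (≪ 1e−12) by
construction. Species outside the training set may fall below 1; they
are flagged, never clipped, since clipping would destroy the fixed-x
rank-preservation property (within any fixed-x stratum, ASR\*
differences equal ASR differences exactly).

## Synthetic data

The gene-model generator lays out, per gene, 2–8 exons of 30–300 bp
separated by 20–500 bp introns; the first isoform contains every exon
and each additional isoform keeps each exon independently with
probability 0.7 (at least one). Isoform counts follow a truncated
geometric distribution (p = 0.45, max 8, mean ≈ 2.2 isoforms/gene,
a plausible vertebrate-like annotation density). Because the primary
isoform spans the full exon set, numerator > denominator whenever a gene
has more than one isoform. The generator keeps its own position-set
bookkeeping of each gene's numerator and denominator; this truth table
is an oracle independent of the parser and must be reproduced with
exact integer equality.

The dropout operation (`degrade_annotation`) retains each non-primary
isoform with probability equal to an evidence-support fraction — the
simplest mechanism producing the observed positive support–ASR
association. It is a stand-in for how evidence thresholds shape
annotation pipelines, not a claim about any pipeline's internals.

The species-panel generator draws x ~ Uniform(0, 1) (a symmetric Beta is
available), sets ASR = q(x) + ε with q the quartic
β = (1.2, 0.4, 1.5, 0.8, 1.4) — rising from 1.2 at zero support to 5.3
at full support with mean ≈ 2.4, the magnitude range seen across
EGAP-annotated eukaryotes — and ε ~ Normal(0, σ), flooring at 1 since
ASR < 1 is impossible by construction of the metric. The default σ is
calibrated in closed form (exact uniform moments of the quartic) so the
population R² of the trend is 0.6, matching the explanatory power the
quartic model typically achieves on real panels. With these defaults
about 15–18% of species are floored at 1 near x = 0; the fitted r²
nevertheless stays within [0.5, 0.7] across seeds. Remaining metadata
fields are filled with mutually consistent placeholder counts so the
full 23-metric pipeline runs end to end.

**What passing tests do and do not show.** The panel generator
reproduces the *assumed* statistical structure — a smooth quartic trend,
homoscedastic noise, independent species. Real cross-species panels have
heteroscedastic scatter (tight at low support), phylogenetic
non-independence, and metadata that correlate with each other and with
x. Passing the decorrelation and recovery tests therefore demonstrates
correctness of the machinery, not that a real panel's bias is fully
captured by a quartic in one variable.

## Problem sizes and runtime

Tests and the acceptance script run on desk-scale inputs chosen to
exercise every code path well inside a minute each: 670-species panels
(matching the record count of a realistic cross-species analysis),
simulated annotations of 10–60 genes, 200-species dropout panels, and
1000 randomized interval sets of up to 50 intervals for the union
oracle. All stochastic operations take explicit seeds and are
deterministic given the seed.

## Known limitations

- Genome ASR treats each gene's footprint independently; a global
  genome-wide union (shared bases across overlapping genes counted once)
  would give slightly different values for dense genomes and is not
  implemented.
- No sequence-level validation: FASTA is never read, splice sites are
  not checked, and aligners/assemblers are not invoked — the package
  consumes their GTF output only.
- The normalization is empirical: ASR\* values are representative
  estimates conditioned on one annotation pipeline's support metric, not
  precise measurements of splicing complexity.
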