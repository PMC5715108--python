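# Methods

`butycore` quantifies the butyrate-producing guild of the human colonic
microbiota from gene-level read counts. This note records the models
and procedures implemented, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
and design choices made where the workflow left room for them.

## Pathway model

Four butyrate-synthesis routes are modelled, each as a fixed gene
roster (`butycore.pathways`):

| pathway | core genes | terminal genes | quantification genes | aggregation |
|---|---|---|---|---|
| acetyl-CoA (Ac) | thl, bhbd, cro, bcd, etfA, etfB | but, buk | thl, bhbd, cro | mean |
| glutarate (Gl) | gctA, gctB, hgCoAdA/B/C, gcdA, gcdB | — | core minus gcdB | mean |
| 4-aminobutyrate (4A) | abfH, abfD | 4hbt | abfH, abfD | median |
| lysine (Ly) | kamA, kamD, kamE, kdd, kce, kal | atoA, atoD | all core | mean |

Terminal genes and the bcd–etfAB complex are never used for
quantification: the complex takes part in all pathways and cannot be
attributed to one of them. gcdB is excluded from Gl quantification
because the gene family recruits many false-positive reads; the 4A
pathway is aggregated by median because abfD recruits
disproportionately many reads. Housekeeping genes rplB, recA and pyrG
are treated as universal and single-copy; the mean of their
length-corrected counts proxies total bacterial abundance and is the
denominator of every abundance.

## Genome genotyping

Input is an annotation table of gene hits (genome, taxon bin, gene
symbol, locus ordinal, model-similarity score, reference flag).

**Score cutoff.** Per gene, hits are sorted by score and a low-score
cutoff is placed at the dominant score drop at or below the
lowest-scoring reference. "Dominant drop" is operationalized
deterministically: among consecutive gaps whose upper score is at or
below the lowest reference score and within `window` (default 0.5) of
it, a gap qualifies when it is at least `gap_factor` (default 2.0)
times the median consecutive gap **and** at least `min_drop` (default
0.25) of the lowest reference score. The second condition is needed
because order statistics of genuinely homologous scores always contain
an outlier gap relative to the median; a real drop is also large on
the score scale itself. With no qualifying drop the cutoff falls back
to the lowest reference score. Both thresholds are configurable; the
manual inspection they replace has no recoverable exact value.

**Synteny filters.** For multi-copy genes, a copy is syntenic when
within 10 locus ordinals (same contig) of another gene of the same
pathway; non-syntenic copies are dropped only when a syntenic copy
with a higher score exists. etfA/etfB are kept only when syntenic with
a retained bcd, marking the electron-bifurcating butyryl-CoA
dehydrogenase complex. The filter is idempotent.

**Pathway call.** A pathway is present when at most one core gene is
missing. For Ac, thl is never counted as missing (alternative routes
form acetoacetyl-CoA), and a genome missing one counted core gene must
carry but or buk. Ac-positive genomes lacking both terminal enzymes
are retained and classified "alternative"; the monotonicity property
(adding a gene never revokes a call) holds by construction.

**Per-taxon aggregation.** A taxon is credited with a pathway when any
of its genomes carries it. The genes used to *quantify* the taxon are
the union over its pathway-positive genomes; the genes *required* for
sample-level detection are the intersection, so a gene absent from
some reference genomes of a taxon is not demanded in samples. The two
sets coincide for genomically homogeneous taxa, which is the case for
all synthetic fixtures.

## Gene catalogue

Construction order is fixed and part of the contract: dereplicate →
length filter (≥ 70% of the median reference length per gene) →
complete-linkage clustering at 95% nucleotide identity → annotation.
Reordering changes cluster membership because truncated sequences
distort linkage.

Clustering is agglomerative with the complete-linkage criterion:
clusters merge only while *every* cross-pair identity stays at or
above the threshold, so every final cluster has minimum internal
identity ≥ 0.95. At each step the pair with the highest
complete-linkage identity merges; ties break lexicographically on the
smallest member id, making the output independent of input order. The
O(n³) implementation is deliberate — catalogue pools are per-gene and
small, and determinism and auditability outweigh speed here.

Pairwise identity defaults to matches over the longer sequence length
(exact `1 − Hamming/length` for the indel-free synthetic sequences;
truncation is penalized). The identity function is a hook
(`identity_fn`) so a gapped aligner can be swapped in for real data,
where identity computed on HMM-guided alignments may move borderline
clusters.

Clusters containing no reference sequence are annotated against the
references of their gene: accepted when cluster multiplicity ≥ 3 and
alignment coverage ≥ 0.80, with an additional ≥ 0.75 identity
requirement for but/buk (these families have close non-producer
homologs). Accepted representatives merge with the dereplicated
references; decoy entries (paralogs and homologs from non-producer
lineages) are carried in the catalogue solely so reads hitting them
can be discarded. Chimera removal and frameshift correction are
explicit no-op pass-throughs with warnings: both need dedicated
external tools and are out of scope.

## Quantification

For one sample: decoy-hit counts are removed (and logged); counts are
pooled per (taxon bin, gene symbol) — raw counts are summed *before*
length correction; pooled counts are divided by the median reference
length of the gene; the housekeeping denominator is the arithmetic
mean of the three genes' corrected totals (a missing gene contributes
0 with a warning; all three missing flags the sample unquantifiable).

* Pathway abundance: aggregate of the quantification genes' corrected
  totals (genes with no reads enter as 0) over the denominator, ×100.
* Taxon presence: every required gene (minus the global exemptions
  gctA, atoA, atoD, kal, which are unreliable detectors) must have at
  least `min_reads` (default 1) raw reads; low-depth metatranscriptome
  mode (`data_mode="metatranscriptome_lowdepth"`) tolerates one
  missing gene. The same code path serves metatranscriptomes, with
  housekeeping expression as the reference.
* Taxon abundance: median of the taxon's quantification-gene corrected
  counts over the denominator, ×100. Present taxa with zero median are
  reported at their computed value, never imputed.
* Enzyme groups: Ac-taxon abundances summed by terminal class; taxa
  carrying both but and buk are split proportionally to the two genes'
  corrected counts (50/50 with a warning when both are zero). Group
  sums equal the taxon-abundance sum identically.
* Family groups: sums over Lachnospiraceae, Ruminococcaceae,
  Porphyromonadaceae and "others"; same conservation identity.
* Taxon linkage: share of quantification-gene reads attributable to a
  present taxon (abfD excluded for 4A).

All abundances are invariant to scaling every raw count by a constant.

## Ecology statistics

Bray–Curtis dissimilarity is computed on square-root-transformed
abundances; an all-zero pair is defined as 1 with a warning. Community
types come from complete-linkage clustering of that matrix with the
cluster count chosen by silhouette maximum over 2–10 when not fixed.
PERMANOVA uses the standard pseudo-F on squared dissimilarities with a
permutation P-value `(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`; it is
implemented in-package so the random generator is explicit and
seedable, and is cross-checked against an independent implementation
in the tests.

Co-occurrence networks: per dataset, taxa present in > 50% of samples
are tested pairwise by Spearman correlation; a pair qualifies at
P < 0.05, Benjamini–Hochberg Q < 0.05 (within dataset) and ρ > 0.4;
an edge requires qualification in ≥ 3 datasets. The ρ boundary is
strict (>) with the threshold configurable, and FDR is computed per
dataset — both points the source workflow leaves ambiguous. Edges are
invariant to dataset and taxon ordering.

Group comparisons: pathway totals are tested with a two-group linear
model (equivalent to the pooled t-test), returning the absolute
difference, its SE and P; taxa, enzyme groups and family groups with
pooled prevalence ≥ 25% are tested by Mann–Whitney U with BH-FDR
across features. Relative differences are percentages of the control
mean (undefined, with warning, when that mean is zero). The Q
procedure is a hook with BH as default. Meta-analysis pools absolute
differences by fixed-effect inverse variance — the pooling rule is
this package's choice — and re-expresses the pooled difference
against the inverse-variance-weighted control mean.

## Stability statistics

Per subject, signed per-taxon changes (percentage points of total
bacteria) are computed between the first time point and every later
one; taxa at zero in both time points of a pair are excluded,
mirroring the tied-zero convention of paired tests. Statistics per
record: the fraction of taxa strictly decreasing (zero counts as
non-decrease); the absolute change |Σ changes| versus the total change
Σ|changes|, equal exactly when all non-zero changes share a sign, and
their ratio (undefined at total 0). The random baseline draws, per
repeat, 1000 integers uniformly from −100..100 inclusive (expected
fraction negative 100/201 ≈ 49.75%). The variance test compares
squared deviations of observed fractions from 50 against baseline
deviations with a two-sample t test; squared deviation is the default
with absolute deviation available (`deviation="abs"`), the statistic
being ambiguous between the two.

## Synthetic-data generator

The generator (`butycore.synth`) emulates the study conditions the
pipeline targets, with ground truth serialized beside every output.

* **Communities**: 20 producer taxa by default carrying the Ac pathway
  with lognormal abundances summing to 0.30 of the community; the
  remaining 0.70 is background carrying only housekeeping genes —
  matching a gut community where roughly a quarter to a third of
  bacteria are butyrate producers. Protein-fed pathways are added per
  taxon with probabilities 0.15 (Gl), 0.12 (4A), 0.20 (Ly), yielding
  the few-taxon protein-fed communities seen in real cohorts. Terminal
  classes default to but-dominant frequencies (but 0.60, buk 0.15,
  both 0.15, alternative 0.10) and families to Lachnospiraceae 0.45 /
  Ruminococcaceae 0.35 / Porphyromonadaceae 0.10 / others 0.10,
  the qualitative composition of healthy adult cohorts.
* **Counts** are multinomial over all (taxon, gene) cells with
  expected reads proportional to abundance × gene length × copy
  number, at a configurable depth. No noise model is stated for the
  real data, so none is default; gamma-perturbed weights
  (`dispersion`) give negative-binomial-like overdispersion when
  wanted. `expected_pathway_se` returns the delta-method standard
  error of the estimated pathway abundance under this model — the
  estimator is a ratio of linear combinations of multinomial counts,
  and its correct sampling SE is roughly twice the naive
  `sqrt(p(1−p)/depth)`; recovery tests use the analytic SE.
* **Sequences** mutate under uniform substitution with no indels, so
  identity is exactly `1 − Hamming/length` and the clustering oracle
  is exact. "Within-cluster divergence" w is a guaranteed *pairwise*
  bound: each member carries exactly `round(w/2 × L)` substitutions
  from its taxon ancestor, so pairwise within-taxon divergence never
  exceeds w and cross-taxon divergence never falls below
  `between − w`. Taxon ancestors are redrawn until all pairs are
  separated by at least the between rate.
* **Designs**: longitudinal series shift each taxon by
  ±`magnitude` (sign negative with probability `concordance`), clip at
  zero (flagged) and renormalize; case/control designs jitter
  abundances lognormally (σ = 0.25) and scale the targeted pathway's
  taxa by (1 + effect) in cases — renormalization compresses the
  realized relative difference below the planted one (a −30% planted
  effect on a 30%-abundant pathway realizes ≈ −23%), which is a
  property of compositional data, not an estimator bias. Correlated
  taxon tables use a Gaussian copula with latent correlation
  `2·sin(πρ/6)` so the population Spearman correlation equals ρ.

What the generator does **not** emulate: sequencing error and quality
scores, read-length variation, indels, chimeras, strain-level
heterogeneity within a taxon bin, copy-number variation of
housekeeping genes, and compositional correlations between taxa
beyond those explicitly planted. Passing recovery tests therefore
demonstrates correctness of the estimators under proportional
sampling, not robustness to mapping error or assembly artifacts.

## Problem sizes and reproducibility

Tests and the acceptance script use 20-taxon communities, cohorts of
20 samples or seeds, depth 10⁶ for recovery checks and 10⁴–10⁵
otherwise, 8 datasets × 100 samples for networks, and n = 50/50 for
case/control recovery — sizes at which every statistic's sampling
error is small against its acceptance band while a full run stays in
the tens of seconds. Every random draw flows from an explicit seed
(the pipeline derives per-stage seeds by fixed offsets); a fixed
configuration reproduces all outputs byte-identically.

## Known limitations

* The score-drop detector is a deterministic stand-in for a manual
  inspection; its `gap_factor`/`min_drop` defaults were chosen for
  well-separated score bands and may need tuning for real HMM scores.
* The toy k-mer read mapper exists to close the loop on simulated
  reads; it is not a substitute for a real mapper on real data.
* With only two quantification genes, the 4A median equals their mean;
  the distinction matters only if a third gene is added.
* Meta-analysis assumes fixed effects; heterogeneous cohorts would
  warrant a random-effects extension.
* The variance-ratio interpretation of stability ("x-fold higher than
  random") is reported as a plain ratio; its interpretation is left to
  the user.
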