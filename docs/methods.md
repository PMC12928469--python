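# Methods

`pathsim` is a simulation laboratory for asking how the *structure* of a
complex-trait disease shapes how predictable it is from genotype. It couples
abstract pathway-threshold disease models with a calibrated synthetic
genotype generator, a marginal-preserving population expander, a standard
case/control classifier panel, and weight-space introspection of the neural
network. This note records the models, the generator, the numerical choices,
and what the package's tests do and do not demonstrate.

## Disease models

An individual is a vector of risk-allele doses, one value in {0, 1, 2} per
locus (homozygous wild type / heterozygous / homozygous risk; for loci where
the variant is protective the wild-type allele is relabelled as the risk
allele, so higher dose always means higher risk). A model partitions (or
covers) the loci with P pathways of R loci each and applies two strict
thresholds:

- pathway i malfunctions iff its burden `Re_i = sum_j w_j * dose_j`
  strictly exceeds `mg`;
- the individual is a Case iff the (weighted) count of malfunctioning
  pathways strictly exceeds `mp`.

Thresholding makes the genotype-phenotype map non-additive: doses beyond a
pathway's failure point contribute nothing, and the pathway count introduces
a second non-additive layer. Four architectures are provided, with the stock
parameterizations used throughout the experiments:

| name | structure | parameters |
|---|---|---|
| `simple-default` | 8 disjoint pathways x 6 loci, unit weights | mg=5, mp=4 |
| `simple-low-prevalence` | same | mg=5, mp=5 |
| `weighted-default` | 2 high-risk (w=5) + 4 low-risk (w=2.5) loci per pathway; 3 central (w=5) + 5 peripheral (w=2.2) pathways | mg=20, mp=11 |
| `overlap-default` | 8 pathways x 7 loci in 4 pairs, each pair sharing its 2 lowest-index loci (48 distinct loci); shared doses count in both burdens | mg=5, mp=6 |
| `overlap-low-prevalence` | same | mg=6, mp=5 |
| `subtype-default` | two disjoint 24-locus Simple sub-diseases (P=4, R=6, mg=5, mp=2), Case if either fires | — |
| `single-subtype` | the first sub-disease alone | — |

The subtype sub-model thresholds deserve a note: the threshold pair is only
feasible in the ordering used here — a pathway-count threshold of 5 can
never be strictly exceeded by 4 pathways — so mg=5, mp=2 is the default and
both orderings remain constructible.

All weights are positive and all thresholds strict, so raising any single
dose can never turn a Case into a Control; this monotonicity is enforced by
randomized property tests and by exhaustive enumeration against a literal
formula evaluator for every variant at small L.

**In-model prevalence** is the fraction of the core Case matrix a model
classifies as Case — a proxy for how hard it is to *be* a Case under that
architecture. Burdens are integers, so the (mg, mp) grid is effectively
integer-valued; for the Simple 8x6 architecture on the calibrated core the
reachable prevalences near the common-disease range jump in large steps:
the common-disease default (5, 4) measures near 50% on the calibrated core
and the next grid point (5, 5) near 24%. That rare-vs-common contrast
drives the prevalence experiments.

## Synthetic core data

The generator emulates the statistical profile of a 48-locus case/control
panel: 3004 cases with mean risk-allele load 46.5 and 1949 controls with
mean load 43.5 (about a 7% difference). Per-locus risk-allele frequencies
are drawn once from a Beta distribution centred on the load-implied midpoint
frequency with standard deviation 0.12 (`frequency_dispersion`; this spans
roughly 0.2–0.75, a realistic spread for common GWAS risk alleles), then
shifted additively so each group's expected load matches its target
*exactly*. Both groups share one heterogeneity draw when seeded alike, so
the case/control difference at every locus is the same small uniform shift
(3/96 ≈ 0.031): no single locus separates the classes, as in real data.
Genotypes are Hardy–Weinberg doses, Binomial(2, p_j), independent across
loci and individuals.

What this emulates: the printed load targets, the dose-histogram shape
(controls have more 0s, cases more 2s), frequency heterogeneity. What it
does not: the true per-locus frequencies of any real panel, linkage
disequilibrium, locus-specific effect sizes, population structure. Passing
tests therefore demonstrate properties of the *method* under a clean,
independent-locus regime, not performance on real GWAS data.

A nearest-neighbour imputation routine reproduces the pre-processing applied
to the original panel: each missing dose is copied from the closest same-class
row by Hamming distance over mutually observed loci (ties broken by lowest
row index; if the closest donor is also missing there, the next-closest is
consulted, and so on).

## Rectangle-shuffle population expansion

A rectangle swap exchanges two values held in crossed positions by two rows,
preserving every row and column sum of the integer matrix exactly. One epoch
performs `ceil(N*M*ln(N*M))` accepted swaps (uniformly proposed; invalid
proposals are resampled and not counted; natural log), enough to decorrelate
the arrangement from its origin.

Expansion manufactures a population consistent with a disease model: after
each epoch, rows that classify as the target status are **moved** from the
working matrix into the output pool and the remainder is shuffled again.
Moving rather than copying means nearly every core individual is placed
exactly once per pass, so the pooled load distribution tracks the core's
(measured: expanded Case mean load 46.7–46.8 against the 46.5 core target) —
and it explains why production gets harder as the pool fills: the stragglers
are rows whose loads rarely realize the target phenotype. When rectangle
production dries up (10 consecutive empty epochs, or acceptance below 0.5%
once 80% of the pass target is pooled — late epochs run on small remainder
matrices and are cheap, so patience is generous), the pass falls back to
independent within-row value permutation under the same accept/reject rule,
which preserves each row's load but lets column counts drift. Targets larger
than the core are met by repeated passes from fresh core copies, so sizes above
100% are concatenations of independently simulated sets (100% = 3004 Case
+ 1949 Control, 200% = two such sets, ...).

A caveat measured on the synthetic core: a small residue of extreme-load
rows has per-arrangement acceptance probability near zero, so the fallback
stage engages for the final sliver
of essentially every full-size expansion; those rows are eventually
abandoned and replaced by extra-pass rows. Every emitted row is verified to
hold the target status (status purity is asserted exhaustively in tests).

## Classifier panel and evaluation

Gaussian naive Bayes, logistic regression, decision tree and random forest
at scikit-learn defaults (RF: 100 trees), plus the reference network:
one hidden layer of 25 sigmoid units, fully connected, trained by
constant-rate SGD (learning rate 0.3, momentum 0.2, up to 500 epochs,
standardized inputs, scikit-learn's default mini-batch of min(200, n)).
Evaluation is a stratified 2/3–1/3 holdout per replicate; the experimental
protocol defines separate train and test sets, and a holdout (rather than
cross-validation) is required for the mislabeling experiment, whose label
flips must touch the training partition only. AUC is computed from
continuous class scores by the Mann–Whitney rank statistic and is checked in
tests against brute-force case/control pair counting. Model comparisons use
a one-tailed two-sample Welch t-test across replicates (unequal variances
assumed — the safer default when none is stated).

Every stage draws its randomness from seeds spawned deterministically from a
master seed (`numpy` `SeedSequence`), so experiment results are bitwise
reproducible; the CLI echoes resolved configuration and seeds to a manifest.

## Perturbations

- `drop_features`: removes a uniformly random `floor(f*L)` column subset
  from the feature view; status was fixed by the full genotype, labels are
  untouched.
- `add_features`: appends `floor(f*L)` columns drawn i.i.d. from the pooled
  empirical {0,1,2} distribution, independent of labels.
- `mislabel_cases`: flips exactly `round(f * n_training_cases)` training
  Case labels to Control (round-half-up); Controls and test labels are never
  touched. Only this direction is studied; the reverse flip is available but
  not part of the replicated experiments.

## Introspection

The trained network's input-to-hidden weight matrix (48 x 25) is tabulated
row-per-locus and embedded in the plane with t-SNE (perplexity 8 for L=48 —
small enough for ~6-locus pathway clusters to act as neighbourhoods, and
well under the L/3 feasibility bound; PCA initialization; fixed seed makes
the embedding deterministic). **Pathway purity** — the mean fraction of a
locus's k nearest neighbours (k=5, one less than the pathway size) sharing a
pathway label, with overlap loci matching on either label — quantifies the
clustering the embeddings show. Purity is computed on the raw weight table
by default, which removes t-SNE stochasticity from the quantitative claim;
the embedding is for visualization. Chance level for 8 equally filled
pathways is ~1/8. Surplus (noise) features are annotated `none`.

## Problem sizes used by the test suite and acceptance script

One CPU is assumed throughout. The acceptance script
(`scripts/acceptance.py`) keeps the full population sizes (3004/1949
core; 100–400% expansions) and averages 5 seeded replicates for the ML
quantities (the full design uses 20) and 10 generator seeds for prevalence. The
pytest acceptance layer runs full-size populations wherever an absolute
value or a size-sensitive ordering is asserted (single-subtype AUC,
mislabeling, classifier-panel ordering at 100–300%, expansion load tracking,
prevalence, calibration), a half-size core (1502/975) for the subtype ladder
and the introspection size/AUC ladder (whose purity is measured on the
embedding, matching the visual claim), and a small core (360/240) for the
20-replicate Welch directionality comparisons, whose effects are
size-stable.

## Known limitations

- Loci are unlinked and exchangeable within a pathway; no LD, dominance,
  two-allele phasing, environmental terms or population structure.
- The fallback stage of expansion lets column marginals drift for the last
  ~20% of a pass, and a small residue of extreme-load rows is never placed.
- The neural network approximates the reference configuration (online
  backpropagation in the original toolkit) with mini-batch SGD; absolute
  AUCs are sensitive to this optimizer detail even though orderings are
  stable.
- The prevalence of a model is measured on the synthetic core, so it
  inherits the generator's dispersion choice; values for real panels would
  differ.
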