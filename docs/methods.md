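# Methods

## Model and procedure

The toolkit models miRNA-guided target recruitment observed by RIP-Chip
as a per-gene scoring problem.  Each gene receives 19 variables built
from (i) predicted miRNA binding sites in its 3'UTR and coding region,
(ii) the miRNA expression profile of the input (IN) sample, and
(iii) its own mRNA expression — all combinations of the site-count
matrix BS (or the per-base density dBS), the miRNA weights
e<sub>i</sub> and the mRNA level g<sub>j</sub>, plus the raw expression
(F9) and region lengths (L1, L2).  Genes enriched (UP) or
underrepresented (LOW) in the immunoprecipitated (IP) versus unbound
(FT) fraction define the classes; a variable's explanatory power is its
ROC-AUC for UP vs LOW.

### Seed matching

Binding sites are exact Watson–Crick matches to the reverse complement
of a miRNA seed.  Supported seed definitions: 6mer (mature positions
2–7), 7mer-m8 (2–8, the default), and 8mer (2–8 plus a target adenine
opposite position 1, implemented by prepending T to the stored seed so
the site string ends in A).  Every start position is tested
independently, so overlapping occurrences each count once; N never
matches.  This is a deliberately minimal, fully reproducible site
model: it ignores context scores, site accessibility, pairing energy
and conservation, all of which external predictors add.  When several
sequences exist per gene and region the longest is kept (ties broken by
record identifier); sequences under 50 nt are discarded, and the gene
universe is restricted to genes with both regions.

### Expression handling

Intensities stay on the **linear** scale inside the variable formulas —
this is what lets a single dominant miRNA (60% of the profile mass in
the emulated data) dominate the expression-weighted sums, which is the
phenomenon the shuffling analysis probes.  log2(x+1) is applied only
inside sample clustering, where correlation structure matters more than
absolute intensity.  Quantile normalization forces all samples onto the
per-rank mean distribution (stable-sort tie handling makes it
idempotent); replicate averaging is a plain feature-wise mean;
clustering is average-linkage on 1 − Pearson r.

### Enrichment calls (SAM-style)

For gene g: d = (mean<sub>IP</sub> − mean<sub>FT</sub>) / (s + s₀),
with s the pooled standard error and s₀ a fudge constant that damps
low-variance genes.  s₀ defaults to the **median** of the per-gene
pooled SEs — a fixed-percentile simplification of the original
coefficient-of-variation-minimising tuner; it is configurable.  The
FDR at each observed |d| cutoff is the median permutation call count
divided by the observed call count, capped at 1; each gene's q-value is
the minimum FDR over the cutoffs at which it is called, which makes q
monotone in |d|.  All distinct label permutations are enumerated when
they number at most `n_perm` (20 for the default 3 + 3 design),
otherwise `n_perm` random assignments are drawn.  The comparison is
unpaired by default (pairing of IP/FT by experiment was considered an
open choice); a paired mode (one-sample d on per-experiment
differences, sign-flip permutations) sits behind a flag.  Calls: UP if
d > 0 and q ≤ 0.05, LOW if d < 0 and q ≤ 0.05.

### Evaluation

AUC is computed by the Mann–Whitney identity with ties worth 1/2;
higher score ⇒ UP is the positive orientation and values are not
folded around 0.5.  Score-distribution comparisons between UP and LOW
genes use the two-sample Wilcoxon rank-sum test (the sets are unpaired
and unequal, so a signed-rank test does not apply): exact enumeration
for tie-free samples up to n = 25 per group, tie-corrected normal
approximation otherwise.  Paired AUC comparisons use DeLong's
structural-components estimator; degenerate cases (identical rankings,
zero variance of the difference) return p = 1.

### SVM pair models

A linear soft-margin SVM (liblinear, squared hinge, primal — exact and
deterministic) is trained on one or two variables; performance is the
AUC of leave-one-out decision values (a continuous score, unlike class
predictions).  Because F-variables span orders of magnitude, features
are log10(x + ε) transformed (ε = smallest positive value / 10, per
column) and z-scored on each training fold; both transforms are
configurable.  Cost defaults to C = 1.  The 19 × 19 matrix holds every
pair's LOOCV AUC with single-variable models on the diagonal; failed
cells become NaN rather than aborting the matrix.

### Shuffling validation

Schemes over the top-k expressed miRNAs (k = 50 by default):
`random_identity` reassigns the ordered top-k values to a uniform draw
from all expressed miRNAs (everything else gets zero weight — the
scheme asks whether the *identity* of the top-k matters);
`within_top` permutes the top-k values among the same miRNAs (does the
specific value-to-miRNA assignment matter?); the `fix_top_n` /
`fix_low_n` families pin n of the top-k and permute the rest, and a
sweep over n localises the signal.  Each draw recomputes the single
variable and its AUC against fixed labels.  The exceedance fraction
counts simulated AUCs **≥** the original, so identity shuffles give
exactly 1.0 rather than 0.0; a strict `>` mode is available.  One
master seed spawns order-stable per-draw substreams
(`SeedSequence.spawn`), making results byte-reproducible.  Variables
without miRNA dependence (F9, L1, L2) yield a degenerate distribution
and are flagged, not errored.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

| quantity | model | default |
|---|---|---|
| 3'UTR length L1 | log-normal | median 1 kb, σ = 0.7 |
| CDS length L2 | log-normal | median 1.5 kb, σ = 0.6 |
| miRNA profile | one dominant species + log-normal tail | dominant share 0.6, total mass 10⁵ |
| mRNA profile | log-normal | median 500, σ = 1 |
| BS counts | Poisson(length × propensity), propensity log-normal around the chance 7-mer rate 4⁻⁷ | |
| labels | P(UP) = σ(α + Σ β·z(driver)), P(LOW) mirrored with −β | α = −2, β = 1.5 (AGO2-like, driver F6) or 2.0 (GW182-like, driver L2) |
| IP/FT | IN × exp(±shift·sign + N(0, σ)) | shift 1.0, σ = 0.25, 3 experiments |

Defaults are sized for desk scale: 2,000 genes × 50 miRNAs × 3
experiments; these are also the problem sizes the test suite and the
acceptance script use.  The Poisson-with-length rate induces the
count-vs-length correlation any real site scanner shows, which is what
makes F6/F8 correlate with L2 and gives the GW182-like mode its
character.  An optional second driver (e.g. F4d at β₂ = 1.0 next to F6
at β = 1.5) plants two independent signals for pair-synergy analyses.
If a label draw yields fewer than `min_class_size` (30) genes per
class, α is widened in 0.4 steps up to three times before erroring.

**Null mode** sets β = 0 *and* removes the IP/FT shift: labels are
decoy draws at the base rate, independent of both the variables and the
intensities.  This single mode serves two calibration roles — SAM
false-discovery control (no true enrichment exists) and shuffling-null
uniformity (labels exist but carry no information).

What the generator does **not** emulate: probe-level array artifacts,
dye bias, spatial effects, background subtraction (removed upstream by
scanner software in real data), cross-hybridisation, miRNA-family
shared seeds, and any dependence of binding on sequence context.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted structure, not biological
validity on a given real dataset.

A companion generator plants exact seed-site counts into random
background sequences (background resampled until spurious-match-free,
then re-verified), enabling end-to-end testing from FASTA to matrices.

## Numerical choices

- Ties in top-k selection break on the lexicographically smaller miRNA
  id; "longest sequence" ties break on record id.  All tie-breaks are
  deterministic.
- Constant genes (zero spread, zero difference) get d = 0, not NaN.
- Zero-variance columns in the variable correlation matrix are reported
  as NaN (undefined), never silently 0; zero-variance samples abort
  clustering with the sample named.
- Quantile normalization of a single column is the identity.
- density × length reconstructs counts to better than 1e-12 relative
  error; the triple-loop variable oracle agrees to the same tolerance.
- The pipeline manifest hashes every data output; `run.log` carries
  wall-clock timings and is excluded from the hash list so two runs
  from one config + seed compare byte-identical.

## Known limitations

- The seed matcher is intentionally simpler than dedicated target
  predictors; absolute site counts are not comparable to theirs.
- The SAM s₀ simplification can differ from the CV-minimising tuner on
  strongly heteroscedastic data (both are fudge heuristics; the
  q-ranking is typically unaffected).
- With 3 + 3 samples only 20 distinct permutations exist, flooring the
  attainable q resolution; the implementation enumerates them all and
  logs the fact.
- LOOCV refits one model per held-out gene; the 19 × 19 pair matrix at
  thousands of labelled genes is the most expensive stage and scales
  linearly in labelled-gene count × 190 pairs.
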