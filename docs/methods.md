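# Methods

`drugrepo` implements a three-stage computational screen that proposes
repurposable drugs for a query protein target from a sparse binary
drug–target association network, and ships a planted-structure synthetic
data generator that makes every stage testable without any external
database.

## Model

### Probabilistic matrix factorization

The association network is an n × m binary matrix R (1 = annotated
drug–target interaction). The model approximates R ≈ U Vᵀ with drug
latent rows U ∈ ℝ^{n×D} and target latent rows V ∈ ℝ^{m×D}, minimizing

    L(U, V) = Σ_{(i,j) ∈ S} (R_ij − U_i·V_j)² + λ_U‖U‖² + λ_V‖V‖²

over a supervision set S consisting of all observed positives plus an
equal number of unobserved pairs sampled uniformly as implicit negatives
(the binary matrix carries no true negatives; 1:1 subsampling is
standard implicit-feedback practice). The sample is drawn once per fit
from the fit's own seeded generator rather than resampled every
iteration: a fixed supervision set makes the objective a deterministic
function of (U, V), which is what permits the monotone-descent guarantee
below and makes each fit a pure function of its seed.

Optimization is full-batch gradient descent from a N(0, 0.1²)
initialization with backtracking step halving: a step that would
increase the objective is halved until it does not, so the objective is
non-increasing across accepted iterations, and a step that cannot be
repaired within 40 halvings raises a divergence error. Fits run in a
canonical identifier-sorted index space, which makes them exactly
label-invariant: permuting registry order permutes factor rows and
changes nothing else.

Predicted scores are raw dot products U_i·V_j. No logistic squashing is
applied because only the rank order of candidates feeds the later
stages. Defaults: D = 20, λ_U = λ_V = 0.1, learning rate 0.01, at most
500 iterations, convergence tolerance 1e-6 on the objective decrease.
All are configuration; the defaults are conventional mid-scale values
for implicit-feedback factorization, not fitted constants.

### Ensemble candidate generation

A single factorization of a sparse binary matrix is sensitive to its
initialization and negative sample, so candidates come from an ensemble:
run r uses seed seed_base + r, and contributes its top-k drugs for the
query target ranked by predicted score, after removing the target's
known binders (ties break by drug identifier). A drug is selected as a
candidate when it appears in at least a fraction `freq_threshold`
(default 0.5) of runs. The production-scale protocol this mirrors used
1e5 parallel runs with top-10 per run; the desk-scale default is 100
runs. Because per-run frequencies sum to k, a 0.5 cut can select at most
2k drugs — k must be sized to the candidate pool one expects to admit.
The accumulated table is independent of run order, so sequential and
parallel schedules agree exactly.

### Latent-vector clustering and known-drug enrichment

The combined set (approved known binders ∪ selected candidates) is
clustered by its latent geometry. Because factorizations are only
identified up to rotation and sign, latent rows from different runs
cannot be averaged; drug–drug *distances*, however, are invariant to
those transformations. The pipeline therefore computes pairwise
distances within each of `n_representative_fits` (default 5) seeded
fits and averages the distance matrices before agglomeration. This
consensus geometry suppresses the per-fit negative-sampling noise that
otherwise scatters family members out of their cluster (measured on the
planted scenario: hidden-drug recovery rises from roughly 0.7–0.9 per
seed block with a single fit to 1.0 with five).

Agglomeration is hand-rolled Lance–Williams (single, complete, or
average linkage; average is the default for its robustness and
guaranteed height monotonicity) with a fully specified tie rule —
minimum-distance ties break on the lowest (node_a, node_b) identifier
pair — so the dendrogram is a pure function of its inputs. scipy's
implementation is used in the test suite as an independent cross-check
on tie-free data but not in the pipeline, because it does not guarantee
this tie rule. Supported metrics are euclidean, cosine, and city-block;
Mahalanobis (using the latent covariance) is available behind the same
interface.

Each internal node whose cluster size lies in [min_size, max_size]
(defaults 3 and n−1) is scored for over-representation of known drugs
with the one-sided hypergeometric tail P[X ≥ x] for
X ~ Hypergeom(N, K, n_c), computed in log space; Benjamini–Hochberg
correction is applied across the evaluated nodes and nodes with
q ≤ alpha (default 0.05) are significant. Nested significant nodes are
collapsed to the most significant (lowest-p) representative of each
chain; disjoint significant nodes are all kept. The alternative collapse
rule — keep the smallest significant node — was considered and rejected:
any significant pure-known subcluster (a handful of knowns merging
early) would then suppress every ancestor, including the
candidate-bearing family cluster, so the enrichment scan would
systematically return clusters with no repurposable members. The
candidate members of significant clusters, intersected across all
configured metrics and with the ensemble-selected universe, form the
consensus hits.

### Combined chemical similarity filtering

Consensus hits are finally filtered by chemical similarity to the known
drugs. The score is a sum of two Tanimoto coefficients — a structural
fingerprint and a pharmacophoric-feature fingerprint — ranging over
[0, 2], with 1.5 as the default cut for "strong similarity". The default
backend is a deterministic 2D surrogate built on RDKit Morgan
fingerprints (radius 2, 2048 bits; plain atom invariants for the
structural channel, feature invariants for the pharmacophoric one),
replacing the conformer-based 3D shape + color scoring of proprietary
toolkits while preserving the score range and threshold semantics; the
two component scorers are injectable so a true 3D backend can be swapped
in without touching the filtering logic. Tanimoto of two all-zero
vectors is defined as 1.0 to avoid 0/0, but featurization rejects empty
molecules so the case is unreachable through the public path.

Filtering proceeds in two steps mirroring the screen it reproduces: the
reference set is first expanded from the known drugs to all library
molecules whose best combined score against any known drug meets a
threshold (its own parameter, default 1.5 — whether the original screen
used the same value at both steps is not documented), and each hit is
then kept if its best combined score against that reference meets the
filter threshold, ranked by that score.

## Synthetic data

Three generators, all pure functions of their seed:

- **Planted low-rank matrices** (`make_planted_dti`): nonnegative
  uniform factors of rank D_true; positives are the exact top
  density-quantile of U_true·V_trueᵀ (thresholding rather than Bernoulli
  sampling keeps the planted structure sharp); `n_hidden` positives are
  withheld for evaluation together with an equal number of ground-truth
  negatives; optional label noise flips a fraction of training cells,
  never re-inserting withheld pairs. Defaults (200 × 50, rank 5, 5%
  density, 20 hidden) give ≈480 training positives.
- **Planted fingerprint families** (`make_drug_library`): per family a
  random prototype bit-vector pair (density 0.3, length 256); members
  are prototypes with each bit flipped at `mutation_rate` (default
  0.03). Parameters are validated against closed-form expectations of
  within-family (≥ τ_in = 0.75) and between-family (≤ τ_out = 0.3)
  Tanimoto, so infeasible settings fail loudly instead of silently
  producing unplanted structure.
- **End-to-end scenario** (`make_pipeline_scenario`): a 40-target
  network whose query target t00 has 14 known binders (12 approved, 2
  illicit) drawn from a 10-target family block at edge probability 0.9
  plus one random extra edge each; 4 hidden repurposable drugs carry the
  exact family profile minus the withheld t00 edge, placing them at the
  family consensus in both latent and fingerprint space (the screen's
  favorable case — planted hits are canonical family members, knowns are
  noisy satellites). Three 10-drug distractor families occupy
  overlapping target blocks: they earn genuinely elevated query scores,
  so the ensemble admits them and the enrichment universe is not
  saturated by the query family — without them every clustered drug
  would be family, no cluster could be enriched, and the stage would be
  vacuous. Fifteen decoys have random interactions (never t00) and
  random fingerprints. Family sizes were chosen for hypergeometric
  power: with ≈12 knowns among ≈50 clustered drugs, the family cluster's
  tail probability (~1e-7) survives BH correction with a wide margin.
  Scenario fingerprints are emitted as hex-token surrogates
  (`fp:<hex>:<hex>`) in place of SMILES, so the scenario exercises the
  similarity machinery without a chemistry backend.

What the generators deliberately do not emulate: the degree
distribution, modular overlap, and annotation biases of a real
drug–target database; real chemistry (fingerprints are random bits, not
molecules); and multi-target pharmacology of candidates. Passing the
planted-recovery tests therefore certifies the machinery — that each
stage recovers structure it is pointed at, rejects unstructured decoys,
and composes deterministically — not performance on curated databases.

## Pipeline determinism

One global seed derives every stage seed by fixed offsets (ensemble
seed base = seed + 1; representative fits = seed + 1,000,003 + i), so a
rerun under one integer is bit-identical, and the report carries the
seed list and a configuration hash. Any stage failure aborts with the
stage name and the partial report attached.

## Numerical and degenerate-input choices

- Hypergeometric tails are assembled in log space (logsumexp over
  log-pmf terms) and match exhaustive enumeration to 1e-12 for all
  universes up to N = 12.
- Ranking ties (equal scores, equal frequencies, equal similarity)
  always break by ascending drug identifier.
- Candidate-k of 0, empty candidate sets, empty per-metric hit sets, and
  a disabled/descriptor-less similarity stage all propagate as empty or
  pass-through results with report warnings rather than errors; an empty
  known set, an unknown query target, and a zero-norm latent vector
  under the cosine metric are hard errors.
- `filter_approved` treats unknown status strings as not-approved
  (conservative: only drugs verifiably on the market are proposed).

## Problem sizes

Default test and reproduction workloads are desk-scale by design: 20
seeded factorizations of the 200 × 50 planted matrix for held-out AUC,
and 20 pipeline replicates of the ≈60-drug scenario for end-to-end
recovery, each replicate running a 20-fit ensemble plus 5 representative
fits. The ensemble's production-scale analogue (1e5 runs) is reachable
by configuration (`n_runs`), not needed for correctness.

## Known limitations

- The surrogate similarity scorer is 2D; molecules similar in shape but
  not in 2D substructure will score low. The scorer interface is the
  extension point.
- Frequency-threshold aggregation is one reading of an under-specified
  consensus protocol; union or rank-averaging readings are expressible
  by setting `freq_threshold` low or post-processing the candidate
  table.
- Enrichment assumes the clustered universe is a meaningful sampling
  frame; with very few non-family drugs the hypergeometric test is
  underpowered, which is why the synthetic scenario plants distractor
  families.
- The factorization treats unobserved pairs as (sampled) negatives;
  systematically missing annotations violate that assumption in real
  data.
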