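# Methods

This note documents the statistical and algorithmic conventions of
`revnet`: what each stage assumes, which defaults matter, and what the
synthetic-data tests do and do not establish.

## Study design and data model

The package targets a three-group design — `control`, `model` (disease),
`treated` — with one feature-by-sample abundance matrix per omics layer
(`transcript`, `protein`, `metabolite`) and a shared undirected
interactome. Abundances are analyzed on the log2 scale; raw counts must
be passed through `OmicsMatrix.to_log2()` (log2(x+1)) explicitly — there
is no silent transformation. Matrices with missing values are rejected
at construction: imputation is the caller's responsibility and must be
an explicit, visible step.

## Differential screen

Per feature, the two-group contrast is tested with Welch's
unequal-variance t-test (Student's t available via `equal_var=True`).
No dispersion-sharing count model is used: with ~5 samples per group and
log-scale intensities across three heterogeneous layers, a plain
location test is the least-assumption common denominator, and the
screen's calibration is verified by simulation (type-I error within two
binomial standard errors of α at 1,000 null features).

- log2FC is the difference of log2 group means (not the log of the
  ratio of arithmetic means), consistent with analyzing on the log scale.
- Calling uses the raw p-value (p < 0.05) together with |log2FC| > 1;
  Benjamini–Hochberg q-values are always reported but deliberately not
  used for calling — they document the multiplicity burden.
- Degenerate features (zero variance in both groups): p = 1 when the
  group means are equal; when means differ with zero variance the
  p-value underflows to the smallest positive float. Both conventions
  keep p in (0, 1].

PCA scores come from the SVD of the per-feature-centered matrix;
explained-variance fractions are non-increasing and sum to ≤ 1.

## OPLS-DA and VIP

The metabolite screening statistic is a from-scratch two-class OPLS-DA:
X is mean-centered and unit-variance scaled, the class vector is encoded
−1/+1 (lexicographically smaller group = −1), `n_orth` orthogonal
components are removed by the classical deflation scheme (orthogonal
weight = predictive loading minus its projection on the predictive
weight), and a single predictive component is fitted to the deflated X.

- **VIP** is computed on the predictive component:
  VIP_j = sqrt(p)·|w_j|/‖w‖, so mean(VIP²) = 1 by construction; VIP > 1
  marks above-average influence. This identity and the orthogonality of
  predictive vs orthogonal scores (≤ 1e-8) are asserted in tests on
  every fit.
- **Q²** uses 7-fold cross-validation with class-interleaved, seeded
  fold assignment (each class's samples are shuffled then dealt to folds
  round-robin, keeping folds balanced at n = 5 + 5).
- **Permutation validation** refits the model under shuffled labels
  (default 200 permutations) and reports the empirical p-value
  (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1). Under the null the permuted
  Q² distribution centers at or below zero.
- `n_orth` defaults to 1; there is no universal rule for choosing it,
  so it is an explicit argument, and `n_orth = 0` reduces the model to
  one-component PLS1-DA (verified against a directly coded PLS1 in
  tests).

Metabolite calling combines VIP > 1 from the OPLS-DA with p < 0.05 from
the univariate Welch test, since multivariate importance alone does not
control the per-feature false-positive rate.

## Reversal screen

A feature is *reverted* when it is significant in the disease contrast
(model vs control) and in the treatment contrast (treated vs model) with
opposite fold-change signs. No magnitude-of-restoration requirement is
imposed by default — any significant opposite change counts — because a
restoration threshold is an extra modeling choice; a stricter mode
(|log2FC_tm| ≥ r·|log2FC_mc|) is available via `min_restoration`.
Output is sorted by |log2FC_mc| descending with feature-id tie-breaks,
and the reverted set is by construction a subset of both contrasts'
significant sets.

## MCODE module detection

Vertex weight = (highest k-core number of the closed neighborhood) ×
(density of that k-core), zero below the degree cutoff (default 2).
Complexes grow breadth-first from the highest-weight unvisited seed,
admitting a neighbor when its weight is ≥ (1 − node_score_cutoff) ×
seed weight (default cutoff 0.2) **and** it attaches to at least
`k_core` (default 2) current members once the complex has that many.
The attachment requirement is this package's one deliberate departure
from the textbook growth rule: without it, a single bridge edge between
two dense regions chains them into one complex (the admitted endpoint
has high weight because of *its own* dense neighborhood). Requiring two
attachments is the growth-time counterpart of the k-core post-filter and
makes detection recover planted communities as separate modules.
Post-processing: complexes lacking a 2-core are discarded; haircut
(default on) trims to the 2-core; fluff (default off) adds dense
neighbors. Scores are density × size; all orderings and tie-breaks are
lexicographic, so the result is independent of node insertion order.

## Separation score S_AB

S_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2 on hop-count shortest paths
(edge confidences are treated as filters, never as lengths). Every
node's contribution — in the within terms *and* the between term — is
its distance to the nearest node of the target module **other than
itself**. Consequences:

- S_AA = 0 identically for any module, so the score is calibrated
  against self-separation;
- singleton modules have within-distance 0 by convention (conservative:
  never inflates synergy);
- module pairs detected on the same dense region score ≈ 0 (the floor),
  interleaved disjoint modules score strictly negative, and separated
  pairs score positive.

The alternative convention in the network-medicine literature lets a
node shared by both modules contribute 0 to ⟨d_AB⟩; it makes heavily
overlapping pairs strongly negative but also makes S_AA = −⟨d_AA⟩ < 0,
losing the self-calibration. This package prefers the calibrated form;
the argmin over the matrix — the quantity used to nominate the
synergistic pair — ranks pairs the same way in the common case.

Distances are undefined across connected components, so the matrix is
computed on the largest connected component; module members outside it
are dropped and logged, and any module losing more than half its members
is flagged unevaluable rather than given an imputed distance. Argmin
ties break toward the smaller A label, then the smaller B label. A
degree-preserving randomization null for S_AB significance is a known
extension and is not implemented.

Hub ranking is within-module degree with lexicographic tie-breaks — a
transparent stand-in for the various "cytoHubba-style" hub scores, all
of which correlate strongly with degree on dense modules.

## Over-representation analysis

One-sided hypergeometric upper-tail p-values P(X ≥ k) with BH
correction, computed after restricting query and sets to the universe
(default: the union of all collection members). Database content is
input (GMT), never bundled; results therefore depend on the user's
collection version, which is why no specific pathway lists are asserted
anywhere in the package.

## Synthetic data: what it emulates, what it does not

`generate_dataset` draws per-feature baselines from N(8, 1) log2 units,
adds ±effect_log2 to disease features in the model group, restores
reversed features to the control mean in the treated group (non-reversed
disease effects persist), and adds i.i.d. Gaussian noise (default SD 0.5
log2 units) — i.e., log-normal abundances, matching common omics
practice of analyzing log-transformed intensities. Defaults mirror the
emulated design: 5 samples per group; effect sizes and dispersions are
stated choices, not values fitted to any dataset (none are published for
the motivating study). Disease features occupy the *front* of the
feature list deterministically (signs and noise remain seeded-random),
which keeps planted truths aligned across layers that share a feature
space. The generator does **not** simulate counts, batch effects,
missingness, or correlated features; a green recovery test therefore
establishes correctness of the screening logic, not robustness to those
real-data pathologies. `generate_interactome` is a stochastic block
model: declared blocks occupy consecutive feature runs, leftover nodes
form a background community at the mean between-block probability.

## Determinism

Every stochastic step (generators, fold assignment, permutations) is
driven by an explicit integer seed through `numpy.random.default_rng`;
the pipeline writes a MANIFEST of SHA-256 content hashes, and rerunning
with the same config and seed reproduces every artifact byte for byte.

## Known limitations

- Welch calling with n = 5 per group has limited power at |log2FC| ≈ 1;
  the reversal screen inherits two-contrast multiplicity that is
  reported (q-values) but not controlled jointly.
- MCODE parameters are the canonical defaults; no parameter search is
  performed.
- S_AB is reported without a randomization-based significance level.
- Identifier matching between abundance tables and the interactome is
  exact-string; no cross-database identifier mapping is attempted.
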