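# Methods

## Decision model

A decision hierarchy has a single goal, a tree of objectives of unrestricted
depth, and one ordered set of at least two alternatives shared by every leaf
objective. Labels are matched case-insensitively after whitespace trimming,
so model files can be authored loosely without creating silent mismatches.
Each non-leaf node with ≥ 2 children defines one objective comparison group;
each leaf objective defines one alternative comparison group. A group of
*n* items requires *n*(*n* − 1)/2 pairwise questions. Single-child nodes are
legal and get local weight 1 without elicitation — normalization over a
one-element group forces it, so asking the question would be meaningless.
Groups larger than 7 raise a validation *warning*, not an error: the
question count grows quadratically and large groups strain judgment
reliability, but nothing in the mathematics breaks.

Alternative groups are enumerated before objective groups, matching the
elicitation order used in practice (judge how the alternatives perform on
each outcome before weighting the outcomes, to limit anchoring).

## Priorities and consistency

Local priorities are the normalized principal right eigenvector of the
judgment matrix, computed by power iteration from the uniform vector:
repeated multiplication and sum-normalization until the max-abs change
between iterates is ≤ `tol`. Defaults: `tol = 1e-12`, `max_iter = 10_000`.
Positivity of the matrix guarantees (Perron–Frobenius) a unique positive
dominant eigenvector, so the iteration is globally convergent and
deterministic; non-convergence within the cap raises with the last residual.
λ<sub>max</sub> is estimated as the mean of the component-wise Rayleigh
ratios (Aw)<sub>i</sub>/w<sub>i</sub>, which is exact at the fixed point and
less sensitive to any single small component than a one-component estimate.
The suite cross-checks the eigenpair against a direct dense
eigen-decomposition (`scipy.linalg.eig`) to 1e−8 over 1,000 random
reciprocal matrices, n = 3..8, and against the 3×3 closed form
λ<sub>max</sub> = 1 + t + 1/t, t = (a₁₂a₂₃/a₁₃)<sup>1/3</sup>.

CI = (λ<sub>max</sub> − n)/(n − 1) for n ≥ 3; 1×1 and 2×2 reciprocal
matrices are consistent by construction (CI = 0). The random-index table is
Saaty's (n = 1..10: 0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49);
sizes above 10 raise rather than extrapolate. The inconsistency verdict
applies the 0.15 cutoff to CR = CI/RI. Source conventions differ on whether
the cutoff belongs on CI or CR (and 0.10 vs 0.15); CR is the standard
thresholded quantity, and both CI and CR are always reported so either
convention can be applied by the caller.

Direct-weight entry (`matrix_from_direct_weights`) builds a_ij = w_i/w_j
from typed weights — the pilot-style alternative to answering pairwise
questions. Weights of exactly 0 are rejected rather than smoothed (the
ratio is undefined, and a zero priority is outside the method's premises).
Optional clamping of the ratios into [1/9, 9] is off by default: clamping
changes the matrix, and whether elicitation software does it is a tool
convention, not part of the method, so both behaviours are exposed.

## Synthesis

Global objective weights: goal = 100 %, child global = parent global ×
child local. The identity makes every sibling partition sum *exactly* to
its parent; the test suite asserts this at machine precision.

Overall alternative scores:

- **distributive**: score_k = Σ_leaf g(leaf) · p(leaf, k) with each leaf
  vector normalized to sum 1;
- **ideal**: each leaf vector is divided by its maximum first, then the
  weighted sum is taken.

Both final vectors are renormalized to sum 1 for reporting. This is a
presentation choice: the ratio tables built from scores are invariant to
the normalization, and a common scale makes the two modes comparable side
by side. Internal computation is never display-rounded; rendering rounds to
2 decimals. Ties in ranking share the better rank, with label order used
only to stabilize display.

Ideal mode preserves the relative ranks of existing alternatives when an
alternative that is nowhere the leaf maximum is added or removed (the
idealized vectors of the originals are unchanged; the final renormalization
is rank-neutral). Distributive mode carries no such guarantee, and the test
suite constructs a concrete reversal instance by seeded random search.

Relative differences are larger/smaller score ratios, displayed in the row
of the larger item with ratios ≥ 1.1 flagged significant (the conventional
AHP rule of thumb: a 10 % multiplicative gap). Zero scores are an error —
a zero priority upstream signals a degenerate input, not a valid ratio.

## Group aggregation

Group priorities are element-wise geometric means of the experts'
normalized vectors, renormalized (AIP — aggregation of individual
priorities). The geometric mean is the aggregation consistent with ratio
judgments: it commutes with per-expert positive rescaling, which the suite
asserts in the log domain (pre-normalization log group weight = mean of log
individual weights). AIP is applied to *local* vectors per group, then the
group locals are synthesized once; aggregating each expert's final scores
instead is available behind `aggregate="scores"` for sensitivity checking,
since elicitation reports rarely state which level was aggregated.
Disagreement is the per-item sample standard deviation (ddof = 1 —
appropriate for small panels) of individual weights, in percentage points.
Zero weights abort aggregation rather than being epsilon-smoothed:
eigenvector priorities of positive reciprocal matrices are strictly
positive, so a zero can only be an upstream bug.

## Sensitivity scenarios

A scenario forces named objectives to fixed local shares within their
sibling groups; non-overridden siblings are scaled proportionally to fill
the remainder (the standard remainder rule, and the only one implemented).
Overriding a node never touches the internal weights of its descendant
subtree — a "benefits to 100 %" scenario changes only the top-level split.
Renormalization is skipped when the adjusted weights already sum to 1
within 1e−12, so a no-op scenario (overrides equal to baseline weights)
reproduces the baseline bit-identically. Overriding the only child of a
single-child group is rejected: its weight is pinned by normalization.

Distributive-mode scores are *linear* in an override share α, so along a
scenario path each alternative's score moves monotonically between its
endpoint values, and at α = 1 the forced branch's own leader ranks first.
Note the slope for the alternative that leads *under the forced objective
alone* can still be negative (it may score even higher on the rest of the
tree), so "increasing an objective's weight never hurts its champion" is
not a theorem; the suite tests the monotone-interpolation property and the
α = 1 endpoint instead.

## Synthetic expert panels

The generator emulates the study design the package was built around: a
small panel judging one hierarchy, where only aggregated priorities — not
raw judgments — were ever published. Per comparison group, a latent truth
w is drawn from a symmetric Dirichlet (`concentration` = 1 by default:
uniform on the simplex; smaller → more lopsided "strong opinions", larger →
near-equal weights). Each expert's matrix is a_ij = (w_i/w_j)·exp(σ·z_ij)
with z_ij standard normal and z_ji = −z_ij, so reciprocity is exact by
construction and σ maps monotonically to the expected CR (asserted by
Monte-Carlo over 1,000 matrices at σ = 0.2 vs 0.5). σ = 0 yields perfectly
consistent matrices whose eigenvector recovers w exactly. Defaults,
`n_experts = 9` and `noise_sigma = 0.3`, reflect the emulated panel size
and a mid-range consistency level chosen once; with no published raw
judgments, σ is a free simulation parameter, not an estimate of the real
panel. Optional snapping maps entries to the nearest of the 17 Saaty values
in log space (so reciprocal pairs stay reciprocal).

Streams are keyed by (seed, role, CRC-32 of normalized labels), making
output reproducible and independent of iteration order; identical configs
give byte-identical judgment files.

What the generator does **not** model: systematic expert bias clusters,
correlated noise across groups, attention drift across a long
questionnaire, or the verbal-to-numeric coarsening of real 1–9 elicitation
(unless snapping is enabled). Passing recovery tests therefore show the
*pipeline* is correct and well-conditioned under its own noise model — not
that any real panel's judgments satisfy that model.

## Problem sizes in the test suite

Simulation-based checks run on compact models (a 3-objective/4-alternative
flat hierarchy, or the 13-group diabetes model) with 50–200 replicates per
condition and panels up to 27 experts — large enough for the monotonicity
claims (recovery MAE vs σ; group MAE vs panel size) to hold strictly at the
chosen seeds, small enough that the whole suite runs in well under a
minute. The eigen-oracle cross-check uses 1,000 random matrices. These
sizes are the package's own test design choices.

## Worked case: add-on therapies to metformin

The embedded case carries the final decision model (1 benefit, 7 harms in
two subgroups, 5 alternatives) and the published group-level global
priorities of the 12 objective rows. Local vectors are recovered by the
synthesis identity run backwards (child global / parent global);
re-synthesizing them reproduces every published global to display rounding,
and the ratio table reproduces all 21 printed lowest-level relative
differences to 2 decimals. Alternative-level scores were published only as
a figure and the raw judgments are unavailable, so alternative-level
behaviour is validated by properties (rank preservation, reversal,
recovery) rather than value regressions, and the fixture deliberately
embeds no alternative scores. One layout quirk of the published ratio
table: the GI-symptoms row prints the 1.67 ratio against weight gain even
though weight gain has the larger score; this package always places a ratio
in the larger item's row, so that cell lands in the weight-gain row
instead, with the same value.

## Known limitations

- Only eigenvector prioritization is implemented (no geometric-mean row
  method / LLSM).
- Only the ideal and distributive additive syntheses are implemented (no
  multiplicative AHP, no outranking methods).
- No consensus-iteration (Delphi-style) support; aggregation is one-shot.
- Random-index values stop at n = 10; larger groups need their own RI.
- No probabilistic sensitivity (weight sampling) — scenarios are
  deterministic overrides.
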