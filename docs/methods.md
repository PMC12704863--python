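# Methods

## Model

`hormonet` implements logic-based ODE models of intracellular signaling in
the normalized-Hill formalism.  Every species `X` carries a dimensionless
activity `y_X ∈ [0, y_max]` (`y_min = 0` network-wide) interpreted as its
fractional activation.  A reaction transmits regulator activity through the
normalized Hill functions

    f_act(X) = W · B · Xⁿ / (Kⁿ + Xⁿ),        f_inh(X) = W − f_act(X),

with

    B = (EC50ⁿ − 1) / (2·EC50ⁿ − 1),          K = (B − 1)^(1/n),

which pin `f_act(0) = 0`, `f_act(EC50) = W/2` and `f_act(1) = W`.  The
construction requires `EC50ⁿ < 1/2` (otherwise `B < 0` and `K` is complex);
the constructor enforces this.  Reactions with several regulators AND their
term values together (product); several reactions converging on one product
OR together by inclusion–exclusion, folded left-to-right in table order
(associative, so the fold order matters only at round-off; permutation
invariance is asserted to 1e-12 in tests).  Each species relaxes toward its
logic drive Φ:

    dy_i/dt = (Φ_i(y) · y_max,i − y_i) / τ_i.

The model therefore assumes saturating, cooperative regulation with shared
kinetics across reactions, no explicit synthesis/degradation, no transport
or spatial effects, and constant inputs.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Hill coefficient `n` | 1.4 | – | uniform mild cooperativity, the standard choice in this model family when per-reaction kinetics are unknown |
| `EC50` | 0.5 | activity | half-maximal effect at mid-range activity |
| reaction weight `W` | 1 (interior), calibrated (source) | – | source weights encode input strength; interior reactions at full weight |
| `τ` | 0.1 h (all species), 300 h (CellArea) | hours | signaling is fast relative to growth; the output integrates slowly |
| `y0` | 0 | activity | the formalism is silent on initial conditions; activities start fully deactivated and the baseline steady state is always established before perturbations |
| `y_max` | 1 | activity | normalized activities |

Steady states are fixed points of `y = Φ(y)·y_max` and are independent of
`τ` and `y0` in every regime we probe (verified by test); `τ` only shapes
transients.

## Numerical treatment

The reference integrator is `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8,
atol 1e-10).  Integration proceeds in windows of `20·max(τ)` until
`max|dy/dt| < 1e-6 h⁻¹`, because a cascade of depth *d* relaxes on a
timescale proportional to `d·τ`, not `max(τ)`; non-convergence after 25
windows is flagged on the result rather than raised.  State entries are
clipped to [0, 1] inside the drive evaluation so transient solver overshoot
cannot produce invalid Hill arguments.

An independent damped fixed-point iteration `y ← (1−α)y + α·Φ(y)·y_max`
(α = 0.5, chosen because it converged on every bounded monotone fixture
tried; the oracle does not need to be fast) solves the same equation by a
different route.  The two agree to better than 1e-6 across 100+ random
synthetic networks (acceptance test).  Large batches (Sobol sampling,
screens, landscapes) may use the vectorized fixed-point path; the ODE
integrator remains the reference and every batch path is cross-checked
against per-sample simulations in tests.

Clamping a node ("τ → ∞") pins its state entry and zeroes its derivative,
making clamps exact rather than stiff approximations.

## The packaged hypertrophy network

The packaged asset (`data/hypertrophy/`) encodes a 29-species, 49-signed-
edge cardiomyocyte hypertrophy network with inputs E2 (estradiol), T
(testosterone), Strain (mechanical), AngII and ET-1 (humoral), and the
composite output CellArea (0.5 = homeostasis, >0.5 hypertrophy, <0.5
atrophy).  It was transcribed from the published description of this model
class: all explicitly documented reactions are encoded verbatim (direct
activation of IP3 by T; NFAT's OR of an ERK1/2∧CaN gate with GSK3β
inhibition; estradiol attenuation gates on Strain/AngII/ET-1 → ERK1/2 and
Strain → p38; estradiol's rescue of PI3K from Strain/ET-1 inhibition;
sex-split AMPK arms with Hk2/Pfk2 and MCIP1 downstream).  Connections the
description leaves open were completed with canonical pathway edges
(IP3→Ca²⁺→CamKII/CaN, eNOS→NO→cGMP→PKG1 with PKG1 opposing the
calcium/NFAT/mTOR growth drives, androgen-receptor activation of mTOR and
GSK3β inactivation).  Every reaction's provenance is annotated in the
`source` column of the table; `text:`-style notes distinguish documented
reactions from pathway completion.

Fidelity caveats (all logged in the repository's analysis outputs):

* the betweenness bottleneck ranking of this transcription is led by the
  NO–cGMP corridor together with ERK1/2, and the hormone inputs reach 16
  (E2) and 14 (T) downstream species — a sparser hormone fan-out than the
  source network evidently has;
* eNOS is the top knockdown-influence node only in the high-estradiol
  (pre-menopausal) background, because its baseline activity elsewhere is
  near zero in this transcription;
* the first-order Sobol indices of E2 and T on CellArea are statistically
  indistinguishable here (≈0.19 each at `n_base` 16384), so orderings
  between them are not meaningful on this network.

## Calibration

Baseline calibration ties all five source weights to one shared value and
solves `CellArea(w) = 0.5` by bracketed root finding (Brent, xtol 1e-4) on
the steady-state map; the map is verified to be monotone in each input
weight (increasing for T/Strain/AngII/ET-1, decreasing for E2).  Multiple
weight combinations reach the same output, so the shared value is the
documented tie-break; a general multi-weight least-squares mode exists but
is explicitly labeled degenerate.  Demographic models move only hormone
weights: pre-menopausal `w_E2 = 0.5` (a chosen mid-range convention, not a
fit), post-menopausal `w_E2 = 0.01`, younger male `w_T` solved so CellArea
reaches 0.65, older male `w_T` at 80 % of the younger-male value with its
CellArea left as a prediction.  All other inputs stay at baseline.

## Validation protocols

*Qualitative*: each input (and each stimulus+hormone pair) is up-regulated
by adding Δy = 0.3 to its source weight (clipped at 1); steady-state
changes of all nodes are ternarized with a ±0.05 dead band.  Combined
conditions are referenced to the stimulus alone and simulated sequentially
from its steady state (fixed points are path-independent; the sequential
protocol is asserted to agree with direct weight setting).  The packaged
observation table is a 39-cell reconstruction: 22 rows are anchored in the
documented validation outcome (including all seven cells where the model
and literature are known to disagree) and 17 rows encode the canonical
pathway expectations the network was assembled from; each row is marked.
Agreement on it is computed at run time — 32/39 (82 %) — and the
acceptance check is the soft ≥75 % bound appropriate for a reconstructed
table.

*Quantitative*: three experimental studies are encoded as input-weight
prescriptions (in vitro AngII/ET-1 at 0.9 with estradiol arms at 0.5;
aortic banding as Strain 0.6 with doubled AngII on an estradiol-0.5
background; spontaneously hypertensive rats as doubled AngII plus Strain
0.6 on an ovariectomized estradiol-0.01 background, hormone increments of
+0.3).  Percent CellArea changes are reported against each study's own
control background — a 152 %-scale change is only possible against a
suppressed control, not against the 0.5 baseline — and additionally
against the stimulus-alone arm where a hormone is layered on a stimulus.
Experimental uncertainty for ratios is propagated to first order assuming
independent errors: `σ_R = |num/den|·√((σ_num/num)² + (σ_den/den)²)`.

## Perturbation analyses

Influence of node *i* is `I_i = Σ_{j≠i} |Δy_ij|` and sensitivity of node
*j* is `S_j = Σ_{i≠j} |Δy_ij|`, where `Δy_ij` is the steady-state change
of *j* when *i* is clamped — up-regulation at 0.8, knockdown at 0.1 —
against the background steady state.  Inputs are clamped like any other
node.  The diagonal is excluded by construction; non-converged clamps are
excluded from sums and reported.  Response curves sweep source weights for
inputs (clamp sweeps available behind a flag) and clamps for interior
nodes, since clamping is the only way to set an interior activity.
Crosstalk landscapes grid two input weights on [0, 1] with the rest at
baseline.

First-order Sobol indices use Saltelli sampling: scrambled Sobol' points
give matrices A and B (seeded; default seed 20250101, `n_base` 1024 rounded
up to a power of two with a warning), plus hybrids AB_i; the estimator is
`S_i = mean(f_B·(f_AB_i − f_A)) / Var(f)` with bootstrap standard errors.
Only the five source weights are treated as factors: interior nodes are
mutually dependent through the network, and the independence assumption of
variance-based sensitivity analysis only holds for the most upstream
quantities.  CellArea's total variance over the full input hypercube is
dominated by interactions, so first-order indices are small (≈0.19 for the
hormones) with appreciable Monte-Carlo error; reported standard errors
should always be read alongside the indices.

## Synthetic networks

The generator produces chains, trees, random DAGs, random cyclic networks
(with at least one guaranteed negative-feedback edge, exercising
inhibition-in-cycle behavior the feedback-free packaged network lacks), and
three-node AND/OR/inhibition motifs — all seed-deterministic.  These
fixtures have closed-form or brute-force-checkable steady states and give
every pipeline stage a test that does not depend on the packaged asset.
They emulate the *mathematical* class (bounded activities, AND/OR
combination, source-driven inputs), not biological topology: no scale-free
degree structure, no crosstalk motifs, and sizes of order ten species.
Passing on them demonstrates correctness of the machinery, not realism of
any particular biological network.

## Known limitations

* The packaged network is a text-anchored reconstruction; topology details
  that were never published (gate assignments, the full edge list) are
  pathway-completed, and the three fidelity caveats above follow from that.
* Steady-state analyses assume the unique-fixed-point regime; networks
  with strong positive feedback can be bistable, in which case results
  depend on the starting state (the chaining API makes the starting state
  explicit).
* Hormone inputs are constant; cyclical hormone dynamics and dose-time
  effects are out of scope.
* The composite CellArea output is deliberately sensitive — calibrated
  inputs sit on the steep flank of the Hill curves — so absolute percent
  changes inherit that steepness.
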