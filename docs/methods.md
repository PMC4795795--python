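# Methods

## The model

`reachframes` implements a feedforward basis-function network that computes
desired reach trajectories in visual (eye-centered) coordinates, together
with the population-analysis pipeline used to compare such a network against
recordings from reach-related posterior parietal cortex (PPC).

All simulations are 1D: positions are eccentricities in degrees along a
single axis, matching the quasi-linear stimulus arrangements of the
neurophysiological tasks the model addresses.  A task condition is a triple
(E, H, T) of eye, initial-hand and target positions, with derived
quantities TE = T − E (target in eye coordinates), HE = H − E (hand in eye
coordinates) and TH = TE − HE = T − H (the displacement vector, expressed
in eye coordinates).

Task time t is dimensionless with three unit-length epochs: pre-target
(−2 ≤ t < −1), delay (−1 ≤ t ≤ 0) and movement (0 < t ≤ 1).  The temporal
interpolation function is piecewise linear,

    psi(t) = 1          for −1 ≤ t ≤ 0   (back-extrapolated to t < −1)
    psi(t) = 1 − t      for 0 < t ≤ 1,

and the desired trajectory is computed in two stages:

    TH    = TE − HE
    he(t) = TE − psi(t)·TH.

During the delay he = HE; at movement offset he = TE.  A smooth
(smoothstep) falling sigmoid is available behind the same interface
(`psi(t, form="smooth")`); it shares the endpoints and monotonicity and
does not change any qualitative result, so the piecewise-linear form is
the default.  The "0.1 s time step" of the modeled experiments maps to a
step of 0.1 in normalized time: 31 samples across the full task.

## Unit responses

The network's three internal nodes represent the target in eye-centered,
hand-centered, and eye-and-hand-centered coordinates.  Units carry Gaussian
tuning of length scale σ and a semi-linear gain modulation
f(x) = max(x, 0) whose slope sign alternates between adjacent units:

    r1 = A exp[−(TE − u)² / 2σ²] · f[±(HE − v)/σ]          (eye)
    r2 = A exp[−(psi(t)·TH − u)² / 2σ²]                     (hand, dynamic)
    r3 = A exp[−(TE − u)² / 2σ²] · f[±(psi(t)·TH − v)/σ]    (eye-and-hand)

Before target onset the target-related factors are set to unity:
r1 = A·f[±(HE − v)/σ], r2 = A, r3 = A.  Defaults are A = 30 (rate units),
σ = 15°.  Gaussian rate noise (zero mean, sd 5) is added after evaluation,
independently per unit × condition × time point, unclipped (clipping at
zero would distort the regression's noise model).  Within one experiment
all noise comes from a single seeded stream, so repeated analyses at
different times use fresh but reproducible draws.

Three alternative arrangements of the same trajectory computation are
implemented as contrasts (`rising_phi`, `dual_sigmoid`, `static_hand`,
corresponding to replacing the dynamic displacement-vector node or
re-expressing he(t) with the rising sigmoid phi = 1 − psi).  Variant nodes
have no stated pre-target response; requesting one raises rather than
guessing, and the variant analyses are restricted to the delay and
movement epochs, which is all their contrasts require.

## Populations

Each node is tiled with N = 30 onset values per onset dimension over
−3σ..+3σ: N units for the single-onset hand node, N² for the dual-onset
nodes.  Onsets are an evenly spaced deterministic grid by default — the
phrase "uniformly sampling" is ambiguous between a grid and uniform random
draws, and the grid makes the downstream screened-unit counts stable and
exactly reproducible; a seeded uniform-random mode exists for robustness
checks.  Gain signs alternate +/− in row-major (u, v) order starting with +.

## Tasks

* Delay task: 9 targets spanning −2σ..+2σ in steps of σ/2, crossed with
  5 eye/hand configurations, probed at t = 0 (45 conditions).
* Screening task: E = H = 0, the same 9 targets (center-out probe).
* Gradient task: all 125 (E, H, T) combinations from {−20, −10, 0, 10, 20}°,
  followed over the 31-sample time grid.

The five (E, H) configurations are a genuinely open design choice (the
modeled experiments show them only graphically).  The package default
displaces eye and hand by equal and opposite amounts about the origin so
that the gaze–hand offset HE takes five symmetric values
{0, ±2σ, ±3σ}: `{(0,0), (1.5σ,−1.5σ), (−1.5σ,1.5σ), (σ,−σ), (−σ,σ)}`.
This is the standard reference-frame design — five distinct eye–hand
offsets, all positions on the σ/2 grid — and it dissociates TE, TH and HE
while driving the gain modulation across its full working range (the
offsets span the ±3σ onset range, so saturated gain branches are well
represented).  Narrower designs — e.g. offsets {0, ±σ, ±2σ}, or the
compact "cross" `{(0,0), (±σ,0), (0,±σ)}` which exposes at most one
saturated gain level per unit — produce noticeably cleaner (less
heterogeneous) classifications of the pure-frame nodes; the reported
heterogeneity of parietal populations is matched by the wide-offset
design.  The pair set is a config entry (`eh_pair_fractions`) so
alternatives can be swapped in.  With the ±3σ offsets the eye-centered
target TE can reach ±3.5σ, slightly beyond the regression's μ bound of
±45°, as happens in real workspaces; the affected extreme-onset units are
largely removed by the peak-location screen.

## Screening

Center-out responses are fit to r = a·exp[−(T − μ)²/2s²] + c under bounds
a ∈ [0, 100], μ ∈ [−45, 45]°, s ∈ [10, 30]°, c ∈ [0, 10].  Spike variance
explained is SVE = r²·a; a unit is accepted when μ lies at least s/2 inside
the task range [−2σ, 2σ] and SVE ≥ 10.  When noise is enabled the screen
runs on the same noisy dataset as the downstream regression (one simulated
dataset per experiment), matching an experimental workflow.

## Reference-frame regression and classification

Each screened unit's 45 delay-task responses are fit to

    r = a exp[−(TX − μ)²/2s²] (1 + g·HE) + c,   TX = w·TE + (1 − w)·TH,

with bounds a ∈ [1, 100], s ∈ [10, 30], g ∈ [−0.15, 0.15], μ ∈ [−45, 45],
c ∈ [0, 10], w ∈ [−1.5, 2.5].  Two nested submodels freeze w at 0
(hand-centered) and 1 (eye-centered).  Each submodel is compared with the
full model by F = (RSS_sub − RSS_full) / (RSS_full/(n − 6)) on (1, n − 6)
degrees of freedom; at P < 0.01, both rejected → intermediate, only hand
rejected → eye, only eye rejected → hand, neither → indeterminate.  This
decision table is the package's reconstruction of stepwise classification
from the four class labels and the nested tests; it is isolated in
`classify_unit` so it can be swapped.  Indeterminate units are excluded
from weight histograms but counted in class-size reports.

### Optimization

Both objectives are multimodal in the peak location, so all fits use a
deterministic multistart: a coarse grid over the nonlinear parameters
(μ over the 9 target positions, s over {10, 15, 20, 25, 30}, and for the
full model w over {−1, 0, 0.25, 0.5, 0.75, 1, 2}), where the remaining
parameters enter linearly and are solved in closed form per grid point.
The best grid candidates (up to three, pruned when clearly dominated) are
polished with bounded trust-region least squares (analytic Jacobians,
tolerances 1e−12).  Residual ties are broken deterministically: smallest
width then smallest |μ| for the screen, w closest to 0.5 for the full
model.  The full-model polish additionally starts from both submodel
solutions, which guarantees the nesting inequality RSS_full ≤ RSS_sub up
to solver tolerance; a submodel beating the full model beyond 1e−6
relative tolerance raises as an optimizer-failure signal.  Degenerate
inputs (variance-free responses) return a flagged fit with amplitude at
its lower bound and r² = 0 instead of raising; RSS_full = 0 cases yield
p = 0 against an imperfect submodel and p = 1 when both residuals vanish.

### A known, deliberate property

For eye-node units whose gain modulation is truncated at zero over part of
the tested HE range, the regression's linear gain (1 + g·HE) cannot
represent the clipped branch, and the full model genuinely attains its
global optimum at w below 1 even for noiseless responses (verified with a
dense per-w residual profile).  These are the same saturated units that
produce ambiguous (intermediate/indeterminate) classifications under
noise.  Noiseless recovery of w = 1 for *every* screened eye-node unit is
therefore not a property of this model under any eye/hand design that
retains saturated units; the recovery tests document this.

## Movement dynamics

Starting from the delay-period state, the screen and the classification
are re-applied at each movement time in {0, 0.25, 0.5, 0.75, 1} (fresh
noise draws per time point).  Class membership for the mean-w series is
re-evaluated at each time, which deliberately preserves the reported
artifact that the shrinking hand class drifts past w = 0.  Subpopulation
sizes are reported as fractions of their t = 0 values; linear trends use
unweighted ordinary least squares.  Re-screening at every time point is an
interpretation choice (the alternative fixes inclusion at t = 0); it
matches the description of hand-centered units progressively failing to
qualify for inclusion.

## Gradient analysis

For each analysis-parameter pair (T×H, T×E, H×E; third parameter fixed at
0°) and each unit, a 5×5 activity matrix over {−20..20}° is differentiated
by central differences (one-sided at edges, 10° grid step).  Each
element's gradient angle is doubled (magnitude preserved) before vector
summation, so directions that differ by 180° — indistinguishable for a
relative variable (T − H vs H − T) — reinforce instead of cancel.  Unit
resultants sum to node resultants.  For the hybrid population the node
weights 0.25 : 0.50 : 0.25 (eye : hand : eye-and-hand) are treated as
composition fractions: each node contributes its *mean* unit resultant
times its weight.  (Raw summation would let the N²-unit nodes swamp the
N-unit hand node, contradicting the intermediate go-epoch direction the
hybrid is meant to produce.)  Gradients are computed on noiseless
responses by default; the epoch samples are the unit-normalized resultants
at t = −1.5 (pre-target; the exact pre-target instant is not critical),
t = 0 (go) and t = 1 (movement offset).  Directions are reported both in
doubled-angle space and halved into (−90°, 90°] for reading against the
parameter axes (first pair parameter at 0°, second at 90°, their
difference at −45°).

## What the synthetic data does and does not emulate

The generator produces idealized rate responses: deterministic tuning
plus additive Gaussian noise, one draw per condition.  It omits trial
structure and trial-to-trial kinematic variability, spiking (Poisson)
statistics, adaptation, target-onset transients and the delay-to-movement
transition, and any 2D/3D workspace structure.  Passing tests therefore
show that the analysis pipeline recovers the representations the network
actually contains under the stated noise model — not that it would do so
for real spike trains with correlated, non-Gaussian variability.

## Problem sizes and runtime choices

The study-size runs use the full tiling (N = 30; 1830 units) and ten noise
seeds for the seed-averaged classification percentages.  Examples use
N = 10 so they run in seconds; test fixtures use small hand-built
populations where the full tiling adds nothing to the property under
test.  All randomness flows from explicit seeds; identical (experiment,
config, seed) produce byte-identical summary artifacts.

## Known limitations

* The stepwise decision table is a reconstruction (see above); other
  stepwise variants could classify borderline units differently.
* The exact five eye/hand configurations of the modeled experiment are
  unknown; classification percentages shift by several points between
  reasonable choices (see Tasks).
* The hybrid-population weighting is interpreted as composition fractions;
  the alternative (raw weighted sums of node totals) is available by
  pre-scaling weights but is not the default for the reason given.
* Percentages and counts quoted for the noisy pipeline are seed averages;
  single seeds vary by a few points (binomial variation over ~200 units).
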