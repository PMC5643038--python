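# Methods

## Model

`liftbn` implements a static, bilaterally symmetric, sagittal-plane (2D)
top-down linkage model of lifting. Only gravity acts: the lift is analysed
as a quasi-static posture, so every intersegmental reaction force is
vertical and equals the weight supported distal of the joint. The chain is

    hands (+ external load) -> elbow -> shoulder -> L5/S1

with both arms computed once and doubled, and the hand load split equally
between the hands. At L5/S1 the net sagittal moment is balanced by a single
equivalent erector spinae muscle at a fixed moment arm (default 0.053 m,
the recommended value for models that exclude intra-abdominal pressure);
its line of action is perpendicular to the disc, so muscle force
contributes to compression only. The vertical reaction is resolved in the
disc frame at the disc angle α (degrees from horizontal):

    erector force E = |M_L5S1| / d
    compression   C = E + W cos α
    shear         S = W sin α        (positive down the anterior slope)

α = 40° + β(T, K), where β is a polynomial regression in the
torso-from-vertical angle T = 90° − torso angle and the included knee angle
K = 180° − (knee − ankle), both in degrees.

### Geometry and sign conventions

All five posture angles are link orientations measured counter-clockwise
from the anterior horizontal, proximal to distal. Reaction moments are
reported as Σ W·(x_load − x_joint): positive when the supported load lies
anterior to the joint (extensor demand). Under this convention the
reference lifting posture yields a positive elbow moment (+43.5 N·m, hands
anterior to the elbows) and a negative shoulder moment (−39.3 N·m, the
hands hang posterior to the shoulders of the flexed trunk). Units are SI
internally; degrees and kilograms at the API and config boundary.

## Anthropometric constants: provenance and calibration

The segment-parameter table (length fraction of stature, mass fraction of
body mass, COM fraction from the proximal joint) follows the standard
stature-proportion (Drillis–Contini) and cadaver (Dempster) traditions.
Because the verification scenario's source does not print its
anthropometric or regression constants, **the defaults are a
reconstruction**: most entries are the standard published fractions, and
five remaining degrees of freedom were solved in closed form — once, then
frozen — so that the deterministic pipeline reproduces the published
verification values for the carbon-lifting task (elbow 43.5 N·m, shoulder
−39.3 N·m, L5/S1 150.9 N·m, compression 3315.2 N, shear 682.2 N):

| constant | value | pinned by |
|---|---|---|
| hand grip-centre fraction | 0.30973 | elbow moment |
| upper-arm length fraction | 0.18521 | shoulder moment |
| torso-above-L5/S1 mass fraction | 0.37612 | reaction-force magnitude implied by (C, S) |
| torso COM fraction | 0.65422 | L5/S1 moment |
| β-regression intercept | −17.2125 | disc angle implied by (C, S) |

The torso segment is the L5/S1→shoulder link and its mass fraction covers
everything above L5/S1 (head, neck, upper trunk); a `pelvis` entry closes
the whole-body mass budget to 1. The β slopes (0.30 °/° in T, 0.12 °/° in
K; higher-order terms zero) are themselves reconstructions — modest
positive couplings of the order reported for lumbosacral posture — and
only the intercept is calibrated. Every constant is overridable per
scenario (`segments:` and `disc_regression:` blocks).

Two independent consistency checks support the reconstruction. First, with
the elbow/shoulder/L5/S1 contributions pinned by the deterministic
calibration, the posture-random Monte Carlo mean shift is fully determined
analytically (E[cos θ] = cos θ̄ · e^(−σ²/2) for normal angles): the model
predicts −31.0 N, and the published independently simulated value is
−31.1 N. Second, the model's posture+hand-load compression SD (~807 N)
reproduces the published injury-evidence experiment (posterior means
3190.5/3667.2 N computed here vs 3190.2/3660.9 N published; shear
673.5/715.0 vs 673.1/715.7). Gravitational acceleration is 9.81 m/s².

## Stochastic layer

Inputs are independent untruncated normals. Posture SDs represent
video-posturometry measurement error; they are stated as standard
deviations converted from mean absolute errors under normality
(σ = MAD·√(π/2), available as `mad_to_sd`), with a pooled value reused for
knee and ankle. The hand-load distribution (53.1 ± 12.8 kg in the packaged
scenario) describes genuine task variability. Negative hand-mass draws
(probability ≈ 2×10⁻⁵ at those parameters) are clamped to zero and counted.

Each varied input draws from its own child stream of a
`numpy.random.SeedSequence`, so runs are bit-reproducible per seed and the
posture draws do not change when hand load is additionally varied.
Simulation default is n = 10⁶ draws (the verification study used 10⁷; at
10⁶ the Monte Carlo SE of the mean is ≈ 0.6 N posture-random, already far
below any decision threshold, and a run takes under a second vectorised).

Summaries are weight-aware so the same code serves forward simulation and
posterior inference: weighted mean, population-style weighted SD, weighted
quartiles with Hazen plotting positions ((cumw − w/2)/Σw, linearly
interpolated; coincides with unweighted Hazen quantiles for uniform
weights), and effective sample size ESS = (Σw)²/Σw².

## Injury inference

Disc prolapse is stress–strength interference: injury ⇔ C > strength, with
strength ~ N(5448, 2366) N (cadaver motion-segment testing in mild
flexion) independent of every other input. Conditioning on observed injury
status is exact importance weighting: each prior draw i is reweighted by
the analytic likelihood Φ((Cᵢ−μₛ)/σₛ) (or its complement), integrating the
strength node out in closed form — no rejection, no discretisation, and no
extra variance from sampling strengths. A `sample_strength=True` mode that
does sample strengths and uses indicator weights exists for didactic
parity with the network diagram. All-zero weights (impossible evidence)
raise an error; ESS below 1% of n triggers a warning.

The same update is verified by an independent discrete route: compression
is histogrammed into equal-probability bins (edges at weighted quantiles),
the injury CPT is evaluated analytically at bin midpoints, and a small
exact variable-elimination engine computes the posterior over bins. Bin
representatives are within-bin weighted means, so the no-evidence marginal
reproduces the sample mean exactly and the posterior-mean discrepancy
against importance weighting shrinks as bins are refined (≈144 N at 10
bins → ≈20 N at 100 bins in the packaged scenario).

## What the scenario generator does and does not emulate

Monte Carlo inputs emulate *measurement error* in posture and *task
variability* in load, as independent normals. Real lifting data violate
several of these assumptions: joint angles co-vary (a deeper squat moves
knee, hip and torso together), postures and loads vary within and between
lifts (the static model sees one frozen instant), and measurement error is
bounded rather than Gaussian. Passing tests therefore demonstrate correct
probabilistic machinery under the stated input model, not validity of the
normal-independence assumptions for any particular workplace dataset.

## Numerical choices, degenerate inputs, tie-breaks

- Vectorised float64 throughout; the chained-recursion and one-shot
  free-body formulations agree to ~1e-12 relative and are cross-checked at
  1e-9 in tests.
- Moments use |M| when converting to erector force; the model targets
  extensor-demand lifting tasks, and a flexor-demand posture would need a
  different muscle equivalent (limitation, not an error path).
- Degenerate SD = 0 inputs reproduce the deterministic output exactly;
  n = 1 simulations are legal.
- Weighted-quantile ties are handled by stable sorting; grouped equal
  values interpolate through their pooled Hazen position.
- Φ underflows to exactly 0/1 beyond ~±39σ; impossible-evidence detection
  relies on this and raises rather than returning NaN.

## Known limitations

- Intra-abdominal pressure relief of the extensor moment is excluded by
  design (the 5.3 cm moment arm is the matching recommendation).
- Single-equivalent-muscle lumbar mechanics; no antagonist cocontraction,
  no multi-muscle partitioning, no EMG drive.
- Static 2D analysis: no inertial forces, no asymmetric or twisting lifts.
- Injury is compression-only single-load interference; cyclic-loading
  fatigue and shear-based failure criteria are out of scope.
- The anthropometric defaults are calibrated reconstructions (above);
  users with measured segment parameters should override them.
- The published hand-load-random compression SD (133.7 N) is not
  reproducible by this — or, we argue, any — top-down model consistent
  with the published deterministic moments: the implied load-to-compression
  slope (≈10.4 N/kg) contradicts the slope (≈38.5 N/kg) forced by the
  printed elbow moment at 53.1 kg. The model reports ≈492 N; the
  same-source posterior experiment, which this package reproduces closely,
  is consistent with the larger value.
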