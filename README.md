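# liftbn — probabilistic L5/S1 spinal loading during lifting

`liftbn` predicts the compression and shear force on the L5/S1
intervertebral disc during a sagittal-plane lift, for ergonomists and
biomechanists who need not just a point estimate but a full probability
distribution — and who may hold *evidence about the outcome itself*: whether
the lifter actually suffered a disc prolapse.

Three layers build on each other:

1. **Deterministic statics.** A classical 2D static top-down link-segment
   model: body-segment lengths, masses and centres of mass are scaled from
   stature and body mass; intersegmental reaction forces and moments are
   propagated hands → elbow → shoulder → L5/S1; the net extensor moment
   `M` is balanced by a single equivalent erector spinae muscle at a fixed
   moment arm `d` (default 5.3 cm), acting perpendicular to the disc.
   With the vertical reaction `W` (the supported weight) and disc angle `α`
   (40° plus a regression deviation `β(T, K)` in the torso-from-vertical
   angle `T` and included knee angle `K`):

   compression `C = |M|/d + W·cos α`, shear `S = W·sin α`.

2. **Monte Carlo uncertainty.** Joint angles and hand mass become
   independent normal random variables (posture SDs from ergonomic
   measurement-error studies, converted from mean absolute errors via
   `σ = MAD·√(π/2)`); seeded draws are propagated through the vectorised
   statics and summarised with weighted means, SDs and quartiles.

3. **Bayesian injury evidence.** Disc prolapse is a stress–strength
   interference event: injury ⇔ `C > strength`, strength ~ N(5448, 2366) N
   from cadaver testing. The injury node is a *descendant* of compression,
   so observed prolapse status updates compression (and, through shared
   draws, shear) by Bayes' theorem — implemented as exact importance
   weighting with the closed-form likelihood `Φ((Cᵢ−μₛ)/σₛ)` per draw, and
   cross-checked by a small discrete factor-network verifier.

## Worked example

The packaged `carbon_lifting` scenario describes a 50th-percentile female
(161.8 cm, 65.6 kg) lifting 53.1 ± 12.8 kg carbon chunks in a smelter, with
measured posture (ankle 82°, knee 114°, torso 40°, shoulder 192°, elbow
−56°, from the horizontal):

```bash
liftbn run --config carbon_lifting
```

```text
       quantity    mean   sd     p25     p50     p75  ess
   elbow_moment   43.50 ...
shoulder_moment  -39.30 ...
    l5s1_moment  150.90 ...
  erector_force 2847.17 ...
     disc_angle   55.55 ...
    compression 3315.20 ...
          shear  682.20 ...
```

The 3315 N compression sits near the 3400 N action limit used in lifting
guidelines. Adding uncertainty and injury evidence
(`python examples/injury_evidence.py`, 10⁶ draws, seed 2017):

```text
P(disc injury) under the prior = 0.193

evidence        E[C] (N)   SD (N)    p25     p75   | E[shear] (N)
injury=none      3282.5    806.7  2714.5  3802.6   |     681.6
injury=false     3190.5    774.2  2647.4  3691.7   |     673.5
injury=true      3667.2    826.1  3086.7  4206.7   |     715.0

injury evidence raises mean compression by +476.7 N (14.9%)
```

Learning that the lifter suffered a prolapse raises the mean compression
estimate by ~15% and shifts the whole distribution — including shear, which
the injury node influences only through the draws it shares with
compression. Note the posture-random mean (3282.5 N) sits ~30 N below the
deterministic value: the angle-to-compression map is nonlinear, so
measurement error biases the mean, while the hand-load effect is affine and
leaves it unchanged.

Other entry points: `python examples/deterministic_lift.py`,
`python examples/posture_uncertainty.py`,
`liftbn run --config <file> --mode posterior --evidence true --verify-discrete`,
`liftbn validate <file>`, `liftbn fixtures list`.

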