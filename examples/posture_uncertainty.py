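"""Propagate posture-measurement error and hand-load variability.

Monte Carlo with 10^6 draws: once with only the five joint angles random
(video posture-measurement error), once with only the hand mass random
(the 53.1 +/- 12.8 kg carbon chunks), once with both.  Note the
posture-random mean drops ~30 N below the deterministic 3315 N value —
the angle-to-compression map is nonlinear, so measurement error biases the
mean, while the hand-load effect is affine and leaves the mean in place.
"""

from liftbn import fixture_path, load_config, simulate, summarize

config = load_config(fixture_path("carbon_lifting"))
scenario = config.to_random_scenario(n=1_000_000, seed=2017)

print("varying inputs      mean      sd     p25     p50     p75  (compression, N)")
for vary in ("posture", "hand_load", "both"):
    s = summarize(simulate(scenario, vary), "compression")
    print(
        f"{vary:<12} {s.mean:9.1f} {s.sd:7.1f} {s.p25:7.1f} {s.p50:7.1f} {s.p75:7.1f}"
    )
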