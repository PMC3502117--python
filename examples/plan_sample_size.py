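"""Plan sample sizes for main effects and gene-environment interactions.

Computes the cases (= controls) needed at 90% power, alpha 0.05, for
carrier frequencies typical of rare (1-3%) and common (8-16%) variants,
then verifies one analytic answer by simulation.
"""

from poolgen import power

print("main effect, OR 1.5:")
for p0 in (0.02, 0.04, 0.16):
    n = power.sample_size_main(power.PowerSpec(p0, odds_ratio=1.5))
    print(f"  carrier freq {p0:.0%}: {n} cases and {n} controls")

print("gene-environment interaction (environment prevalence 40%):")
for p0 in (0.03, 0.16):
    for i_or in (1.5, 2.0):
        n = power.sample_size_interaction(power.PowerSpec(
            p0, interaction_or=i_or, env_prevalence=0.4))
        print(f"  carrier {p0:.0%}, interaction OR {i_or}: {n} per group")

spec = power.PowerSpec(0.16, odds_ratio=1.5)
n = power.sample_size_main(spec)
sim = power.power_by_simulation(spec, n, replicates=2000, seed=1)
print(f"check by simulation at n={n}: empirical power "
      f"{sim['power']:.3f} (target {spec.power}, "
      f"95% CI {sim['ci_low']:.3f}-{sim['ci_high']:.3f})")
# Rare variants need several-fold larger samples than common ones for the
# same effect size; interactions are costlier still.
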