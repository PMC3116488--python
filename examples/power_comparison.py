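"""Power of the marginal test versus the joint scan as LD strengthens.

Runs a reduced replicate count for speed; the qualitative picture -- the
marginal test losing power as r^2 grows while the joint scan keeps finding
the planted pair -- is stable.
"""

from hiddenpair import SimConfig, power_experiment, solve_model_params

R2_GRID = (0.1, 0.3, 0.5, 0.7)
models = [solve_model_params(0.1, 0.02, 0.3, 0.3, r2, "+") for r2 in R2_GRID]
cfg = SimConfig(models[0], replicates=30, seed=99)

marginal = power_experiment(models, cfg, methods=("marginal",), alpha=0.05)
joint = power_experiment([models[-1]], cfg, methods=("joint_scan",), alpha=0.05)

print("power to detect the planted pair (30 replicates each):")
for _, row in marginal.iterrows():
    print(f"  marginal test, r2={row.ld_r2:.1f}: {row.power:.2f}")
print(f"  joint scan,    r2=0.7: {joint.loc[0, 'power']:.2f}")
print("-> single-locus power collapses as correlation cancelation strengthens;")
print("   the exhaustive pair scan keeps most of its power at r2 = 0.7.")
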