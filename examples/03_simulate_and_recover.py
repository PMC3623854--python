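"""End-to-end analysis of a synthetic region with known effects.

Generates a 50x50 study region where log10 morbidity depends on the two
deprivation components with standardized effects b1 = 0.6 and b2 = 0.3 and
residual noise 0.74, runs the full pipeline, and compares the fitted
standardized slopes with the closed-form targets
b / sqrt(b1^2 + b2^2 + sigma^2).
"""

from deprivdiff import SimulationConfig, expected_standardized_beta, run_simulation

cfg = SimulationConfig(seed=1)  # defaults: 50x50, rho 0.8, b1 0.6, b2 0.3, sigma 0.74
report = run_simulation(cfg, out_dir="sim_out")

t1 = expected_standardized_beta(cfg.effect_target, cfg.effect_target,
                                cfg.effect_differential, cfg.noise_sd)
t2 = expected_standardized_beta(cfg.effect_differential, cfg.effect_target,
                                cfg.effect_differential, cfg.noise_sd)
print(f"closed-form targets: beta1* = {t1:.3f}, beta2* = {t2:.3f}\n")
for outcome, rec in report.recovery["outcomes"].items():
    print(f"{outcome}: fitted beta1 = {rec['beta1_fitted']:+.3f}, "
          f"beta2 = {rec['beta2_fitted']:+.3f} "
          f"({'ok' if rec['within_tolerance'] else 'off target'})")
# both fitted slopes should sit within ~0.05 of the targets: the pipeline
# (lag -> PCA -> standardized OLS) recovers the generative effects despite
# binomial count noise. Full tables are written to sim_out/.
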