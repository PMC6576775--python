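"""Staged AICc model selection over a simulated multi-method survey.

Simulates 150 sites with a strong method effect on detection, generates a
covariate table (study area, access type, distances, tree-loss buffers),
z-scores the continuous columns, and runs the three-stage workflow:
stage 1 tests the method factor, stage 2 screens detection covariates,
stage 3 compares tree-loss buffer scales and psi/theta covariate placements.
"""

from multiscale_occupancy import (
    SimDesign,
    ThreeStageConfig,
    default_method_map,
    run_three_stage,
    simulate_covariates,
    simulate_method_level,
    zscore_covariates,
)

mmap = default_method_map()
cov = simulate_covariates(150, mmap, seed=7)
cov, _ = zscore_covariates(cov, ["Loss100m", "Loss500m", "Loss1k", "Loss5k",
                                 "DistAve", "DistMax", "DistMin"])

design = SimDesign(n_sites=150, occasions=(16, 23), psi_true=0.7,
                   theta_true=0.4, p_true=(0.15, 0.45, 0.70, 0.40, 0.60),
                   seed=11)
pooled, _ = simulate_method_level(design, mmap)

result = run_three_stage(pooled, cov, ThreeStageConfig(n_starts=2, seed=3))

print("stage 1 (method factor vs constant detection):")
print(result.stage1.table[["model", "K", "dAICc", "weight"]].round(3)
      .to_string(index=False))
print("\nstage 2 top models (detection covariates):")
print(result.stage2.table[["model", "dAICc", "weight"]].head(4).round(3)
      .to_string(index=False))
print(f"\nbest-supported tree-loss buffer: {result.best_buffer}")
print(f"final model: {result.final_fit.model_id}")
print("\nmodel-averaged detection per method (unconditional SEs):")
print(result.averaged_detection.round(3))
# With the generating method effect, stage 1 should leave p(.) far behind
# (dAICc >> 2); the averaged per-method detection recovers the generating
# spread (lowest for the single camera, highest for three cameras).
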