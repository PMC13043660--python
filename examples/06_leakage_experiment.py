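"""How selecting genetic features on the full cohort inflates performance.

On a zero-heritability trait, an honest protocol (feature selection inside
each training split) scores near zero, while selecting on the whole cohort
- test folds included - manufactures apparent signal out of pure noise.
"""

import cytopred as cp
from cytopred.ctpredict import DESK_SCALE_CLUMP
from cytopred.evaluate import leakage_experiment

cohort = cp.simulate_cohort(
    cp.SimConfig.null(n_individuals=400, seed=6, n_blocks=125))  # 5000 variants
trait = cohort.cytokines.iloc[:, 0]  # pure noise by construction

report = leakage_experiment(cohort.genotypes, cohort.covariates, trait,
                            model_kind="rf", clump_params=DESK_SCALE_CLUMP,
                            search=False, seed=6)

rho_honest = report.train_only.mean_rho("rf", "combined")
rho_leaky = report.full_cohort.mean_rho("rf", "combined")
print(f"TRAIN_ONLY  mean test Spearman: {rho_honest:+.3f}  (truth: no signal)")
print(f"FULL_COHORT mean test Spearman: {rho_leaky:+.3f}  (leakage artifact)")
print(f"inflation:  {report.mean_delta_rho:+.3f}")
print(f"SNPs-importance inflation: "
      f"{report.delta_snp_importance.mean():+.3f}")
# both deltas should be clearly positive: every unit of them is fictitious
# predictive power created by letting test individuals influence selection
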