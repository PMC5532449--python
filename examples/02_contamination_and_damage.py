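"""Inject outliers into clean factor-model data and watch ML-Normal break.

Ten percent of 500 rows receive a shift h * Lambda_o xi lying in the
orthogonal complement of the loading space (h log-normal).  The normal-
theory chi-square and RMSEA deteriorate sharply; the multivariate-t fit and
the Huber-weighted two-stage fit barely move.
"""

import robustsem as rs

params = rs.generating_parameters()
spec = rs.correct_spec()

clean = rs.generate_clean(500, params, seed=2)
bad = rs.apply_outliers(clean, epsilon=0.10, seed=3)
print(f"{len(bad.modified_rows)} of {bad.n} rows modified")

for label, data in [("clean", clean.data), ("contaminated", bad.data)]:
    fit = rs.fit_ml_normal(data, spec)
    rep = rs.fit_index_report(
        fit, rs.fit_saturated_normal(data), rs.fit_baseline_normal(data)
    )
    print(f"ML-Normal on {label:>12}: {rep.summary()}")

fit_t = rs.fit_ml_t(bad.data, spec)
rep_t = rs.fit_index_report(
    fit_t, rs.fit_saturated_t(bad.data), rs.fit_baseline_t(bad.data)
)
print(f"ML-t      on contaminated: {rep_t.summary()}"
      f"  (df estimate {fit_t.params.df:.1f})")

fit_r = rs.fit_tsr(bad.data, spec, phi=0.10)
mom = (fit_r.sample_mean, fit_r.sample_cov, 500)
rep_r = rs.fit_index_report(
    fit_r, rs.fit_saturated_normal(mom), rs.fit_baseline_normal(mom)
)
print(f"TSR       on contaminated: {rep_r.summary()}  (uncorrected statistic)")
print()
print("The normal-theory chi-square inflates under contamination while the")
print("t-based and Huber-weighted fits stay near their clean-data values;")
print("a small t df estimate flags the heavy tails.")
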