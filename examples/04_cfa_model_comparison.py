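"""Fit the four candidate structures and compare them.

One-factor, two-factor (correlated), four-factor (correlated) and bifactor
models are fitted by maximum likelihood to a simulated bifactor cohort; the
fit battery (chi-square, CFI, TLI, RMSEA with 90% CI, SRMR) and the nested
four-factor-vs-bifactor likelihood-ratio test are printed.
"""

import promstruct as ps

pop = ps.default_population()
data = ps.simulate(ps.SimulationConfig(n_respondents=5000, seed=314, population=pop))
moments = ps.sample_moments(data)
baseline = ps.baseline_model(moments)

fits = {}
print(f"{'model':12s} {'chisq':>9s} {'df':>4s} {'CFI':>6s} {'TLI':>6s} {'RMSEA':>6s} {'SRMR':>6s}")
for name, make in ps.MODEL_FIXTURES.items():
    fit = ps.fit_ml(make(), moments)
    ix = ps.compute_indices(fit, moments, baseline)
    fits[name] = fit
    print(f"{name:12s} {ix.chisq:9.2f} {ix.df:4d} {ix.cfi:6.3f} {ix.tli:6.3f} "
          f"{ix.rmsea:6.3f} {ix.srmr:6.3f}")

test = ps.chisq_difference_test(fits["four_factor"], fits["bifactor"])
print(f"\nnested test (four-factor vs bifactor): delta chisq = "
      f"{test.delta_chisq:.2f} on {test.delta_df} df, p = {test.p_value:.3g}")
print("The data were generated from the bifactor model, so it should fit "
      "best (highest CFI/TLI, lowest RMSEA/SRMR); the misspecified one- and "
      "two-factor structures show clearly inadequate fit (CFI/TLI < 0.9).")

mis = ps.modification_indices(fits["one_factor"], moments)[:3]
print("\ntop modification indices for the one-factor model "
      "(residual pairs the model wants freed):")
for m in mis:
    print(f"  {m.parameter:12s} expected chisq drop {m.expected_chisq_drop:7.1f}")
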