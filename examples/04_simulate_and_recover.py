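"""Forward-simulate a campaign and check the pipeline recovers the truth.

Draws a deep-Mediterranean ground-truth scenario, emits noisy raw
observations (replicate DPM counts, blanks, ETS assays, cell counts and a
dilution series), analyses them with the same estimators used on real
data, and prints recovery diagnostics.
"""

from darkcarbon import (
    analyze_campaign,
    estimate_isotope_dilution,
    make_scenario,
    recovery_report,
    simulate_campaign,
)

scenario = make_scenario("mediterranean-deep", seed=42)
obs = simulate_campaign(scenario)

est = analyze_campaign(obs)
print(recovery_report(scenario, est).round(4))
# relative_bias ~ 0 and rmse ~ the 5% replicate CV / sqrt(replicates):
# the estimators add no systematic error of their own.

fit = estimate_isotope_dilution(obs.dilution_series)
print(f"\nrecovered leucine isotope dilution: {fit.isotope_dilution:.2f} "
      f"(truth {1 + scenario.true_kt_plus_sn / 5.0:.2f})")
# The kinetic t/f linearisation amplifies counting noise, so a single
# series scatters noticeably around the truth; campaigns average several.
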