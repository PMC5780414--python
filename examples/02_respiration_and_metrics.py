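"""ETS respiration and the per-depth community carbon budget.

Converts an electron-transport-system assay into prokaryotic respiration
(PR), then assembles the derived metrics for one bathypelagic sample.
"""

from darkcarbon import DepthSample, ETSMeasurement, derive_metrics, pr_from_ets

# Potential respiration measured at 18 °C in the lab, corrected to the
# 13.9 °C in-situ water by the Arrhenius factor, scaled by the PR:ETS
# calibration (0.68) and the O2->C remineralisation stoichiometry.
ets = ETSMeasurement(ets_assay_rate=145.0, assay_temperature=18.0, insitu_temperature=13.9)
pr = pr_from_ets(ets)
print(f"PR = {pr:.0f} µg C m⁻³ d⁻¹")

# A 3,000 m sample: slow heterotrophic production, moderate dark fixation,
# sparse cells — the deep-sea regime where per-cell activity peaks.
sample = DepthSample(
    "demo", 3000.0, pa=53e3, php=6.7, pr=570.0, abd=207.0,
)
m = derive_metrics(sample)
print(f"PCD  = {m.pcd:.1f} µg C m⁻³ d⁻¹   (carbon demand = PHP + PR)")
print(f"PGE  = {100 * m.pge:.1f} %            (growth efficiency)")
print(f"csPCD = {m.cs_pcd:.2f}, csABD = {m.cs_abd:.2f} fg C cell⁻¹ d⁻¹")
print(f"ABD covers {m.abd_of_pcd:.0f} % of the community carbon demand")
lo, hi = m.generation_time
print(f"autotroph generation time: {lo:.1f}-{hi:.1f} d for 10-20 fg C per cell")
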