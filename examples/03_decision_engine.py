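"""From diagnostics to an equation recommendation, with the rule trace."""

from isofoodweb import (
    DistinctnessReport,
    ViolationSummary,
    recommend_equations,
)

# Scenario: clearly distinct baselines, 40% of raw LCU values outside
# [0, 1] (baselines under-bracket the fish), and baseline taxa that sit at
# different assumed trophic positions (e.g. oligochaete 2.5 vs mussel 2.0).
distinctness = (
    DistinctnessReport(isotope="d13c", statistic=400.0, p_value=1e-9, distinct=True),
    DistinctnessReport(isotope="d15n", statistic=380.0, p_value=1e-6, distinct=True),
)
violations = ViolationSummary(
    n_total=100, n_above_1=35, n_below_0=5, pct_outside=40.0,
    exceeds_threshold=True,
)

rec = recommend_equations(distinctness, violations, lambdas_equal=False)
print(f"resource-use metric : {rec.ru_method}")
print(f"TP equation         : {rec.tp_method}")
print(f"alpha source        : {rec.alpha_source}")
print("rationale:")
for line in rec.rationale:
    print(f"  - {line}")

# With >5% of fish outside the mixing bounds, raw LCU is replaced by the
# min-max rescaled variant; unequal baseline lambdas select the
# absolute-lambda two-source TP, with the rescaled LCU as its alpha.
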