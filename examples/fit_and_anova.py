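"""Fit the blocked quadratic model to the published 20-run sheet.

Refits total polyphenol content (mg GAE/g DW) on the coded factors and
prints the coded equation, the full ANOVA with the lack-of-fit test,
and the adequacy statistics. Refitting the printed runs does not
exactly reproduce the published coefficients (a documented
transcription discrepancy in the source tables); the printed-equation
identities are exercised separately in examples/optimize_conditions.py.
"""

import phytorsm as pr

data = pr.datasets.tpc_response_data()
model = pr.fit_quadratic(data)

print("Coded equation (A = time, B = temperature, C = ratio):")
print("  TPC =", pr.coded_equation(model))
print(f"  block effects: {model.block_effects}")
print()
table = pr.anova(model, data)
print(table.table.round(4).to_string(index=False))
print()
a = pr.adequacy(model, data)
print(f"R^2 = {a.r2:.4f}, adjusted R^2 = {a.adj_r2:.4f}, "
      f"CV% = {a.cv_percent:.2f}, adequate precision = {a.adeq_precision:.2f}")
# Adequate precision > 4 means the fitted surface carries enough signal
# relative to its average prediction noise to navigate the design space.
# The lack-of-fit p tests model adequacy against pure (replicate) error.
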