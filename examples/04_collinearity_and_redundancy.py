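"""Collinearity diagnostics on a part-whole predictor block.

The leukocyte count (WBC) is the noisy sum of five cell-type counts, so WBC
and its largest component NEU are almost interchangeable in a regression.
Variance inflation factors quantify this; the rule engine proposes the
standard reparameterization WBC_NONEU = WBC - NEU, which removes the
collinearity while keeping both coefficients interpretable.
"""

from idascreen import redundancy_analysis, run_screening, vif
from idascreen.synthetic import (
    default_bacteremia_like_spec,
    default_plan,
    generate_synthetic_study,
)

spec = default_bacteremia_like_spec(seed=11, n_rows=2000)
dictionary, ds, _ = generate_synthetic_study(spec)
plan = default_plan(dictionary, seed=11)

members = ["WBC", "NEU", "LYM", "MONO", "ALB", "CA"]
res = vif(ds, members, dictionary, plan, basis="linear")
print("VIF (linear basis, complete cases):")
for name in members:
    print(f"  {name:<5} {res.vif[name]:8.2f}")
print("\nWBC and NEU inflate far beyond the flag threshold of 5; the "
      "independent labs ALB and CA sit near 1.")

red = redundancy_analysis(ds, members, dictionary, plan)
print("\nRedundancy analysis (additive spline fits, remove while R^2 > 0.9):")
for var, r2 in red.removal_sequence:
    print(f"  removed {var} at R^2 = {r2:.3f}")

bundle = run_screening(ds, dictionary, plan)
for f in bundle.findings:
    if f.rule_id == "PART_WHOLE_REPARAM":
        print(f"\nproposed amendment: {f.derived.formula}")
        print(f"  evidence: Spearman rho = {f.evidence['spearman']:.3f}")
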