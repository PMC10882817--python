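"""Run the whole pipeline with one config and inspect the JSON report.

Every stage (preprocess, overlap, field-unique, transmission, compartment
attribution, ordination) lands in one machine-readable report keyed by the
parameters and seed that produced it.
"""

import json

from tubertrace import RunConfig, run_pipeline

config = RunConfig(seed=42, rarefaction_depth=2000, n_permutations=199)
report = run_pipeline(config)

print("stages:", ", ".join(sorted(report["stages"])))
tr = report["stages"]["transmission"]["daughter_tuber"]
print(f"seed tuber -> daughter tuber: {tr['n_shared']} shared, "
      f"{tr['n_lost']} lost, {tr['n_acquired']} acquired")
print(f"  destination abundance shared/acquired: "
      f"{tr['dest_abundance']['shared']:.2f} / "
      f"{tr['dest_abundance']['acquired']:.2f}")
perm = report["stages"]["ordination"]["permanova"][0]
print(f"PERMANOVA {perm['factor']}: R2 = {perm['R2']:.2f}, p = {perm['p']:.3f}")
print(json.dumps(report["stages"]["field_unique"], indent=2))
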