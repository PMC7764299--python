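"""DMR calling and splice-site-anchored methylation profiles.

Simulates diagnosis and control methylomes in which retained introns carry a
0.3 methylation dip, calls DMRs between the groups, and builds the
retained vs non-retained metaprofiles around splice sites.
"""

import numpy as np

from intronret import (
    CohortConfig, build_truth, call_dmrs, profile_group_test,
    simulate_methylome, splice_anchor_profile,
)

cfg = CohortConfig(
    n_samples={"diagnosis": 3, "remission": 0, "control": 3},
    m0=0.8, dip_depth=0.3, affected_intron_length=800,
)
truth = build_truth(cfg, seed=3)
sheet = truth.sample_sheet
tracks = {s: simulate_methylome(truth, s) for s in sheet["sample"]}
diag = [tracks[s] for s in sheet.query("condition == 'diagnosis'")["sample"]]
ctrl = [tracks[s] for s in sheet.query("condition == 'control'")["sample"]]

dmrs = call_dmrs(diag, ctrl)
print(f"{len(dmrs)} DMRs between diagnosis and control "
      f"(mean delta {dmrs['delta'].mean():+.3f}); the planted dip sits over "
      f"the {len(truth.affected_introns)} retained introns.")

retained_ids = set(truth.retained_intron_ids("diagnosis"))
retained = [iv for iv in truth.introns if iv.intron_id in retained_ids]
non_retained = [iv for iv in truth.introns if iv.intron_id not in retained_ids]
prof = splice_anchor_profile(diag, retained, non_retained)
for anchor in ("5ss", "centre", "3ss"):
    sub = prof[prof["anchor"] == anchor]
    vals = {
        g: np.average(s["meth"], weights=s["coverage"])
        for g, s in sub.groupby("group")
    }
    print(f"{anchor:>6}: retained {vals['retained']:.3f} "
          f"vs non-retained {vals['non_retained']:.3f}")
tests = profile_group_test(diag, retained, non_retained)
print(tests.to_string(index=False, float_format="%.3g"))
print()
print("Retained-intron methylation is depressed in the intron body (centre")
print("anchor) but not in the exonic flanks; the group test quantifies this")
print("per anchor with a binomial GLM.")
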