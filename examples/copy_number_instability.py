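"""Copy-number gain/loss calls and the copy-number instability (CNI) score.

Simulates a 30-sample normal panel and two tumors over a 200-region target
grid — one diploid, one with 10% of regions amplified to CN 6 — and runs the
full correction / log2-ratio / Z-score / retention pipeline.
"""

import numpy as np

from somaticmetrics import analyze_sample
from somaticmetrics.simulate import simulate_region_counts

cn_amplified = {i: 6 for i in range(20)}  # 10% of 200 regions at CN 6
tumors, panel = simulate_region_counts(
    200, 30, {"DIPLOID": {}, "AMPLIFIED": cn_amplified}, seed=13
)

for sid in ("DIPLOID", "AMPLIFIED"):
    profile, cni = analyze_sample(tumors[sid], panel)
    print(f"{sid}:")
    print(f"  gains {profile.n_gain}, losses {profile.n_loss}, "
          f"CNV burden {profile.burden:.3f}")
    print(f"  regions above Z threshold: {int(cni.retained.sum())}, "
          f"median threshold {float(np.median(cni.thresholds)):.2f}")
    print(f"  CNI score: {cni.cni:.1f}")

print(
    "\nRead rates are corrected for GC and region length, turned into log2 "
    "ratios against the panel mean, and standardized into Z-scores against "
    "the panel's leave-one-out spread. Regions with CN > 4 are gains, "
    "CN < 1.2 losses; the CNI score sums Z-scores above the per-region "
    "P95 + 2*SD panel threshold, so a diploid genome scores near zero."
)
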