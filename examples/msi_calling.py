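"""Call microsatellite instability from STR allele-count histograms.

Builds a 30-sample normal panel over 12 STR loci, derives the per-locus
baseline (mean and SD of detectable allele counts), then calls one planted
MSI-H tumor and one microsatellite-stable tumor against it.
"""

from somaticmetrics import build_baseline, call_sample
from somaticmetrics.simulate import default_str_loci, simulate_str_panel

loci = default_str_loci(12, seed=3)
panel, tumors = simulate_str_panel(
    30, loci, {"TUMOR_A": "MSI-H", "TUMOR_B": "MSS"}, seed=3
)

baseline = build_baseline(panel)
print("baseline (per locus: mean alleles, SD, instability threshold mean+4*SD):")
for locus_id, entry in list(baseline.loci.items())[:4]:
    print(
        f"  {locus_id}: mean {entry.mean_allele_count:.2f}, SD "
        f"{entry.sd_allele_count:.2f}, threshold {baseline.threshold(locus_id):.2f}"
    )
print(f"  ... {len(baseline.loci)} loci total\n")

for sid in ("TUMOR_A", "TUMOR_B"):
    call = call_sample(tumors[sid], baseline, sid)
    print(
        f"{sid}: {call.n_unstable} unstable / {call.n_stable} stable loci "
        f"-> {call.status}"
    )
print(
    "\nA locus is unstable when its detectable allele count exceeds the "
    "baseline mean + 4*SD; a sample is MSI-H with >= 2 unstable loci, MSS "
    "with >= 4 stable loci, otherwise QNS (insufficient evaluable loci)."
)
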