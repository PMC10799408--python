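"""Full cohort run: simulate, filter, measure, and contrast two arms.

Generates a 12-sample cohort shaped like a treatment-sensitivity study (a
sensitive arm with a C>A-dominant spectrum, an insensitive arm C>T-dominant
with one MSI-H sample and three copy-number-altered samples), computes every
per-sample metric, and contrasts the arms.
"""

import tempfile

from somaticmetrics import TmbConfig, build_baseline, run_cohort_analysis
from somaticmetrics.simulate import (
    CohortConfig,
    GroupSpec,
    dominant_spectrum,
    simulate_cohort,
)

config = CohortConfig(
    groups=[
        GroupSpec("SENSITIVE", 6, dominant_spectrum("C>A", 0.7)),
        GroupSpec(
            "INSENSITIVE", 6, dominant_spectrum("C>T", 0.7), n_msi_h=1, n_cn_altered=3
        ),
    ]
)
cohort = simulate_cohort(config, seed=17)
baseline = build_baseline(cohort.str_panel)

with tempfile.TemporaryDirectory() as out_dir:
    metrics, comparisons, spectra = run_cohort_analysis(
        cohort.variants,
        cohort.truth.groups,
        TmbConfig(exon_bases=34_000_000),
        out_dir=out_dir,
        str_by_sample=cohort.str_tumors,
        msi_baseline=baseline,
        region_tumors=cohort.region_tumors,
        region_panel=cohort.region_panel,
    )
    print((open(f"{out_dir}/summary.txt").read()))

print(
    "Dominant classes recover the planted spectra; the TiTv rank-sum p "
    "contrasts per-sample transition fractions between arms; MSI-H and "
    "CNI/CNV differences reflect the planted instability. P-values are raw "
    "and descriptive at these sample sizes."
)
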