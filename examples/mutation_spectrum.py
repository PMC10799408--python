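"""Six-class mutation spectrum and transition/transversion imbalance.

Simulates one C>T-dominant tumor, collapses its SNVs onto the pyrimidine
strand, and tests whether transitions are enriched beyond the 1/3 expected
under a uniform spectrum.
"""

from somaticmetrics import summarize_spectrum, titv_imbalance_test
from somaticmetrics.simulate import VariantSimConfig, dominant_spectrum, simulate_variants

config = VariantSimConfig(
    n_variants=300, spectrum=dominant_spectrum("C>T", 0.7), indel_fraction=0.0
)
records, _ = simulate_variants("DEMO", config, seed=11)

summary = summarize_spectrum(records)
print("six-class substitution counts (pyrimidine strand):")
for cls, n in summary.class_counts.items():
    print(f"  {cls}: {n}")
print(f"\ntransitions (C>T + T>C) : {summary.ti_count}")
print(f"transversions           : {summary.tv_count}")
print(f"Ti fraction             : {summary.ti_fraction:.3f}  (null expectation 1/3)")
p = titv_imbalance_test(summary)
print(f"exact binomial p        : {p:.3g}")
print(
    "\nA small p means the transition/transversion balance deviates from what "
    "a uniform spectrum would produce — here driven by the planted C>T excess."
)
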