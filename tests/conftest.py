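import pytest

from somaticmetrics import VariantRecord


def make_variant(**overrides) -> VariantRecord:
    """A missense SNV engineered to pass every filter criterion."""
    fields = dict(
        sample_id="S1",
        chrom="chr1",
        pos=1_000_000,
        ref_allele="C",
        alt_allele="T",
        variant_type="SNP",
        variant_class="missense",
        region_class="exonic",
        gene="TP53",
        depth=200,
        alt_fwd=30,
        alt_rev=28,
        tumor_vaf=0.29,
        control_vaf=0.0,
        in_cosmic=True,
        in_snp138=False,
        polyphen_div="D",
        polyphen_var="D",
        popmax_af=0.0,
        is_hotspot=False,
        in_blacklist=False,
    )
    fields.update(overrides)
    return VariantRecord(**fields)


@pytest.fixture
def clean_variant() -> VariantRecord:
    return make_variant()


#: One engineered violator per removal reason; each triggers exactly
#: that criterion and no other.
VIOLATION_FIXTURES = {
    "low_depth": dict(depth=20, alt_fwd=5, alt_rev=5, tumor_vaf=0.5),
    "blacklist": dict(in_blacklist=True),
    "intronic": dict(region_class="intronic"),
    "nonsense": dict(variant_class="nonsense"),
    "db_absent": dict(in_cosmic=False, in_snp138=False),
    "hla_or_none_gene": dict(gene="HLA-A"),
    "polyphen_benign": dict(polyphen_div="B", polyphen_var="B"),
    "population_af": dict(popmax_af=0.01),
    "strand_support": dict(alt_fwd=0, alt_rev=58),
    "vaf_support": dict(tumor_vaf=0.02, alt_fwd=2, alt_rev=2),
}


@pytest.fixture
def audit_table():
    """10 variants each violating one distinct criterion, plus 1 clean survivor."""
    violators = [
        (reason, make_variant(pos=1_000_000 + i, **overrides))
        for i, (reason, overrides) in enumerate(VIOLATION_FIXTURES.items())
    ]
    return violators, make_variant(pos=42)
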