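"""Seeded synthetic tumor/normal cohorts with a ground-truth manifest.

The generator stands in for controlled-access patient data. It emulates the
statistical structure the downstream modules assume, at desk scale:

* **Variant tables** — per sample, SNVs drawn multinomially over the six
  pyrimidine-collapsed substitution classes and rendered on a random strand
  (so strand collapsing is exercised), plus a configurable indel fraction.
  Depths are negative binomial (WES-like overdispersion, mean 200), VAFs are
  Beta, strand splits binomial. A configurable fraction of variants is
  engineered to violate exactly one named filter criterion; every violation
  is recorded in the truth manifest.
* **STR histograms** — a panel of normal samples whose per-locus detectable
  allele counts are rounded-Gaussian, rendered as read histograms that pass
  allele QC (depth > 100x); MSI-H tumors inflate allele counts beyond
  mean + 4*SD at designated loci, MSS tumors draw from the normal model.
* **Region read counts** — a shared target-region grid with Uniform(0.3,
  0.7) GC, counts Poisson around length x GC-bias x (CN/2); the normal panel
  sits at CN 2 throughout, tumors follow an integer copy-number truth.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence` spawn keys, one child stream per sample,
so any single sample is reproducible in isolation and outputs are
byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .model import (
    SUBSTITUTION_CLASSES,
    CohortGroup,
    RegionCount,
    StrLocusHistogram,
    VariantRecord,
)
from . import io as smio

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Filter criteria the generator can plant, with the reason label they trigger.
PLANTABLE_VIOLATIONS = (
    "low_depth",
    "blacklist",
    "intronic",
    "nonsense",
    "db_absent",
    "hla_or_none_gene",
    "polyphen_benign",
    "population_af",
    "strand_support",
    "vaf_support",
)

_GENE_POOL = (
    "TP53", "PIK3CA", "ERBB2", "APOB", "BRCA1", "BRCA2", "GATA3", "MAP3K1",
    "CDH1", "PTEN", "AKT1", "TBC1D32", "XAB2", "KMT2C", "NCOR1", "RUNX1",
)

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))


def uniform_spectrum() -> dict[str, float]:
    return {c: 1.0 / 6.0 for c in SUBSTITUTION_CLASSES}


def dominant_spectrum(dominant: str, weight: float = 0.7) -> dict[str, float]:
    """A spectrum with one dominant class and the rest uniform."""
    if dominant not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown class {dominant!r}")
    rest = (1.0 - weight) / 5.0
    return {c: (weight if c == dominant else rest) for c in SUBSTITUTION_CLASSES}


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    group: str
    spectrum: dict[str, float]
    n_variants: int
    msi_truth: str  # MSI-H / MSS
    cn_truth: dict[int, int]  # region index -> integer CN (absent = 2)
    seed: int
    violations: list[Optional[str]] = field(default_factory=list)  # per variant


@dataclass
class CohortTruth:
    """Manifest of every planted feature of a simulated cohort."""

    seed: int
    samples: dict[str, SampleTruth]
    groups: list[CohortGroup]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "seed": self.seed,
            "groups": {g.label: list(g.sample_ids) for g in self.groups},
            "samples": {
                sid: {
                    "group": t.group,
                    "spectrum": t.spectrum,
                    "n_variants": t.n_variants,
                    "msi_truth": t.msi_truth,
                    "cn_truth": {str(k): v for k, v in t.cn_truth.items()},
                    "seed": t.seed,
                    "violations": t.violations,
                }
                for sid, t in self.samples.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _child_seed(root_seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a root seed and a spawn key."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _rng(root_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=root_seed, spawn_key=key))


def _render_substitution(cls: str, rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # present on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _negbin(rng: np.random.Generator, mean: float, dispersion: float = 10.0) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


@dataclass
class VariantSimConfig:
    """Knobs of the per-sample variant generator."""

    n_variants: int = 300
    spectrum: dict[str, float] = field(default_factory=uniform_spectrum)
    indel_fraction: float = 0.08
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0
    vaf_alpha: float = 2.0
    vaf_beta: float = 5.0
    synonymous_fraction: float = 0.25
    violation_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.spectrum.get(c, 0.0) for c in SUBSTITUTION_CLASSES)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"spectrum proportions sum to {total}, expected 1")
        for reason, rate in self.violation_rates.items():
            if reason not in PLANTABLE_VIOLATIONS:
                raise ValueError(f"unknown violation {reason!r}")
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"violation rate for {reason} outside [0, 1]")
        if sum(self.violation_rates.values()) > 1.0:
            raise ValueError("violation rates sum above 1")


def _clean_variant(
    sample_id: str, cfg: VariantSimConfig, rng: np.random.Generator
) -> VariantRecord:
    """A variant engineered to pass every filter criterion."""
    is_indel = rng.random() < cfg.indel_fraction
    depth = max(60, _negbin(rng, cfg.depth_mean, cfg.depth_dispersion))
    vaf = float(np.clip(rng.beta(cfg.vaf_alpha, cfg.vaf_beta), 0.08, 0.95))
    alt_n = max(6, min(depth, round(vaf * depth)))
    vaf = alt_n / depth
    alt_fwd = int(np.clip(rng.binomial(alt_n, 0.5), 1, alt_n - 1))
    common = dict(
        sample_id=sample_id,
        chrom=str(rng.choice(_CHROMS)),
        pos=int(rng.integers(1, 200_000_000)),
        region_class="exonic",
        gene=str(rng.choice(_GENE_POOL)),
        depth=depth,
        alt_fwd=alt_fwd,
        alt_rev=alt_n - alt_fwd,
        tumor_vaf=vaf,
        control_vaf=0.0,
        in_cosmic=True,
        in_snp138=bool(rng.random() < 0.3),
        popmax_af=0.0,
        is_hotspot=False,
        in_blacklist=False,
    )
    if is_indel:
        ins = rng.random() < 0.5
        base = str(rng.choice(list("ACGT")))
        return VariantRecord(
            ref_allele="-" if ins else base + base,
            alt_allele=base + base if ins else "-",
            variant_type="INS" if ins else "DEL",
            variant_class="frameshift",
            polyphen_div=None,
            polyphen_var=None,
            **common,
        )
    cls = str(
        rng.choice(SUBSTITUTION_CLASSES, p=[cfg.spectrum[c] for c in SUBSTITUTION_CLASSES])
    )
    ref, alt = _render_substitution(cls, rng)
    vclass = "synonymous" if rng.random() < cfg.synonymous_fraction else "missense"
    return VariantRecord(
        ref_allele=ref,
        alt_allele=alt,
        variant_type="SNP",
        variant_class=vclass,
        polyphen_div=str(rng.choice(["D", "P"])),
        polyphen_var=str(rng.choice(["D", "P"])),
        **common,
    )


def _plant_violation(
    v: VariantRecord, reason: str, rng: np.random.Generator
) -> VariantRecord:
    """Modify a clean SNV so it violates exactly the named criterion."""
    import dataclasses

    if reason == "low_depth":
        depth = int(rng.integers(15, 30))
        alt_n = max(6, round(0.5 * depth))
        fwd = int(np.clip(rng.binomial(alt_n, 0.5), 1, alt_n - 1))
        return dataclasses.replace(
            v, depth=depth, alt_fwd=fwd, alt_rev=alt_n - fwd, tumor_vaf=alt_n / depth
        )
    if reason == "blacklist":
        return dataclasses.replace(v, in_blacklist=True)
    if reason == "intronic":
        return dataclasses.replace(v, region_class="intronic")
    if reason == "nonsense":
        return dataclasses.replace(v, variant_class="nonsense")
    if reason == "db_absent":
        return dataclasses.replace(v, in_cosmic=False, in_snp138=False)
    if reason == "hla_or_none_gene":
        return dataclasses.replace(v, gene=str(rng.choice(["HLA-A", "HLA-B", "NONE"])))
    if reason == "polyphen_benign":
        return dataclasses.replace(v, polyphen_div="B", polyphen_var="B")
    if reason == "population_af":
        return dataclasses.replace(v, popmax_af=float(rng.uniform(0.005, 0.05)))
    if reason == "strand_support":
        alt_n = v.alt_fwd + v.alt_rev
        return dataclasses.replace(v, alt_fwd=0, alt_rev=alt_n)
    if reason == "vaf_support":
        depth = max(v.depth, 150)
        return dataclasses.replace(
            v, depth=depth, tumor_vaf=0.02, alt_fwd=1, alt_rev=2
        )
    raise ValueError(f"unknown violation {reason!r}")


def simulate_variants(
    sample_id: str,
    config: VariantSimConfig,
    seed: int,
) -> tuple[list[VariantRecord], list[Optional[str]]]:
    """One sample's variant table plus the per-variant violation truth.

    Returns ``(records, violations)`` where ``violations[i]`` is the planted
    filter criterion of record *i*, or ``None`` for a clean record.
    """
    rng = _rng(seed, 0)
    labels = list(config.violation_rates)
    probs = [config.violation_rates[r] for r in labels]
    probs.append(1.0 - sum(probs))
    labels.append(None)

    records: list[VariantRecord] = []
    violations: list[Optional[str]] = []
    for _ in range(config.n_variants):
        choice = labels[int(rng.choice(len(labels), p=probs))]
        v = _clean_variant(sample_id, config, rng)
        if choice is not None:
            if v.variant_type != "SNP":  # plant violations only on SNVs
                v = _clean_variant(sample_id, config, rng)
                while v.variant_type != "SNP":
                    v = _clean_variant(sample_id, config, rng)
            v = _plant_violation(v, choice, rng)
        records.append(v)
        violations.append(choice)
    return records, violations


@dataclass
class StrLocusModel:
    """Generative parameters of one STR locus in the normal population."""

    locus_id: str
    base_length: int
    mean_alleles: float
    sd_alleles: float


def default_str_loci(n_loci: int = 12, seed: int = 0) -> list[StrLocusModel]:
    rng = _rng(seed, 100)
    loci = []
    for i in range(n_loci):
        loci.append(
            StrLocusModel(
                locus_id=f"STR{i + 1:02d}",
                base_length=int(rng.integers(12, 30)),
                mean_alleles=float(rng.uniform(2.0, 3.5)),
                sd_alleles=float(rng.uniform(0.3, 0.7)),
            )
        )
    return loci


def _render_histogram(
    sample_id: str,
    locus: StrLocusModel,
    n_alleles: int,
    rng: np.random.Generator,
    depth: int = 400,
) -> StrLocusHistogram:
    """Render ``n_alleles`` detectable allele lengths so all pass QC."""
    n_alleles = max(1, n_alleles)
    lengths = [locus.base_length + k for k in range(n_alleles)]
    # top allele gets ~60% of depth; the rest share the remainder evenly,
    # each above both the 2-read and the 5%-of-top QC cuts
    weights = np.array([0.6] + [0.4 / max(1, n_alleles - 1)] * (n_alleles - 1))
    counts = np.maximum(np.round(weights * depth), math.ceil(0.06 * 0.6 * depth)).astype(int)
    noise = rng.integers(0, 5, size=n_alleles)
    return StrLocusHistogram(
        sample_id, locus.locus_id, {l: int(c + n) for l, c, n in zip(lengths, counts, noise)}
    )


def simulate_str_panel(
    n_normals: int,
    loci: Sequence[StrLocusModel],
    msi_truth: Mapping[str, str],
    seed: int,
    n_unstable_loci: int = 3,
    qns_samples: Sequence[str] = (),
) -> tuple[dict[str, list[StrLocusHistogram]], dict[str, list[StrLocusHistogram]]]:
    """Normal-panel and tumor STR histograms.

    ``msi_truth`` maps tumor sample ids to MSI-H or MSS. MSI-H tumors inflate
    the allele count beyond mean + 4*SD at the first ``n_unstable_loci``
    loci; MSS tumors draw from the normal generative model. Samples listed in
    ``qns_samples`` get sub-threshold depth everywhere (not evaluable).
    """
    if n_normals < 2:
        raise ValueError("need at least 2 panel samples")
    panel: dict[str, list[StrLocusHistogram]] = {}
    for i in range(n_normals):
        sid = f"N{i + 1:03d}"
        rng = _rng(seed, 1, i)
        panel[sid] = [
            _render_histogram(
                sid, loc, int(round(rng.normal(loc.mean_alleles, loc.sd_alleles))), rng
            )
            for loc in loci
        ]

    tumors: dict[str, list[StrLocusHistogram]] = {}
    for j, (sid, truth) in enumerate(msi_truth.items()):
        rng = _rng(seed, 2, j)
        hists = []
        for k, loc in enumerate(loci):
            if truth == "MSI-H" and k < n_unstable_loci:
                n = math.ceil(loc.mean_alleles + 4.0 * loc.sd_alleles) + 2
            else:
                n = int(round(rng.normal(loc.mean_alleles, loc.sd_alleles)))
            depth = 50 if sid in qns_samples else 400
            hists.append(_render_histogram(sid, loc, n, rng, depth=depth))
        tumors[sid] = hists
    return panel, tumors


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Unimodal coverage bias peaking near 45% GC (amplicon-like)."""
    return 1.0 - 1.8 * (np.asarray(gc) - 0.45) ** 2


def simulate_region_counts(
    n_regions: int,
    panel_n: int,
    cn_truth: Mapping[str, Mapping[int, int]],
    seed: int,
    gc_model: Callable[[np.ndarray], np.ndarray] = default_gc_bias,
    rate_per_base: float = 0.5,
) -> tuple[dict[str, list[RegionCount]], dict[str, list[RegionCount]]]:
    """Tumor and normal-panel read-count tables over one shared region grid.

    ``cn_truth`` maps tumor sample id -> {region index: integer CN}; absent
    regions are CN 2. The panel is CN 2 throughout. Expected counts scale as
    length x gc_bias(gc) x (CN/2); observed counts are Poisson.
    """
    if n_regions < 20:
        raise ValueError("need at least 20 regions")
    grid_rng = _rng(seed, 3)
    lengths = grid_rng.integers(200, 501, size=n_regions)
    gc = np.round(grid_rng.uniform(0.3, 0.7, size=n_regions), 4)
    starts = np.cumsum(np.concatenate([[1000], lengths[:-1] + 500]))
    bias = gc_model(gc)
    base_mu = rate_per_base * lengths * bias

    def sample_regions(sid: str, cn: Mapping[int, int], stream: int, idx: int):
        rng = _rng(seed, stream, idx)
        mult = np.ones(n_regions)
        for region_idx, c in cn.items():
            mult[int(region_idx)] = c / 2.0
        counts = rng.poisson(base_mu * mult)
        return [
            RegionCount(
                sample_id=sid,
                chrom="chr1",
                start=int(starts[i]),
                end=int(starts[i] + lengths[i]),
                gc_fraction=float(gc[i]),
                read_count=int(counts[i]),
            )
            for i in range(n_regions)
        ]

    panel = {
        f"N{i + 1:03d}": sample_regions(f"N{i + 1:03d}", {}, 4, i) for i in range(panel_n)
    }
    tumors = {
        sid: sample_regions(sid, cn, 5, j) for j, (sid, cn) in enumerate(cn_truth.items())
    }
    return tumors, panel


@dataclass
class GroupSpec:
    """One cohort group's generative truth."""

    label: str
    n_samples: int
    spectrum: dict[str, float] = field(default_factory=uniform_spectrum)
    n_variants: int = 300
    n_msi_h: int = 0
    n_cn_altered: int = 0
    cn_altered_fraction: float = 0.10
    cn_altered_value: int = 6


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    Defaults mirror the study design the pipeline targets: two groups of six
    tumors (treatment-sensitive vs -insensitive), a C>A-dominant spectrum in
    the sensitive group and C>T-dominant in the insensitive one, one MSI-H
    sample in the insensitive group, a 30-sample normal panel for
    copy-number work, and a 12-locus STR panel.
    """

    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("HE", 6, dominant_spectrum("C>A", 0.7)),
            GroupSpec("HI", 6, dominant_spectrum("C>T", 0.7), n_msi_h=1),
        ]
    )
    n_regions: int = 200
    region_panel_n: int = 30
    str_panel_n: int = 30
    n_str_loci: int = 12
    violation_rates: dict[str, float] = field(
        default_factory=lambda: {r: 0.02 for r in PLANTABLE_VIOLATIONS}
    )


@dataclass
class SimulatedCohort:
    """In-memory bundle of everything one simulation produced."""

    truth: CohortTruth
    variants: dict[str, list[VariantRecord]]
    str_panel: dict[str, list[StrLocusHistogram]]
    str_tumors: dict[str, list[StrLocusHistogram]]
    region_tumors: dict[str, list[RegionCount]]
    region_panel: dict[str, list[RegionCount]]

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_variants = [v for sid in self.variants for v in self.variants[sid]]
        smio.write_variant_table(all_variants, out / "variants.tsv")
        smio.write_str_histograms(self.str_panel, out / "str_panel.tsv")
        smio.write_str_histograms(self.str_tumors, out / "str_tumors.tsv")
        merged = dict(self.region_tumors)
        merged.update(self.region_panel)
        smio.write_region_counts(merged, out / "region_counts.tsv")
        smio.write_groups(self.truth.groups, out / "groups.tsv")
        self.truth.to_json(out / "truth.json")


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate a full cohort: variants, STR histograms, region counts, truth."""
    cfg = config or CohortConfig()
    rng_regions = _rng(seed, 6)

    sample_truths: dict[str, SampleTruth] = {}
    groups: list[CohortGroup] = []
    counter = 0
    for g in cfg.groups:
        ids = []
        for k in range(g.n_samples):
            counter += 1
            sid = f"S{counter:02d}"
            ids.append(sid)
            cn_truth: dict[int, int] = {}
            if k < g.n_cn_altered:
                n_alt = int(round(g.cn_altered_fraction * cfg.n_regions))
                chosen = rng_regions.choice(cfg.n_regions, size=n_alt, replace=False)
                cn_truth = {int(i): g.cn_altered_value for i in sorted(chosen)}
            sample_truths[sid] = SampleTruth(
                sample_id=sid,
                group=g.label,
                spectrum=dict(g.spectrum),
                n_variants=g.n_variants,
                msi_truth="MSI-H" if k < g.n_msi_h else "MSS",
                cn_truth=cn_truth,
                seed=_child_seed(seed, 7, counter),
            )
        groups.append(CohortGroup(g.label, tuple(ids)))

    variants: dict[str, list[VariantRecord]] = {}
    for sid, truth in sample_truths.items():
        vcfg = VariantSimConfig(
            n_variants=truth.n_variants,
            spectrum=truth.spectrum,
            violation_rates=dict(cfg.violation_rates),
        )
        recs, violations = simulate_variants(sid, vcfg, truth.seed)
        variants[sid] = recs
        truth.violations = violations

    loci = default_str_loci(cfg.n_str_loci, seed)
    msi_truth = {sid: t.msi_truth for sid, t in sample_truths.items()}
    str_panel, str_tumors = simulate_str_panel(
        cfg.str_panel_n, loci, msi_truth, seed
    )

    cn_truth_map = {sid: t.cn_truth for sid, t in sample_truths.items()}
    region_tumors, region_panel = simulate_region_counts(
        cfg.n_regions, cfg.region_panel_n, cn_truth_map, seed
    )

    return SimulatedCohort(
        truth=CohortTruth(seed=seed, samples=sample_truths, groups=groups),
        variants=variants,
        str_panel=str_panel,
        str_tumors=str_tumors,
        region_tumors=region_tumors,
        region_panel=region_panel,
    )
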