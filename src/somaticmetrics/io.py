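"""Readers and writers for the three tabular input formats and config/groups files.

All tables are plain TSV with a header row. ``"."`` denotes a missing value.
Variant tables are 1-based; region-count tables are BED-like, 0-based
half-open. Parsers never silently drop rows: malformed rows raise with the
offending row number, and absent optional columns are filled with documented
defaults under a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .model import (
    CohortGroup,
    FilterConfig,
    RegionCount,
    StrLocusHistogram,
    VariantRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Documented column order of the variant table.
VARIANT_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_type",
    "variant_class",
    "region_class",
    "gene",
    "depth",
    "alt_fwd",
    "alt_rev",
    "tumor_vaf",
    "control_vaf",
    "in_cosmic",
    "in_snp138",
    "polyphen_div",
    "polyphen_var",
    "popmax_af",
    "is_hotspot",
    "in_blacklist",
)

MANDATORY_VARIANT_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "depth",
    "tumor_vaf",
)

MISSING = "."

_BOOL_TRUE = {"1", "true", "True", "TRUE"}
_BOOL_FALSE = {"0", "false", "False", "FALSE", MISSING}


def _parse_bool(value: str, column: str, row: int) -> bool:
    if value in _BOOL_TRUE:
        return True
    if value in _BOOL_FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {column}={value!r}")


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"row {row}: cannot parse integer {column}={value!r}") from None


def _parse_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"row {row}: cannot parse number {column}={value!r}") from None


def _infer_variant_type(ref: str, alt: str) -> str:
    if ref == "-" or len(alt) > len(ref):
        return "INS"
    if alt == "-" or len(ref) > len(alt):
        return "DEL"
    return "SNP"


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_variant_table(path: PathLike) -> list[VariantRecord]:
    """Read an annotated somatic variant table (TSV, 1-based coordinates).

    Missing optional annotation columns are filled with their documented
    defaults (missing/false) and a warning is logged. A missing mandatory
    column or an unparsable numeric field is a hard error.
    """
    df = _read_tsv(path)
    for col in MANDATORY_VARIANT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    absent = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if absent:
        logger.warning(
            "%s: optional columns %s absent; using missing/false defaults",
            path,
            ", ".join(absent),
        )

    records: list[VariantRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def get(col: str, default: str = MISSING) -> str:
            return str(row.get(col, default))

        ref = get("ref_allele")
        alt = get("alt_allele")
        vtype = get("variant_type")
        if vtype == MISSING:
            vtype = _infer_variant_type(ref, alt)
        popmax = get("popmax_af")
        pp_div = get("polyphen_div")
        pp_var = get("polyphen_var")
        try:
            rec = VariantRecord(
                sample_id=get("sample_id"),
                chrom=get("chrom"),
                pos=_parse_int(get("pos"), "pos", i),
                ref_allele=ref,
                alt_allele=alt,
                variant_type=vtype,
                variant_class=get("variant_class", "other").replace(MISSING, "other"),
                region_class=get("region_class", "exonic").replace(MISSING, "exonic"),
                gene=get("gene", "NONE").replace(MISSING, "NONE"),
                depth=_parse_int(get("depth"), "depth", i),
                alt_fwd=_parse_int(get("alt_fwd", "0").replace(MISSING, "0"), "alt_fwd", i),
                alt_rev=_parse_int(get("alt_rev", "0").replace(MISSING, "0"), "alt_rev", i),
                tumor_vaf=_parse_float(get("tumor_vaf"), "tumor_vaf", i),
                control_vaf=_parse_float(
                    get("control_vaf", "0").replace(MISSING, "0"), "control_vaf", i
                ),
                in_cosmic=_parse_bool(get("in_cosmic"), "in_cosmic", i),
                in_snp138=_parse_bool(get("in_snp138"), "in_snp138", i),
                polyphen_div=None if pp_div == MISSING else pp_div,
                polyphen_var=None if pp_var == MISSING else pp_var,
                popmax_af=None if popmax == MISSING else _parse_float(popmax, "popmax_af", i),
                is_hotspot=_parse_bool(get("is_hotspot"), "is_hotspot", i),
                in_blacklist=_parse_bool(get("in_blacklist"), "in_blacklist", i),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from None
        records.append(rec)
    return records


def _format_value(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_variant_table(records: Iterable[VariantRecord], path: PathLike) -> None:
    """Write variant records as TSV in the documented column order."""
    rows = [
        {col: _format_value(getattr(rec, col)) for col in VARIANT_COLUMNS}
        for rec in records
    ]
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_str_histograms(path: PathLike) -> dict[str, list[StrLocusHistogram]]:
    """Read STR allele-length histograms grouped per sample.

    Rows sharing (sample, locus, allele_length) are summed. Loci absent from a
    downstream baseline are accepted here; the MSI caller marks them
    not-evaluable.
    """
    df = _read_tsv(path)
    expected = ("sample_id", "locus_id", "allele_length", "read_count")
    for col in expected:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")

    result: dict[str, dict[str, StrLocusHistogram]] = {}
    for i, row in enumerate(df.to_dict("records"), start=1):
        sample = str(row["sample_id"])
        locus = str(row["locus_id"])
        length = _parse_int(str(row["allele_length"]), "allele_length", i)
        count = _parse_int(str(row["read_count"]), "read_count", i)
        if count < 0:
            raise ValueError(f"{path}: row {i}: negative read_count {count}")
        by_locus = result.setdefault(sample, {})
        hist = by_locus.setdefault(locus, StrLocusHistogram(sample, locus, {}))
        hist.counts[length] = hist.counts.get(length, 0) + count
    return {sample: list(hists.values()) for sample, hists in result.items()}


def write_str_histograms(
    histograms: Mapping[str, Sequence[StrLocusHistogram]], path: PathLike
) -> None:
    rows = []
    for sample in histograms:
        for hist in histograms[sample]:
            for length in sorted(hist.counts):
                rows.append(
                    {
                        "sample_id": sample,
                        "locus_id": hist.locus_id,
                        "allele_length": length,
                        "read_count": hist.counts[length],
                    }
                )
    pd.DataFrame(
        rows, columns=["sample_id", "locus_id", "allele_length", "read_count"]
    ).to_csv(path, sep="\t", index=False)


def read_region_counts(path: PathLike) -> dict[str, list[RegionCount]]:
    """Read BED-like per-region read counts, one region set shared by all samples.

    Regions are returned sorted by (chrom, start). A region present in one
    sample but not another is a hard error naming the first discrepancy.
    """
    df = _read_tsv(path)
    expected = ("chrom", "start", "end", "gc_fraction", "read_count", "sample_id")
    for col in expected:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")

    result: dict[str, list[RegionCount]] = {}
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            rec = RegionCount(
                sample_id=str(row["sample_id"]),
                chrom=str(row["chrom"]),
                start=_parse_int(str(row["start"]), "start", i),
                end=_parse_int(str(row["end"]), "end", i),
                gc_fraction=_parse_float(str(row["gc_fraction"]), "gc_fraction", i),
                read_count=_parse_int(str(row["read_count"]), "read_count", i),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from None
        result.setdefault(rec.sample_id, []).append(rec)

    for sample in result:
        result[sample].sort(key=lambda r: r.key)
    samples = list(result)
    if samples:
        reference = [r.key for r in result[samples[0]]]
        for sample in samples[1:]:
            keys = [r.key for r in result[sample]]
            if keys != reference:
                for a, b in zip(reference, keys):
                    if a != b:
                        raise ValueError(
                            f"{path}: region sets differ across samples: "
                            f"{samples[0]} has {a}, {sample} has {b}"
                        )
                raise ValueError(
                    f"{path}: region sets differ across samples: {samples[0]} has "
                    f"{len(reference)} regions, {sample} has {len(keys)}"
                )
    return result


def write_region_counts(
    regions: Mapping[str, Sequence[RegionCount]], path: PathLike
) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "gc_fraction": repr(r.gc_fraction),
            "read_count": r.read_count,
            "sample_id": r.sample_id,
        }
        for sample in regions
        for r in regions[sample]
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gc_fraction", "read_count", "sample_id"]
    ).to_csv(path, sep="\t", index=False)


def read_groups(path: PathLike) -> list[CohortGroup]:
    """Read a two-column group-membership TSV (sample_id, group_label)."""
    df = _read_tsv(path)
    for col in ("sample_id", "group_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    by_label: dict[str, list[str]] = {}
    for row in df.to_dict("records"):
        by_label.setdefault(str(row["group_label"]), []).append(str(row["sample_id"]))
    return [CohortGroup(label, tuple(ids)) for label, ids in by_label.items()]


def write_groups(groups: Sequence[CohortGroup], path: PathLike) -> None:
    rows = [
        {"sample_id": sid, "group_label": g.label} for g in groups for sid in g.sample_ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "group_label"]).to_csv(
        path, sep="\t", index=False
    )


def load_filter_config(path: PathLike) -> FilterConfig:
    """Load a :class:`FilterConfig` from JSON; unknown keys are a hard error."""
    with open(path) as fh:
        data = json.load(fh)
    valid = set(FilterConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return FilterConfig(**data)
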