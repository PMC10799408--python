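import itertools
import json
import math

import pytest

from somaticmetrics import (
    CohortGroup,
    SampleMetrics,
    TmbConfig,
    build_baseline,
    collect_metrics,
    compare_groups,
    render_report,
    run_cohort_analysis,
    simulate_cohort,
    validate_report,
)
from somaticmetrics.simulate import CohortConfig, GroupSpec, dominant_spectrum


def metrics_from(values, metric="tmb", prefix="S"):
    return [
        SampleMetrics(sample_id=f"{prefix}{i}", **{metric: v})
        for i, v in enumerate(values)
    ]


def group_of(rows):
    return CohortGroup("G", tuple(m.sample_id for m in rows))


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        a = metrics_from([10.0, 11.0, 12.0], prefix="A")
        b = metrics_from([10.0, 11.0, 12.0], prefix="B")
        cmp = compare_groups(a + b, group_of(a), group_of(b), "tmb")
        assert cmp.p_value == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        # n=3 vs 3 fully separated: exact two-sided rank-sum p = 2/C(6,3) * 1 = 0.1
        a = metrics_from([10.0, 11.0, 12.0], prefix="A")
        b = metrics_from([1.0, 2.0, 3.0], prefix="B")
        cmp = compare_groups(a + b, group_of(a), group_of(b), "tmb")
        assert cmp.p_value == pytest.approx(0.1)
        assert cmp.summary_a["median"] == pytest.approx(11.0)

    def test_rank_sum_matches_exact_enumeration_for_small_groups(self):
        # oracle: enumerate all assignments of the pooled values to groups and
        # compute the two-sided p as the probability of a U at least as extreme
        def exact_p(xs, ys):
            pooled = xs + ys
            n = len(xs)

            def u_of(xs_, ys_):
                return sum((x > y) + 0.5 * (x == y) for x in xs_ for y in ys_)

            observed = u_of(xs, ys)
            mid = len(xs) * len(ys) / 2
            dev = abs(observed - mid)
            count = total = 0
            for idx in itertools.combinations(range(len(pooled)), n):
                sub = [pooled[i] for i in idx]
                rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
                if abs(u_of(sub, rest) - mid) >= dev - 1e-12:
                    count += 1
                total += 1
            return count / total

        cases = [
            ([1.0, 5.0, 3.0], [2.0, 8.0, 9.0]),
            ([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0]),
            ([2.0, 9.0], [1.0, 7.0, 8.0]),
        ]
        for xs, ys in cases:
            a = metrics_from(xs, prefix="A")
            b = metrics_from(ys, prefix="B")
            cmp = compare_groups(a + b, group_of(a), group_of(b), "tmb")
            assert cmp.p_value == pytest.approx(exact_p(xs, ys))

    def test_msi_fisher_exact(self):
        a = [SampleMetrics(f"A{i}", msi_status="MSS") for i in range(6)]
        b = [SampleMetrics(f"B{i}", msi_status="MSI-H" if i == 0 else "MSS") for i in range(6)]
        cmp = compare_groups(a + b, group_of(a), group_of(b), "msi_status")
        assert cmp.p_value == pytest.approx(1.0)  # hypergeometric enumeration
        assert cmp.summary_a == {"msi_h": 0, "other": 6}
        assert cmp.summary_b == {"msi_h": 1, "other": 5}

    def test_missing_values_dropped_with_warning(self, caplog):
        a = metrics_from([10.0, None, 12.0], prefix="A")
        b = metrics_from([1.0, 2.0, 3.0], prefix="B")
        with caplog.at_level("WARNING"):
            cmp = compare_groups(a + b, group_of(a), group_of(b), "tmb")
        assert cmp.summary_a["n"] == 2
        assert any("missing" in r.message for r in caplog.records)

    def test_entirely_missing_metric_gives_missing_p(self, caplog):
        a = metrics_from([None, None], prefix="A")
        b = metrics_from([1.0, 2.0], prefix="B")
        with caplog.at_level("WARNING"):
            cmp = compare_groups(a + b, group_of(a), group_of(b), "tmb")
        assert cmp.p_value is None

    def test_unknown_metric_error(self):
        a = metrics_from([1.0], prefix="A")
        with pytest.raises(ValueError, match="unknown metric"):
            compare_groups(a, group_of(a), group_of(a), "nope")


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortConfig(
        groups=[
            GroupSpec("HE", 3, dominant_spectrum("C>A", 0.7), n_variants=150),
            GroupSpec("HI", 3, dominant_spectrum("C>T", 0.7), n_variants=150, n_msi_h=1, n_cn_altered=1),
        ],
        n_regions=100,
        region_panel_n=12,
        str_panel_n=12,
        n_str_loci=8,
    )
    return simulate_cohort(cfg, seed=2024)


class TestCollectMetrics:
    def test_full_cohort_has_no_missing_fields(self, small_cohort):
        c = small_cohort
        baseline = build_baseline(c.str_panel)
        rows = collect_metrics(
            c.variants,
            [s for g in c.truth.groups for s in g.sample_ids],
            TmbConfig(exon_bases=34_000_000),
            str_by_sample=c.str_tumors,
            msi_baseline=baseline,
            region_tumors=c.region_tumors,
            region_panel=c.region_panel,
        )
        assert len(rows) == 6
        for m in rows:
            assert m.tmb is not None and m.math is not None
            assert m.msi_status is not None
            assert m.cni is not None and m.cnv_burden is not None

    def test_missing_modality_yields_missing_fields(self, small_cohort, caplog):
        c = small_cohort
        with caplog.at_level("WARNING"):
            rows = collect_metrics(
                c.variants,
                ["S01"],
                TmbConfig(exon_bases=34_000_000),
            )
        assert rows[0].cni is None and rows[0].msi_status is None
        assert any("no region counts" in r.message for r in caplog.records)

    def test_recomputation_is_deterministic(self, small_cohort):
        c = small_cohort
        args = (c.variants, ["S01", "S04"], TmbConfig(exon_bases=34_000_000))
        assert collect_metrics(*args) == collect_metrics(*args)

    def test_no_samples_error(self):
        with pytest.raises(ValueError):
            collect_metrics({}, [], TmbConfig(exon_bases=1))


class TestRenderReport:
    def test_truth_propagates_to_report(self, small_cohort, tmp_path):
        c = small_cohort
        baseline = build_baseline(c.str_panel)
        metrics, comparisons, spectra = run_cohort_analysis(
            c.variants,
            c.truth.groups,
            TmbConfig(exon_bases=34_000_000),
            out_dir=tmp_path,
            str_by_sample=c.str_tumors,
            msi_baseline=baseline,
            region_tumors=c.region_tumors,
            region_panel=c.region_panel,
        )
        payload = json.loads((tmp_path / "report.json").read_text())
        validate_report(payload)
        spec = payload["spectrum_comparisons"][0]
        assert spec["dominant_class_a"] == "C>A"
        assert spec["dominant_class_b"] == "C>T"
        msi = [cmp for cmp in payload["comparisons"] if cmp["metric"] == "msi_status"]
        assert msi[0]["summary_b"]["msi_h"] == 1
        assert (tmp_path / "summary.txt").exists()
        assert (tmp_path / "metrics.tsv").exists()
        # labels and counts match the groups file
        assert {g.label for g in c.truth.groups} == {
            spec["group_a"],
            spec["group_b"],
        }

    def test_report_with_metrics_only(self, tmp_path):
        rows = metrics_from([1.0, 2.0])
        payload = render_report(rows, [], [], tmp_path)
        validate_report(payload)
        assert payload["comparisons"] == []

    def test_schema_rejects_malformed_payload(self):
        with pytest.raises(ValueError, match="missing key"):
            validate_report({"metrics": []})
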