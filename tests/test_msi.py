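import pytest

from somaticmetrics import (
    StrLocusHistogram,
    build_baseline,
    call_locus,
    call_sample,
    classify_sample,
    filter_alleles,
)
from somaticmetrics.msi import BaselineLocus, MsiBaseline, MsiLocusCall
from somaticmetrics.simulate import default_str_loci, simulate_str_panel


def hist(counts, sample="T1", locus="L1"):
    return StrLocusHistogram(sample, locus, counts)


class TestAlleleQc:
    def test_depth_at_100_not_evaluable(self):
        # the depth rule is strict: > 100x
        assert filter_alleles(hist({15: 50, 16: 40})) is None  # total 90
        assert filter_alleles(hist({15: 60, 16: 40})) is None  # total 100, boundary
        assert filter_alleles(hist({15: 61, 16: 40})) == {15, 16}  # total 101

    def test_min_reads_and_top_fraction(self):
        # 17 fails the 2-read minimum; 16 fails the 5%-of-top cut (9 < 10)
        assert filter_alleles(hist({15: 200, 16: 9, 17: 1})) == {15}
        assert filter_alleles(hist({15: 200, 16: 10, 17: 1})) == {15, 16}

    def test_top_fraction_edge(self):
        assert filter_alleles(hist({15: 1000, 16: 40})) == {15}
        assert filter_alleles(hist({15: 1000, 16: 50})) == {15, 16}  # exactly 5%


class TestBaseline:
    @staticmethod
    def panel_from_counts(counts_per_sample):
        panel = {}
        for i, n_alleles in enumerate(counts_per_sample):
            counts = {15 + k: 100 for k in range(n_alleles)}
            panel[f"N{i}"] = [hist(counts, sample=f"N{i}")]
        return panel

    def test_constant_panel(self):
        baseline = build_baseline(self.panel_from_counts([3] * 30))
        entry = baseline.loci["L1"]
        assert entry.mean_allele_count == pytest.approx(3.0)
        assert entry.sd_allele_count == pytest.approx(0.0)
        assert entry.n_panel == 30

    def test_sample_sd(self):
        baseline = build_baseline(self.panel_from_counts([2, 3, 4]))
        entry = baseline.loci["L1"]
        assert entry.mean_allele_count == pytest.approx(3.0)
        assert entry.sd_allele_count == pytest.approx(1.0)  # (n-1) SD of {2,3,4}

    def test_under_evaluable_locus_dropped(self, caplog):
        panel = self.panel_from_counts([3, 3])
        panel["N1"] = [hist({15: 40}, sample="N1")]  # depth 40: not evaluable
        with caplog.at_level("WARNING"):
            baseline = build_baseline(panel)
        assert "L1" not in baseline.loci
        assert any("dropped" in r.message for r in caplog.records)

    def test_empty_panel_error(self):
        with pytest.raises(ValueError):
            build_baseline({})

    def test_json_round_trip(self, tmp_path):
        baseline = build_baseline(self.panel_from_counts([2, 3, 4]))
        path = tmp_path / "baseline.json"
        baseline.to_json(path)
        assert MsiBaseline.from_json(path) == baseline


class TestLocusCall:
    baseline = MsiBaseline({"L1": BaselineLocus(3.0, 0.5, 30)})  # threshold 5.0

    def test_unstable_above_threshold(self):
        h = hist({15 + k: 60 for k in range(6)})  # 6 alleles, depth 360
        assert call_locus(h, self.baseline).status == "unstable"

    def test_stable_at_threshold_boundary(self):
        h = hist({15 + k: 60 for k in range(5)})  # exactly mean + 4*SD
        assert call_locus(h, self.baseline).status == "stable"

    def test_low_depth_not_evaluable(self):
        h = hist({15: 40, 16: 40})  # depth 80
        call = call_locus(h, self.baseline)
        assert call.status == "not_evaluable" and call.allele_count is None

    def test_locus_absent_from_baseline(self, caplog):
        h = hist({15: 200}, locus="L9")
        with caplog.at_level("WARNING"):
            call = call_locus(h, self.baseline)
        assert call.status == "not_evaluable"


class TestSampleClassification:
    @staticmethod
    def calls(n_unstable, n_stable, n_ne=0):
        out = []
        for i in range(n_unstable):
            out.append(MsiLocusCall(f"U{i}", 7, "unstable"))
        for i in range(n_stable):
            out.append(MsiLocusCall(f"S{i}", 3, "stable"))
        for i in range(n_ne):
            out.append(MsiLocusCall(f"N{i}", None, "not_evaluable"))
        return out

    @pytest.mark.parametrize(
        "u,s,ne,expected",
        [(2, 5, 0, "MSI-H"), (0, 4, 0, "MSS"), (1, 3, 3, "QNS"), (2, 4, 0, "MSI-H")],
    )
    def test_rule_table(self, u, s, ne, expected):
        assert classify_sample(self.calls(u, s, ne)).status == expected

    def test_empty_calls_error(self):
        with pytest.raises(ValueError):
            classify_sample([])


class TestMonotonicity:
    def test_adding_subdominant_allele_never_decreases_count(self):
        base = {15: 200, 16: 30}
        before = filter_alleles(hist(base))
        # add an allele that passes QC without displacing the top allele
        after = filter_alleles(hist({**base, 17: 25}))
        assert after is not None and before is not None
        assert len(after) >= len(before)

    def test_increasing_baseline_sd_never_destabilizes(self):
        h = hist({15 + k: 60 for k in range(5)})
        tight = MsiBaseline({"L1": BaselineLocus(3.0, 0.4, 30)})
        loose = MsiBaseline({"L1": BaselineLocus(3.0, 0.8, 30)})
        assert call_locus(h, tight).status == "unstable"
        assert call_locus(h, loose).status == "stable"
        # the reverse direction (stable -> unstable under larger SD) cannot occur
        stable_h = hist({15 + k: 60 for k in range(3)})
        assert call_locus(stable_h, tight).status == "stable"
        assert call_locus(stable_h, loose).status == "stable"


class TestEndToEndRecovery:
    def test_msi_h_and_mss_recovered(self):
        loci = default_str_loci(10, seed=3)
        panel, tumors = simulate_str_panel(
            30, loci, {"T_high": "MSI-H", "T_stable": "MSS"}, seed=3
        )
        baseline = build_baseline(panel)
        assert call_sample(tumors["T_high"], baseline).status == "MSI-H"
        assert call_sample(tumors["T_stable"], baseline).status == "MSS"

    def test_panel_self_consistency(self):
        # each panel sample called against a baseline built from the others
        # should be overwhelmingly stable
        loci = default_str_loci(10, seed=9)
        panel, _ = simulate_str_panel(20, loci, {}, seed=9)
        stable = total = 0
        for held_out in panel:
            rest = {sid: h for sid, h in panel.items() if sid != held_out}
            baseline = build_baseline(rest)
            call = call_sample(panel[held_out], baseline)
            stable += call.n_stable
            total += call.n_stable + call.n_unstable
        assert stable / total >= 0.95
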