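import numpy as np
import pytest

from somaticmetrics import (
    RegionCount,
    analyze_sample,
    call_cnv,
    cni_score,
    compute_log2_ratios,
    compute_z_scores,
    gc_length_correct,
    panel_log2_ratios,
)
from somaticmetrics.simulate import simulate_region_counts


def regions_from(counts, lengths=None, gcs=None, sample="T1"):
    n = len(counts)
    lengths = lengths or [300] * n
    gcs = gcs or [0.45] * n
    out, start = [], 1000
    for c, l, g in zip(counts, lengths, gcs):
        out.append(RegionCount(sample, "chr1", start, start + l, g, c))
        start += l + 500
    return out


class TestGcLengthCorrect:
    def test_flat_input_corrects_to_constant(self):
        corrected = gc_length_correct(regions_from([150] * 20))
        assert np.allclose(corrected, corrected[0])

    def test_length_normalization(self):
        short = regions_from([150] * 20, lengths=[300] * 20)
        long = regions_from([150] * 20, lengths=[600] * 20)
        ratio = gc_length_correct(short) / gc_length_correct(long)
        assert np.allclose(ratio, 2.0)

    def test_gc_bias_removed(self):
        rng = np.random.default_rng(42)
        gcs = rng.uniform(0.3, 0.7, 500)
        # counts proportional to a quadratic in GC, plus Poisson noise
        mu = 200 * (1.0 - 1.8 * (gcs - 0.45) ** 2)
        counts = rng.poisson(mu)
        regs = regions_from(counts.tolist(), gcs=gcs.tolist())
        corrected = gc_length_correct(regs)
        r_before = np.corrcoef(gcs, counts)[0, 1]
        r_after = np.corrcoef(gcs, corrected)[0, 1]
        assert abs(r_before) > 0.2  # the planted bias is visible
        assert abs(r_after) < 0.1

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            gc_length_correct(regions_from([0] * 20))


class TestLog2Ratios:
    def test_tumor_equal_to_panel_mean_is_zero(self):
        cov = np.full(10, 0.5)
        panel = np.tile(cov, (5, 1))
        assert np.allclose(compute_log2_ratios(cov, panel), 0.0)

    def test_exact_doubling_is_one(self):
        cov = np.full(10, 0.5)
        panel = np.tile(cov, (5, 1))
        tumor = cov.copy()
        tumor[3] = 1.0
        ratios = compute_log2_ratios(tumor, panel)
        assert ratios[3] == pytest.approx(1.0, abs=0.01)

    def test_panel_member_centered_near_zero(self):
        rng = np.random.default_rng(5)
        panel = rng.normal(0.5, 0.02, size=(30, 500)).clip(0.01)
        tumor = rng.normal(0.5, 0.02, size=500).clip(0.01)
        ratios = compute_log2_ratios(tumor, panel)
        assert abs(float(ratios.mean())) < 0.05

    def test_grid_mismatch_error(self):
        with pytest.raises(ValueError, match="region grids"):
            compute_log2_ratios(np.ones(5), np.ones((3, 6)))

    def test_panel_too_small(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_log2_ratios(np.ones(5), np.ones((1, 5)))


class TestZScores:
    def test_tumor_at_panel_mean_is_zero(self):
        rng = np.random.default_rng(1)
        panel = rng.normal(0, 0.1, size=(10, 20))
        z, _ = compute_z_scores(panel.mean(axis=0), panel)
        assert np.allclose(z, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            panel = rng.normal(0, 0.2, size=(12, 20))
            tumor = rng.normal(0, 0.2, size=20)
            z, thr = compute_z_scores(tumor, panel)
            for j in range(20):
                col = sorted(panel[:, j])
                mean = sum(col) / len(col)
                sd = (sum((x - mean) ** 2 for x in col) / (len(col) - 1)) ** 0.5
                zz = (tumor[j] - mean) / max(sd, 1e-6)
                assert z[j] == pytest.approx(zz, abs=1e-9)
                pz = sorted((x - mean) / max(sd, 1e-6) for x in col)
                # linear-interpolation P95 of the panel z-scores
                pos = 0.95 * (len(pz) - 1)
                lo = int(pos)
                p95 = pz[lo] + (pos - lo) * (pz[min(lo + 1, len(pz) - 1)] - pz[lo])
                mz = sum(pz) / len(pz)
                sdz = (sum((x - mz) ** 2 for x in pz) / (len(pz) - 1)) ** 0.5
                assert thr[j] == pytest.approx(p95 + 2 * sdz, abs=1e-9)

    def test_gaussian_panel_threshold_near_theory(self):
        # P95 of a standard normal is 1.645; threshold ~ 1.645 + 2
        rng = np.random.default_rng(2024)
        panel = rng.normal(0, 0.3, size=(30, 400))
        _, thr = compute_z_scores(rng.normal(0, 0.3, size=400), panel)
        assert float(np.median(thr)) == pytest.approx(3.6, abs=0.5)

    def test_constant_panel_region_floored(self, caplog):
        panel = np.zeros((5, 3))
        tumor = np.array([0.0, 0.0, 0.5])
        with caplog.at_level("WARNING"):
            z, _ = compute_z_scores(tumor, panel)
        assert abs(z[2]) > 1e4
        assert any("near-constant" in r.message for r in caplog.records)


class TestCniScore:
    def test_null_tumor_scores_zero(self):
        z = np.array([0.1, -0.5, 1.0])
        thr = np.full(3, 3.6)
        res = cni_score(z, thr)
        assert res.cni == 0.0 and not res.retained.any()

    def test_single_amplified_region(self):
        z = np.array([0.0, 10.0, 0.2])
        res = cni_score(z, np.full(3, 3.6))
        assert res.cni == pytest.approx(10.0)
        assert res.retained.tolist() == [False, True, False]

    def test_deletions_ignored_one_sided(self):
        z = np.array([-10.0, -8.0])
        assert cni_score(z, np.full(2, 3.6)).cni == 0.0

    def test_two_sided_retains_deletions(self):
        z = np.array([-10.0, 0.0, 5.0])
        res = cni_score(z, np.full(3, 3.6), two_sided=True)
        assert res.cni == pytest.approx(15.0)

    def test_monotone_in_amplification(self):
        thr = np.full(4, 3.6)
        z = np.array([0.0, 2.0, 5.0, 1.0])
        base = cni_score(z, thr).cni
        for bump in (1.0, 3.0, 10.0):
            z2 = z.copy()
            z2[1] += bump
            assert cni_score(z2, thr).cni >= base


class TestCallCnv:
    @pytest.mark.parametrize(
        "cn,expected",
        [(5.0, "gain"), (1.0, "loss"), (4.0, "neutral"), (1.2, "neutral"), (2.0, "neutral")],
    )
    def test_boundary_table(self, cn, expected):
        profile = call_cnv(cn_estimates=np.array([cn]))
        assert profile.calls == [expected]

    def test_burden(self):
        profile = call_cnv(cn_estimates=np.array([5.0, 1.0, 2.0, 2.0]))
        assert profile.n_gain == 1 and profile.n_loss == 1
        assert profile.burden == pytest.approx(0.5)

    def test_cn_from_log2(self):
        profile = call_cnv(log2_ratios=np.array([0.0, 1.6, -1.2]))
        assert profile.cn_estimates[0] == pytest.approx(2.0)
        assert profile.calls == ["neutral", "gain", "loss"]

    def test_negative_cn_error(self):
        with pytest.raises(ValueError):
            call_cnv(cn_estimates=np.array([-1.0]))


class TestNullCalibration:
    def test_null_tumors_score_near_zero_and_amplified_score_higher(self):
        cnis_null, cnis_amp, burdens_null, burdens_amp = [], [], [], []
        for rep in range(10):
            cn_amp = {str(i): 6 for i in range(20)}  # 10% of 200 regions
            tumors, panel = simulate_region_counts(
                200, 20, {"null": {}, "amp": cn_amp}, seed=1000 + rep
            )
            _, cni_null = analyze_sample(tumors["null"], panel)
            prof_amp, cni_amp = analyze_sample(tumors["amp"], panel)
            prof_null, _ = analyze_sample(tumors["null"], panel)
            cnis_null.append(cni_null.cni)
            cnis_amp.append(cni_amp.cni)
            burdens_null.append(prof_null.burden)
            burdens_amp.append(prof_amp.burden)
        assert float(np.median(cnis_null)) < 5.0
        assert all(a > n for a, n in zip(cnis_amp, cnis_null))
        assert all(a > n for a, n in zip(burdens_amp, burdens_null))


def test_merged_retained_sets_bound():
    # merging two tumors' retained z-sets: max of the scores <= sum of both
    thr = np.full(6, 3.6)
    z1 = np.array([5.0, 0.0, 4.0, 0.0, 0.0, 0.0])
    z2 = np.array([0.0, 6.0, 0.0, 0.0, 7.0, 0.0])
    s1 = cni_score(z1, thr).cni
    s2 = cni_score(z2, thr).cni
    merged = cni_score(np.maximum(z1, z2), thr).cni
    assert max(s1, s2) <= merged <= s1 + s2
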