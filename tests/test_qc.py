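"""Methylation matrix QC chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedimeth.qc import (
    MethylationMatrix,
    ProbeRecord,
    QCError,
    QCReport,
    annotate_probe_variants,
    cv_outlier_filter,
    lilliefors_test,
    parse_probe_id,
    probe_filters,
    sample_call_rate_filter,
)


def make_mm(beta: np.ndarray, det: np.ndarray | None = None,
            probes=None) -> MethylationMatrix:
    n, p = beta.shape
    samples = [f"S{i}" for i in range(n)]
    probes = probes or [f"G{j}_P1_F" for j in range(p)]
    if det is None:
        det = np.full_like(beta, 0.001, dtype=float)
    return MethylationMatrix(
        pd.DataFrame(beta, index=samples, columns=probes),
        pd.DataFrame(det, index=samples, columns=probes),
    )


def make_manifest(probes, chroms=None):
    chroms = chroms or ["1"] * len(probes)
    df = pd.DataFrame(
        {
            "probe_id": probes,
            "chrom": chroms,
            "cpg_pos": np.arange(1, len(probes) + 1) * 1000,
            "strand": "F",
            "probe_start": np.arange(1, len(probes) + 1) * 1000 - 25,
            "probe_end": np.arange(1, len(probes) + 1) * 1000 + 25,
        }
    ).set_index("probe_id", drop=False)
    df["autosomal"] = [c not in ("X", "Y") for c in chroms]
    return df


class TestMethylationMatrix:
    def test_rejects_out_of_range_beta(self):
        with pytest.raises(QCError, match="beta"):
            make_mm(np.array([[0.5, 1.2]]))

    def test_rejects_mismatched_axes(self):
        beta = pd.DataFrame([[0.5]], index=["a"], columns=["G_P1_F"])
        det = pd.DataFrame([[0.5]], index=["b"], columns=["G_P1_F"])
        with pytest.raises(QCError, match="share"):
            MethylationMatrix(beta, det)

    def test_tsv_roundtrip(self, tmp_path):
        mm = make_mm(np.array([[0.1, 0.9], [0.2, 0.8]]))
        mm.write(tmp_path / "b.tsv", tmp_path / "d.tsv")
        again = MethylationMatrix.read(tmp_path / "b.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(mm.beta, again.beta)


class TestProbeIds:
    def test_parse_convention(self):
        assert parse_probe_id("GSTM1_P266_F") == ("GSTM1", "P266", "F")
        assert parse_probe_id("LTA_E28_R") == ("LTA", "E28", "R")

    def test_bad_id_rejected(self):
        with pytest.raises(QCError):
            parse_probe_id("cg0001")

    def test_cpg_must_sit_inside_probe(self):
        with pytest.raises(QCError, match="outside"):
            ProbeRecord("A_P1_F", "1", 500, "F", 1000, 1050)


class TestSampleCallRate:
    def test_fully_detected_sample_retained(self):
        mm = make_mm(np.full((1, 10), 0.5), np.full((1, 10), 0.01))
        out, rep = sample_call_rate_filter(mm)
        assert out.samples == ["S0"]
        assert rep.entries[0]["excluded"] == 0

    def test_eight_of_ten_called_removed(self):
        det = np.full((2, 10), 0.01)
        det[1, :2] = 0.5  # call rate 0.8 for S1
        mm = make_mm(np.full((2, 10), 0.5), det)
        out, rep = sample_call_rate_filter(mm)
        assert out.samples == ["S0"]

    def test_five_sample_fixture_counts(self):
        # one sample at rate 0.85 (17/20 called), four perfect
        det = np.full((5, 20), 0.01)
        det[2, :3] = 0.9
        mm = make_mm(np.full((5, 20), 0.5), det)
        out, rep = sample_call_rate_filter(mm)
        assert len(out.samples) == 4
        assert rep.entries[0]["excluded"] == 1

    def test_empty_cohort_error(self):
        mm = make_mm(np.full((2, 4), 0.5), np.full((2, 4), 0.5))
        with pytest.raises(QCError, match="empty cohort"):
            sample_call_rate_filter(mm)


class TestCVOutlier:
    def test_identical_samples_none_removed(self):
        mm = make_mm(np.tile(np.linspace(0.2, 0.8, 10), (6, 1)))
        out, _ = cv_outlier_filter(mm)
        assert len(out.samples) == 6

    def test_exactly_top_tail_removed_of_200(self):
        """With 200 distinct CVs, strictly-above-97.5th-percentile leaves
        the top 5 out (brute-force sort oracle)."""
        rng = np.random.default_rng(0)
        base = np.linspace(0.2, 0.8, 50)
        rows = [base + (1 + i / 100) * rng.normal(0, 0.02, 50) for i in range(200)]
        beta = np.clip(np.abs(np.array(rows)), 0.001, 0.999)
        mm = make_mm(beta)
        cvs = beta.std(axis=1, ddof=1) / beta.mean(axis=1)
        cut = np.percentile(cvs, 97.5)
        expected_removed = int((cvs > cut).sum())
        out, rep = cv_outlier_filter(mm)
        assert rep.entries[0]["excluded"] == expected_removed == 5

    def test_gross_outlier_removed(self):
        beta = np.tile(np.linspace(0.4, 0.6, 20), (40, 1))
        beta[7] = np.clip(0.5 + 10 * (np.linspace(0.4, 0.6, 20) - 0.5), 0, 1)
        mm = make_mm(beta)
        out, _ = cv_outlier_filter(mm)
        assert "S7" not in out.samples
        assert len(out.samples) == 39


class TestLilliefors:
    def test_normal_sample_rarely_rejected(self):
        """p > 0.1 for most large normal samples (level-0.1 screen)."""
        rng = np.random.default_rng(11)
        keep = sum(
            lilliefors_test(rng.standard_normal(500), n_mc=2000)[1] > 0.1
            for _ in range(100)
        )
        assert keep >= 80  # ~90 expected at the 0.1 level

    def test_lognormal_strongly_rejected(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.standard_normal(500))
        d, p = lilliefors_test(x, n_mc=2000)
        assert p < 0.01

    def test_too_few_values_error(self):
        with pytest.raises(QCError, match=">=4"):
            lilliefors_test([0.1, 0.2, 0.3])

    def test_zero_variance_error(self):
        with pytest.raises(QCError, match="zero-variance"):
            lilliefors_test([0.5] * 10)

    def test_statistic_matches_statsmodels(self):
        """Cross-check D against the independent statsmodels implementation."""
        from statsmodels.stats.diagnostic import lilliefors as sm_lillie

        rng = np.random.default_rng(3)
        x = rng.standard_normal(80)
        d_ours, _ = lilliefors_test(x, n_mc=500)
        d_sm, _ = sm_lillie(x, dist="norm", pvalmethod="table")
        assert d_ours == pytest.approx(d_sm, abs=1e-12)

    def test_null_rejection_rate_calibrated(self):
        """Rejection at level 0.1 stays inside the binomial 95% CI of 0.10
        over 1,000 simulated normal probes."""
        rng = np.random.default_rng(99)
        n_rej = sum(
            lilliefors_test(rng.standard_normal(120), n_mc=2000)[1] < 0.1
            for _ in range(1000)
        )
        # binomial 95% band around 0.10 at n=1000: +-1.96*sqrt(.1*.9/1000)
        assert 100 - 19 <= n_rej <= 100 + 19


class TestProbeFilters:
    def test_constant_probe_removed_at_variation_stage(self):
        rng = np.random.default_rng(0)
        beta = np.column_stack(
            [np.full(50, 0.5), np.clip(rng.normal(0.5, 0.08, 50), 0, 1)]
        )
        mm = make_mm(beta, probes=["FLAT_P1_F", "OK_P1_F"])
        out, rep = probe_filters(mm, make_manifest(mm.probes), n_mc=500)
        stages = {e["filter"]: e for e in rep.entries}
        assert "FLAT_P1_F" in stages["beta_variation"]["excluded_ids"]
        assert "OK_P1_F" in out.probes

    def test_low_call_rate_probe_removed_first(self):
        rng = np.random.default_rng(1)
        beta = np.clip(rng.normal(0.5, 0.08, size=(100, 2)), 0, 1)
        det = np.full((100, 2), 0.001)
        det[:4, 0] = 0.9  # 96% call rate
        mm = make_mm(beta, det)
        out, rep = probe_filters(mm, make_manifest(mm.probes), n_mc=500)
        assert rep.entries[0]["filter"] == "probe_call_rate"
        assert rep.entries[0]["excluded"] == 1

    def test_x_linked_probe_removed_last(self):
        rng = np.random.default_rng(2)
        beta = np.clip(rng.normal(0.5, 0.08, size=(100, 2)), 0, 1)
        mm = make_mm(beta)
        manifest = make_manifest(mm.probes, chroms=["X", "1"])
        out, rep = probe_filters(mm, manifest, n_mc=500)
        assert rep.entries[-1]["filter"] == "autosomal_only"
        assert out.probes == [mm.probes[1]]

    def test_unknown_probe_errors_by_name(self):
        mm = make_mm(np.full((5, 1), 0.5))
        manifest = make_manifest(["OTHER_P1_F"])
        with pytest.raises(QCError, match=mm.probes[0]):
            probe_filters(mm, manifest)

    def test_report_conservation(self):
        """remaining_before - excluded == remaining_after at every stage."""
        rng = np.random.default_rng(5)
        beta = np.clip(rng.normal(0.5, 0.1, size=(60, 30)), 0, 1)
        beta[:, :3] = 0.5  # flat probes
        mm = make_mm(beta)
        _, rep = probe_filters(mm, make_manifest(mm.probes), n_mc=500)
        prev = rep.initial
        for e in rep.entries:
            assert prev - e["excluded"] == e["remaining"]
            prev = e["remaining"]

    def test_engineered_chain_counts(self):
        """A small engineered panel reproduces per-stage arithmetic
        (the full 1,505-probe version is exercised in the acceptance suite)."""
        from pedimeth.simulate import qc_chain_fixture

        mm, manifest = qc_chain_fixture(
            n_samples=60, seed=4, n_call=5, n_flat=7, n_nonnormal=9,
            n_xlinked=2, n_clean=11, n_mc=500,
        )
        out, rep = probe_filters(mm, manifest, n_mc=2000)
        excl = [e["excluded"] for e in rep.entries]
        assert excl == [5, 7, 9, 2]
        assert len(out.probes) == 11


class TestQCReportBookkeeping:
    def test_inconsistent_entry_rejected(self):
        rep = QCReport(axis="probes", initial=10)
        with pytest.raises(QCError, match="bookkeeping"):
            rep.add("stage", 0.5, excluded=3, remaining=8)

    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=6))
    @settings(deadline=None, derandomize=True)
    def test_chain_conserves_counts(self, exclusions):
        total = sum(exclusions) + 3
        rep = QCReport(axis="probes", initial=total)
        remaining = total
        for k, e in enumerate(exclusions):
            remaining -= e
            rep.add(f"stage{k}", None, e, remaining)
        assert rep.initial - sum(e["excluded"] for e in rep.entries) == rep.final


class TestAnnotateProbeVariants:
    def test_common_variant_near_cpg_flagged(self):
        """A MAF-0.35 variant 19 bp from the CpG inside the probe body."""
        manifest = pd.DataFrame(
            {
                "probe_id": ["LTA_E28_R"],
                "chrom": ["6"],
                "cpg_pos": [31540000],
                "strand": ["R"],
                "probe_start": [31539975],
                "probe_end": [31540025],
            }
        ).set_index("probe_id", drop=False)
        variants = pd.DataFrame(
            {"chrom": ["chr6"], "pos": [31540019], "maf": [0.35]}
        )
        ann = annotate_probe_variants(manifest, variants)
        row = ann.loc["LTA_E28_R"]
        assert row["n_variants"] == 1
        assert row["min_distance_bp"] == 19
        assert row["max_maf"] == pytest.approx(0.35)
        assert bool(row["flag_maf_gt_0.05"])

    def test_variant_outside_interval_not_counted(self):
        manifest = make_manifest(["A_P1_F"])  # interval [975, 1025], cpg 1000
        variants = pd.DataFrame({"chrom": ["1"], "pos": [1026], "maf": [0.4]})
        ann = annotate_probe_variants(manifest, variants)
        assert ann.loc["A_P1_F", "n_variants"] == 0

    def test_rare_variants_counted_not_flagged(self):
        manifest = make_manifest(["A_P1_F"])
        variants = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [990, 1010], "maf": [0.01, 0.01]}
        )
        ann = annotate_probe_variants(manifest, variants)
        assert ann.loc["A_P1_F", "n_variants"] == 2
        assert not bool(ann.loc["A_P1_F", "flag_maf_gt_0.05"])
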