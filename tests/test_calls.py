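"""Regulation classification, overlap fractions, correlations, QC."""

import numpy as np
import pandas as pd
import pytest

from mitoribo import (
    call_mrna_regulation,
    call_te_regulation,
    compute_te,
    fold_correlation,
    fp_only_comparison,
    gene_set_medians,
    merge_and_filter,
    overlap_fraction,
    replicate_qc,
)


def _measurements(records):
    """records: (gene, phase, fp_rpkm, mrna_rpkm, te) with clean flags."""
    rows = []
    for g, ph, fp, mrna, te in records:
        rows.append(
            {
                "gene": g,
                "phase": ph,
                "fp_reads_total": 1000,
                "mrna_reads_total": 1000,
                "fp_rpkm_mean": fp,
                "mrna_rpkm_mean": mrna,
                "flags": "",
                "te": te,
            }
        )
    return pd.DataFrame(rows)


class TestMrnaCalls:
    def test_threshold_and_boundary(self):
        meas = _measurements(
            [
                ("a", "G2", 1, 90.0, 1.0),
                ("a", "M", 1, 20.0, 1.0),   # ratio 4.5 -> down in M
                ("b", "G2", 1, 30.0, 1.0),
                ("b", "M", 1, 10.0, 1.0),   # ratio exactly 3 -> unchanged
                ("c", "G2", 1, 10.0, 1.0),
                ("c", "M", 1, 40.0, 1.0),   # inverse ratio 4 -> up in M
            ]
        )
        calls = call_mrna_regulation(meas, "G2", "M")
        assert calls.loc["a", "mrna_class"] == "down"
        assert calls.loc["b", "mrna_class"] == "unchanged"
        assert calls.loc["c", "mrna_class"] == "up"
        assert calls.loc["a", "mrna_fold"] == pytest.approx(4.5)

    def test_unknown_phase_rejected(self):
        meas = _measurements([("a", "G2", 1, 1, 1.0), ("a", "M", 1, 1, 1.0)])
        with pytest.raises(ValueError):
            call_mrna_regulation(meas, "G2", "S")

    def test_flagged_gene_filtered(self):
        meas = _measurements([("a", "G2", 1, 9.0, 1.0), ("a", "M", 1, 3.0, 1.0)])
        meas.loc[0, "flags"] = "low_reads_mrna"
        calls = call_mrna_regulation(meas, "G2", "M")
        assert calls.loc["a", "mrna_class"] == "filtered"


class TestTeCalls:
    def test_dual_threshold(self):
        meas = _measurements(
            [
                ("a", "G2", 33.0, 10.0, 3.3),
                ("a", "M", 10.0, 10.0, 1.0),   # TE 3.3x & FP 3.3x -> repressed
                ("b", "G2", 15.0, 4.55, 3.3),
                ("b", "M", 10.0, 10.0, 1.0),   # TE 3.3x but FP 1.5x -> unchanged
                ("c", "G2", 10.0, 10.0, 1.0),
                ("c", "M", 35.0, 10.0, 3.5),   # both inverse -> activated
            ]
        )
        calls = call_te_regulation(meas, "G2", "M")
        assert calls.loc["a", "te_class"] == "repressed"
        assert calls.loc["b", "te_class"] == "unchanged"
        assert calls.loc["c", "te_class"] == "activated"

    def test_undefined_te_filtered(self):
        meas = _measurements(
            [("a", "G2", 33.0, 10.0, np.nan), ("a", "M", 10.0, 10.0, 1.0)]
        )
        assert call_te_regulation(meas, "G2", "M").loc["a", "te_class"] == "filtered"

    def test_fp_criterion_always_holds_on_calls(self, small_expression):
        """Asymmetric-threshold consistency on real simulated output."""
        meas = compute_te(merge_and_filter(small_expression))
        calls = call_te_regulation(meas, "G2", "M")
        rep = calls[calls["te_class"] == "repressed"]
        act = calls[calls["te_class"] == "activated"]
        assert (rep["fp_fold"] > 2).all() and (rep["te_fold"] > 3).all()
        assert (act["fp_fold"] < 0.5).all() and (act["te_fold"] < 1 / 3).all()

    def test_phase_swap_symmetry(self, small_expression):
        """Swapping the phase order maps repressed<->activated, up<->down."""
        meas = compute_te(merge_and_filter(small_expression))
        fwd = call_te_regulation(meas, "G2", "M")
        rev = call_te_regulation(meas, "M", "G2")
        swap = {"repressed": "activated", "activated": "repressed"}
        assert (
            fwd["te_class"].map(lambda c: swap.get(c, c)) == rev["te_class"]
        ).all()
        m_fwd = call_mrna_regulation(meas, "G2", "M")
        m_rev = call_mrna_regulation(meas, "M", "G2")
        mswap = {"up": "down", "down": "up"}
        assert (
            m_fwd["mrna_class"].map(lambda c: mswap.get(c, c)) == m_rev["mrna_class"]
        ).all()


def _calls_frame(entries):
    """entries: gene -> (te_class, te_fold)"""
    return pd.DataFrame(
        {
            "te_class": {g: c for g, (c, f) in entries.items()},
            "te_fold": {g: f for g, (c, f) in entries.items()},
            "fp_fold": {g: f for g, (c, f) in entries.items()},
            "mrna_class": "unchanged",
            "mrna_fold": 1.0,
        }
    )


class TestOverlap:
    def test_full_and_half_concordance(self):
        primary = _calls_frame({"a": ("repressed", 4.0), "b": ("repressed", 5.0)})
        secondary = _calls_frame({"a": ("unchanged", 2.5), "b": ("unchanged", 2.2)})
        assert overlap_fraction(primary, secondary, "repressed") == 1.0
        secondary2 = _calls_frame({"a": ("unchanged", 2.5), "b": ("unchanged", 1.5)})
        assert overlap_fraction(primary, secondary2, "repressed") == 0.5

    def test_empty_primary_undefined(self):
        primary = _calls_frame({"a": ("unchanged", 1.0)})
        assert overlap_fraction(primary, primary, "repressed") is None

    def test_direction_for_up_calls(self):
        primary = _calls_frame({"a": ("activated", 0.2)})
        secondary = _calls_frame({"a": ("unchanged", 0.4)})  # < 1/2 -> concordant
        assert overlap_fraction(primary, secondary, "activated") == 1.0


class TestFoldCorrelation:
    def test_identical_folds_r1(self):
        c = _calls_frame({g: ("repressed", f) for g, f in zip("abcd", (3.5, 4, 5, 6))})
        pairs, r = fold_correlation(c, c)
        assert r == pytest.approx(1.0)
        assert len(pairs) == 4

    def test_too_few_genes_undefined(self):
        c = _calls_frame({"a": ("repressed", 4.0), "b": ("repressed", 5.0)})
        _, r = fold_correlation(c, c)
        assert r is None

    def test_independent_folds_near_zero(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(500)]
        c1 = _calls_frame({g: ("unchanged", float(np.exp(rng.normal()))) for g in genes})
        c2 = _calls_frame({g: ("unchanged", float(np.exp(rng.normal()))) for g in genes})
        _, r = fold_correlation(c1, c2)
        assert abs(r) < 3 / np.sqrt(500)


class TestGeneSetMedians:
    def test_single_gene_and_odd_set(self):
        meas = _measurements(
            [
                ("a", "G2", 1, 10.0, 1.0),
                ("a", "M", 1, 10.0, 2.0),
                ("b", "G2", 1, 20.0, 2.0),
                ("b", "M", 1, 20.0, 3.0),
                ("c", "G2", 1, 30.0, 3.0),
                ("c", "M", 1, 30.0, 4.0),
            ]
        )
        med1 = gene_set_medians(meas, ["a"], "te")
        assert med1["G2"] == 1.0 and med1["M"] == 2.0
        med3 = gene_set_medians(meas, ["a", "b", "c"], "te")
        assert med3["G2"] == 2.0

    def test_empty_set_rejected(self):
        meas = _measurements([("a", "G2", 1, 1, 1.0)])
        with pytest.raises(ValueError):
            gene_set_medians(meas, [], "te")

    def test_planted_repressed_set_dips_in_m(self, small_expression, small_truth):
        """The M-repressed set's median TE is lowest in M (re-activation at exit)."""
        meas = compute_te(merge_and_filter(small_expression))
        rep = small_truth.index[small_truth["label"] == "te_repressed_M"]
        med = gene_set_medians(meas, rep, "te")
        assert med["M"] < med["G2"] and med["M"] < med["G1"]


class TestFpOnly:
    def test_fold_table(self):
        meas = _measurements(
            [("a", "G2", 40.0, 1.0, np.nan), ("a", "M", 10.0, 1.0, np.nan)]
        )
        out = fp_only_comparison(meas, "G2", "M")
        assert out.loc["a", "fp_fold"] == pytest.approx(4.0)

    def test_missing_phase_excluded(self):
        meas = _measurements(
            [
                ("a", "G2", 40.0, 1.0, np.nan),
                ("a", "M", 10.0, 1.0, np.nan),
                ("b", "G2", 40.0, 1.0, np.nan),
                ("b", "M", 0.0, 1.0, np.nan),  # zero FP in M -> excluded
            ]
        )
        out = fp_only_comparison(meas, "G2", "M")
        assert list(out.index) == ["a"]


class TestReplicateQC:
    def _expr(self, rpkm2_fn, n=100, reads=500, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            r1 = float(rng.lognormal(2, 1))
            r2 = rpkm2_fn(r1, rng)
            rows.append((f"g{i}", "G2", 1, "FP", reads, r1))
            rows.append((f"g{i}", "G2", 2, "FP", reads, r2))
        return pd.DataFrame(
            rows, columns=["gene", "phase", "replicate", "library", "reads", "rpkm"]
        )

    def test_identical_replicates(self):
        qc = replicate_qc(self._expr(lambda r, rng: r))
        assert qc.loc[0, "r_squared"] == pytest.approx(1.0)
        assert qc.loc[0, "sd_log2_ratio"] == pytest.approx(0.0, abs=1e-12)
        assert qc.loc[0, "fold_at_6sd"] == pytest.approx(1.0)

    def test_planted_lognormal_noise_recovered(self):
        sigma_log2 = 0.4
        qc = replicate_qc(
            self._expr(lambda r, rng: r * 2 ** rng.normal(0, sigma_log2), n=2000, seed=3)
        )
        assert qc.loc[0, "sd_log2_ratio"] == pytest.approx(sigma_log2, rel=0.1)

    def test_decorrelated_replicates_low_r2(self):
        qc = replicate_qc(
            self._expr(lambda r, rng: float(rng.lognormal(2, 1)), n=2000, seed=4)
        )
        assert qc.loc[0, "r_squared"] < 0.01

    def test_refuses_tiny_input(self):
        with pytest.raises(ValueError):
            replicate_qc(self._expr(lambda r, rng: r, n=5))
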