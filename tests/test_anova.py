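import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from crcmeth import anova, synthetic
from crcmeth._util import ValidationError
from crcmeth.anova import (
    fit_interaction_model,
    fit_location_model,
    fit_paired_model,
    genomewide_scan,
    paired_t_test,
    variance_decomposition,
)
from conftest import tiny_sheet


def _pairing(deltas, base=0.3):
    """Pairs dict plus a value series realising the given tumor-normal deltas."""
    y = {}
    pairs = {}
    for i, d in enumerate(deltas):
        y[f"p{i}_T"] = base + d
        y[f"p{i}_N"] = base
        pairs[f"p{i}"] = (f"p{i}_T", f"p{i}_N")
    return pd.Series(y), pairs


class TestPairedModel:
    def test_hand_example_two_pairs(self):
        """deltas (0.2, 0.3): mean 0.25, t=5, F=t^2=25, p~0.1257 at df (1,1)."""
        y, pairs = _pairing([0.2, 0.3])
        fit = fit_paired_model(y, pairs)
        assert fit.effects["tumor_effect"] == pytest.approx(0.25)
        assert fit.terms["Tumor"].f == pytest.approx(25.0, rel=1e-9)
        assert fit.terms["Tumor"].p == pytest.approx(0.12566591637800, rel=1e-9)

    def test_no_tumor_effect_f_zero_p_one(self):
        y = pd.Series({"p0_T": 0.2, "p0_N": 0.2, "p1_T": 0.7, "p1_N": 0.7})
        fit = fit_paired_model(y, {"p0": ("p0_T", "p0_N"), "p1": ("p1_T", "p1_N")})
        assert fit.terms["Tumor"].f == 0.0
        assert fit.terms["Tumor"].p == 1.0
        assert fit.sigma2_person > 0  # spread is between persons

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = rng.integers(3, 12)
            t_vals = rng.random(n)
            n_vals = rng.random(n)
            y = pd.Series(
                {f"p{i}_T": t_vals[i] for i in range(n)} | {f"p{i}_N": n_vals[i] for i in range(n)}
            )
            pairs = {f"p{i}": (f"p{i}_T", f"p{i}_N") for i in range(n)}
            fit = fit_paired_model(y, pairs)
            t, p = paired_t_test(t_vals - n_vals)
            assert fit.terms["Tumor"].f == pytest.approx(t**2, rel=1e-8)
            assert fit.terms["Tumor"].p == pytest.approx(p, rel=1e-8)

    def test_insufficient_pairs_flagged_not_raised(self):
        y, pairs = _pairing([0.2])
        fit = fit_paired_model(y, pairs)
        assert not fit.ok
        assert "insufficient_data" in fit.flags

    def test_missing_half_drops_pair_and_records_n(self):
        y, pairs = _pairing([0.1, 0.2, 0.3])
        y["p1_N"] = np.nan
        fit = fit_paired_model(y, pairs)
        assert fit.n_eff == 2
        assert fit.effects["tumor_effect"] == pytest.approx(0.2)

    def test_ss_partition_sums_to_total(self):
        y, pairs = _pairing([0.12, -0.05, 0.3, 0.07], base=0.4)
        y += pd.Series({k: v for k, v in zip(y.index, np.linspace(0, 0.1, len(y)))})
        fit = fit_paired_model(y, pairs)
        ss_sum = sum(t.ss for t in fit.terms.values())
        assert ss_sum == pytest.approx(fit.ss_total, abs=1e-10)

    def test_mom_person_variance_recovered(self, cohort_sheet):
        """Average MoM person component within 10% of the generating value."""
        noise = synthetic.NoiseSpec(0.2, 0.35)
        effects = synthetic.make_effect_panel({"null": 400}, seed=41, baseline_range=(0.45, 0.55))
        m, _ = synthetic.simulate_beta_matrix(cohort_sheet, effects, noise, seed=42)
        from crcmeth.data_io import validate_pairing

        pairing = validate_pairing(cohort_sheet)
        comps = [fit_paired_model(m.iloc[i], pairing.pairs).sigma2_person for i in range(100)]
        # generating person variance on the beta scale, via the delta method
        baselines = [0.5]
        slope = 0.25  # d expit / d eta at eta = 0
        expected = (0.2 * slope) ** 2
        assert np.mean(comps) == pytest.approx(expected, rel=0.10)


class TestPairedT:
    def test_hand_example(self):
        t, p = paired_t_test([0.2, 0.3])
        assert t == pytest.approx(5.0)
        assert p == pytest.approx(0.1257, abs=2e-4)

    def test_all_zero(self):
        t, p = paired_t_test([0.0, 0.0, 0.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_degenerate(self):
        t, p = paired_t_test([0.2, 0.2, 0.2])
        assert np.isinf(t) and p < 1e-300


class TestInteractionModel:
    def test_hand_2x2_balanced(self):
        """Cell means 0.2/0.3 (MSS N/T), 0.2/0.6 (MSI N/T), 2 per cell, zero
        spread: interaction contrast 0.3, SS = 2 * 0.3^2 / 4 = 0.045."""
        y = np.array([0.2, 0.2, 0.3, 0.3, 0.2, 0.2, 0.6, 0.6])
        tumor = np.array([0, 0, 1, 1, 0, 0, 1, 1], bool)
        msi = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        fit = fit_interaction_model(y, tumor, msi)
        assert fit.terms["Tumor*MSI"].ss == pytest.approx(0.045, abs=1e-12)
        assert fit.terms["Error"].ss == pytest.approx(0.0, abs=1e-12)
        assert fit.effects["delta_beta_msi"] == pytest.approx(0.4)
        assert fit.effects["delta_beta_mss"] == pytest.approx(0.1)

    def test_equal_deltas_zero_interaction_ss(self):
        y = np.array([0.2, 0.5, 0.3, 0.6, 0.25, 0.55, 0.35, 0.65])
        tumor = np.array([0, 1, 0, 1, 0, 1, 0, 1], bool)
        msi = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        fit = fit_interaction_model(y, tumor, msi)
        assert fit.terms["Tumor*MSI"].ss == pytest.approx(0.0, abs=1e-12)

    def test_type_iii_equals_model_comparison_unbalanced(self):
        """Marginal (Type III) F matches the brute-force full-vs-reduced fit
        on unbalanced designs (3 MSS vs 2 MSI persons)."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            tumor = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], bool)
            msi = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1], bool)
            y = rng.random(10)
            fit = fit_interaction_model(y, tumor, msi)
            X = np.column_stack(
                [
                    np.ones(10),
                    np.where(tumor, 1.0, -1.0),
                    np.where(msi, 1.0, -1.0),
                    np.where(tumor, 1.0, -1.0) * np.where(msi, 1.0, -1.0),
                ]
            )

            def sse(M):
                b = np.linalg.lstsq(M, y, rcond=None)[0]
                r = y - M @ b
                return r @ r

            full = sse(X)
            for j, name in ((1, "Tumor"), (2, "MSI"), (3, "Tumor*MSI")):
                f_oracle = (sse(np.delete(X, j, axis=1)) - full) / (full / 6)
                assert fit.terms[name].f == pytest.approx(f_oracle, rel=1e-8, abs=1e-10)

    def test_empty_cell_flagged(self):
        y = np.array([0.1, 0.2, 0.3, 0.4])
        tumor = np.array([1, 1, 0, 0], bool)
        msi = np.array([1, 1, 1, 1], bool)  # no MSS samples at all
        fit = fit_interaction_model(y, tumor, msi)
        assert "inestimable_interaction" in fit.flags

    def test_split_plot_interaction_equals_two_sample_t_on_differences(self):
        sheet = tiny_sheet(
            [(f"p{i}", t, "MSI" if i < 3 else "MSS", "left") for i in range(8) for t in ("tumor", "normal")]
        )
        rng = np.random.default_rng(3)
        y = rng.random(len(sheet))
        tumor = (sheet["tissue"] == "tumor").to_numpy()
        msi = (sheet["msi_status"] == "MSI").to_numpy()
        fit = fit_interaction_model(y, tumor, msi, include_person=True, person=sheet["person_id"])
        d = y[tumor] - y[~tumor]
        m = msi[tumor]
        t, p = stats.ttest_ind(d[m], d[~m], equal_var=True)
        assert fit.terms["Tumor*MSI"].f == pytest.approx(t**2, rel=1e-9)
        assert fit.terms["Tumor*MSI"].p == pytest.approx(p, rel=1e-9)


class TestLocationModel:
    def test_constant_location_reduces_to_interaction_model(self):
        rng = np.random.default_rng(4)
        y = rng.random(12)
        tumor = np.tile([True, False], 6)
        msi = np.repeat([True, False], 6)
        location = np.array(["left"] * 12)
        fit3 = fit_location_model(y, tumor, msi, location)
        fit2 = fit_interaction_model(y, tumor, msi)
        assert fit3.terms["Tumor*MSI"].f == pytest.approx(fit2.terms["Tumor*MSI"].f, rel=1e-8)
        assert "inestimable:Location" in fit3.flags

    def test_pure_location_interaction_zero_msi_interaction_ss(self):
        # zero-noise data with only a Tumor*Location effect
        rows = []
        for i in range(8):
            msi = "MSI" if i % 2 else "MSS"
            loc = "right" if i < 4 else "left"
            rows += [(f"p{i}", "tumor", msi, loc), (f"p{i}", "normal", msi, loc)]
        sheet = tiny_sheet(rows)
        tumor = (sheet["tissue"] == "tumor").to_numpy()
        right = (sheet["location"] == "right").to_numpy()
        y = 0.4 + 0.2 * (tumor & right)  # tumor effect only on the right side
        fit = fit_location_model(
            y, tumor, (sheet["msi_status"] == "MSI").to_numpy(), sheet["location"].to_numpy()
        )
        assert fit.terms["Tumor*MSI"].ss == pytest.approx(0.0, abs=1e-12)
        assert fit.terms["Tumor*Location"].ss > 0

    def test_collinear_msi_location_flagged(self):
        rows = []
        for i in range(6):
            msi = "MSI" if i < 3 else "MSS"
            loc = "right" if i < 3 else "left"  # MSI == right exactly
            rows += [(f"p{i}", "tumor", msi, loc), (f"p{i}", "normal", msi, loc)]
        sheet = tiny_sheet(rows)
        y = np.random.default_rng(5).random(len(sheet))
        fit = fit_location_model(
            y,
            (sheet["tissue"] == "tumor").to_numpy(),
            (sheet["msi_status"] == "MSI").to_numpy(),
            sheet["location"].to_numpy(),
        )
        assert "collinear_design" in fit.flags

    def test_planted_msi_effect_found_location_not(self, cohort_sheet):
        effects = [synthetic.LocusEffectSpec("msi_only", 0.3, 0.0, 0.5)]
        m, _ = synthetic.simulate_beta_matrix(cohort_sheet, effects, synthetic.NoiseSpec(), seed=51)
        res = genomewide_scan(m, cohort_sheet, "location")
        assert res["p_interaction"].iloc[0] < 1e-6
        assert res["p_tumor_x_location"].iloc[0] > 0.001


class TestVarianceDecomposition:
    def test_constant_response_degenerate(self):
        y, pairs = _pairing([0.0, 0.0])
        fit = fit_paired_model(y, pairs)
        out = variance_decomposition(fit)
        assert "degenerate" in out["flags"]
        assert all(v == 0 for v in out["shares"].values())

    def test_person_only_spread_gives_person_share_one(self):
        y = pd.Series({"p0_T": 0.2, "p0_N": 0.2, "p1_T": 0.7, "p1_N": 0.7})
        fit = fit_paired_model(y, {"p0": ("p0_T", "p0_N"), "p1": ("p1_T", "p1_N")})
        out = variance_decomposition(fit)
        assert out["shares"]["Person"] == pytest.approx(1.0)

    def test_shares_sum_to_one(self):
        y, pairs = _pairing([0.1, 0.25, -0.1, 0.3], base=0.45)
        y += pd.Series(dict(zip(y.index, np.linspace(0, 0.2, len(y)))))
        out = variance_decomposition(fit_paired_model(y, pairs))
        assert sum(out["shares"].values()) == pytest.approx(1.0, abs=1e-10)


class TestScan:
    def test_stratum_restricts_to_group_pairs(self, cohort_sheet):
        effects = synthetic.make_effect_panel({"null": 3}, seed=6)
        m, _ = synthetic.simulate_beta_matrix(cohort_sheet, effects, synthetic.NoiseSpec(), seed=6)
        res = genomewide_scan(m, cohort_sheet, "paired", stratum="MSI")
        assert (res["n_eff"] == 30).all()
        res_all = genomewide_scan(m, cohort_sheet, "paired")
        assert (res_all["n_eff"] == 125).all()

    def test_permutation_equivariance(self, cohort_sheet):
        effects = synthetic.make_effect_panel({"null": 6, "msi_only": 2}, seed=7)
        m, _ = synthetic.simulate_beta_matrix(cohort_sheet, effects, synthetic.NoiseSpec(), seed=7)
        res = genomewide_scan(m, cohort_sheet, "interaction")
        perm = m.index[::-1]
        res_perm = genomewide_scan(m.loc[perm], cohort_sheet, "interaction")
        pd.testing.assert_frame_equal(res_perm, res.loc[perm])

    def test_unknown_sample_rejected(self, cohort_sheet):
        m = pd.DataFrame([[0.5]], index=["cg1"], columns=["nobody"])
        with pytest.raises(ValidationError):
            genomewide_scan(m, cohort_sheet, "paired")

    def test_nan_loci_flagged_never_dropped(self, small_sheet):
        effects = synthetic.make_effect_panel({"null": 2}, seed=8)
        m, _ = synthetic.simulate_beta_matrix(small_sheet, effects, synthetic.NoiseSpec(), seed=8)
        m.iloc[0, :] = np.nan
        res = genomewide_scan(m, small_sheet, "paired")
        assert len(res) == 2
        assert res["flags"].iloc[0] == "insufficient_data"
        assert res["flags"].iloc[1] == ""

    def test_person_free_interaction_conservative_under_person_effects(self, cohort_sheet):
        """With person intercepts in the data, the person-free interaction
        F-test rejects at most at the nominal rate (its MSE is inflated)."""
        effects = synthetic.make_effect_panel({"null": 800}, seed=61)
        m, _ = synthetic.simulate_beta_matrix(cohort_sheet, effects, synthetic.NoiseSpec(), seed=62)
        res = genomewide_scan(m, cohort_sheet, "interaction")
        rate = (res["p_interaction"] < 0.05).mean()
        assert rate <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / 800)
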