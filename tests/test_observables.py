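"""CSP, intensity ratios, ΔPRE, Gaussian smoothing, shift normalization.

The CSP and smoothing implementations are checked against independent
brute-force re-evaluations of their defining formulas.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nmrcube import (
    ObservableConfig,
    PeakRow,
    PeaklistTable,
    Series,
    combined_csp,
    compute_observables,
    delta_shifts,
    dpre,
    gaussian_smooth,
    intensity_ratio,
    read_predicted_profile,
    shift_normalize,
)


# ---------------------------------------------------------------------------
# independent oracles

def csp_oracle(dh: float, dx: float, alpha: float) -> float:
    return math.sqrt(0.5 * (dh * dh + (alpha * dx) ** 2))


def smooth_oracle(profile: pd.Series, sigma: float, hw: int) -> pd.Series:
    """Brute-force double-loop kernel sum over residue-number offsets."""
    out = {}
    for i in profile.index:
        num = den = 0.0
        seen = False
        for j in range(-hw, hw + 1):
            k = i + j
            if k in profile.index and not math.isnan(profile[k]):
                w = math.exp(-j * j / (2.0 * sigma * sigma))
                num += w * profile[k]
                den += w
                seen = True
        out[i] = num / den if seen else math.nan
    return pd.Series(out)


def table_pair(shifts_ref, shifts_tgt, heights_ref=None, heights_tgt=None):
    def build(shifts, heights):
        rows = []
        for i, (sx, sh) in enumerate(shifts, start=1):
            h = heights[i - 1] if heights else 1e7
            rows.append(PeakRow(i, "A", "N", "H", sx, sh, height=h))
        return PeaklistTable(rows)
    return build(shifts_ref, heights_ref), build(shifts_tgt, heights_tgt)


# ---------------------------------------------------------------------------

class TestDeltaShifts:
    def test_identity_reference_gives_zero(self):
        ref, tgt = table_pair([(120.0, 8.2)], [(120.0, 8.2)])
        dh, dx = delta_shifts(ref, tgt)
        assert dh.iloc[0] == 0.0 and dx.iloc[0] == 0.0

    def test_simple_subtraction(self):
        ref, tgt = table_pair([(120.0, 8.20)], [(120.5, 8.30)])
        dh, dx = delta_shifts(ref, tgt)
        assert dh.iloc[0] == pytest.approx(0.10, abs=1e-12)
        assert dx.iloc[0] == pytest.approx(0.50, abs=1e-12)

    def test_unassigned_rows_give_nan(self):
        ref = PeaklistTable([PeakRow(1, "P", status="unassigned")])
        tgt = PeaklistTable([PeakRow(1, "P", status="unassigned")])
        dh, dx = delta_shifts(ref, tgt)
        assert math.isnan(dh.iloc[0]) and math.isnan(dx.iloc[0])

    def test_index_mismatch_is_a_contract_violation(self):
        ref, _ = table_pair([(120.0, 8.2)], [(120.0, 8.2)])
        tgt = PeaklistTable([PeakRow(2, "A", "N", "H", 119.0, 8.1)])
        with pytest.raises(ValueError, match="curation"):
            delta_shifts(ref, tgt)


class TestCombinedCsp:
    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(7)
        dh = pd.Series(rng.normal(0, 0.1, 10_000))
        dx = pd.Series(rng.normal(0, 0.8, 10_000))
        alpha = 0.14
        expected = np.array([
            csp_oracle(h, x, alpha) for h, x in zip(dh, dx)
        ])
        got = combined_csp(dh, dx, alpha).to_numpy()
        assert np.max(np.abs(got - expected)) < 1e-12

    def test_hand_checked_value(self):
        # (0.10, 1.00) at alpha 0.14 -> sqrt(0.5*(0.01+0.0196))
        got = combined_csp(pd.Series([0.10]), pd.Series([1.00]), 0.14)
        assert got.iloc[0] == pytest.approx(0.12165525060596439, abs=1e-15)

    def test_zero_and_single_nucleus_reductions(self):
        assert combined_csp(pd.Series([0.0]), pd.Series([0.0])).iloc[0] == 0.0
        d = 0.08
        got = combined_csp(pd.Series([d]), pd.Series([0.0])).iloc[0]
        assert got == pytest.approx(d / math.sqrt(2), rel=1e-14)

    @settings(max_examples=200, derandomize=True)
    @given(
        dh=st.floats(-1, 1), dx=st.floats(-5, 5),
        bump_h=st.floats(0, 1), bump_x=st.floats(0, 5),
    )
    def test_monotone_in_either_delta_magnitude(self, dh, dx, bump_h,
                                                bump_x):
        base = csp_oracle(dh, dx, 0.14)
        grown_h = combined_csp(
            pd.Series([abs(dh) + bump_h]), pd.Series([dx]), 0.14).iloc[0]
        grown_x = combined_csp(
            pd.Series([dh]), pd.Series([abs(dx) + bump_x]), 0.14).iloc[0]
        assert grown_h >= base - 1e-12
        assert grown_x >= base - 1e-12

    def test_glycine_alpha_applied_per_residue(self):
        table = PeaklistTable([
            PeakRow(1, "G", "N", "H", 108.0, 8.0),
            PeakRow(2, "A", "N", "H", 120.0, 8.0),
        ])
        from nmrcube.observables import alpha_series
        alphas = alpha_series(table, ObservableConfig())
        assert alphas.loc[1] == 0.2 and alphas.loc[2] == 0.14


class TestIntensityRatio:
    def test_basic_ratio_and_identity(self):
        ref, tgt = table_pair([(120.0, 8.2)], [(120.0, 8.2)],
                              heights_ref=[2e6], heights_tgt=[1e6])
        assert intensity_ratio(ref, tgt).iloc[0] == 0.5
        assert intensity_ratio(ref, ref).iloc[0] == 1.0

    def test_zero_reference_yields_nan_not_inf(self, caplog):
        ref, tgt = table_pair([(120.0, 8.2)], [(120.0, 8.2)],
                              heights_ref=[0.0], heights_tgt=[1e6])
        with caplog.at_level("WARNING"):
            ratio = intensity_ratio(ref, tgt)
        assert math.isnan(ratio.iloc[0])
        assert any("zero reference" in r.message for r in caplog.records)

    def test_volume_kind_uses_volume_column(self):
        ref = PeaklistTable([PeakRow(1, "A", "N", "H", 120, 8.2,
                                     height=1e6, volume=4e6)])
        tgt = PeaklistTable([PeakRow(1, "A", "N", "H", 120, 8.2,
                                     height=2e6, volume=1e6)])
        assert intensity_ratio(ref, tgt, "volume").iloc[0] == 0.25


class TestDpre:
    def test_equal_profiles_give_zero(self):
        prof = pd.Series([0.9, 0.5, 0.2], index=[1, 2, 3])
        assert (dpre(prof, prof) == 0).all()

    def test_sign_convention_predicted_minus_observed(self):
        observed = pd.Series([0.5], index=[1])
        predicted = pd.Series([0.3], index=[1])
        assert dpre(observed, predicted).iloc[0] == pytest.approx(-0.2)
        assert dpre(observed, predicted, sign=-1).iloc[0] == \
            pytest.approx(0.2)

    def test_antisymmetric_under_profile_swap(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.uniform(0, 1, 50), index=range(1, 51))
        b = pd.Series(rng.uniform(0, 1, 50), index=range(1, 51))
        assert np.allclose(dpre(a, b), -dpre(b, a), equal_nan=True)

    def test_residue_in_one_profile_only_is_empty(self, caplog):
        observed = pd.Series([0.5, 0.4], index=[1, 2])
        predicted = pd.Series([0.5], index=[1])
        with caplog.at_level("WARNING"):
            out = dpre(observed, predicted)
        assert math.isnan(out.loc[2])
        assert any("only one" in r.message for r in caplog.records)

    def test_out_of_range_ratios_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dpre(pd.Series([1.5], index=[1]), pd.Series([0.5], index=[1]))

    def test_predicted_profile_reader(self, tmp_path):
        p = tmp_path / "pred.csv"
        p.write_text("# coil model\n10 0.95\n11 0.80\n12 0.40\n")
        prof = read_predicted_profile(p)
        assert list(prof.index) == [10, 11, 12]
        assert prof.loc[12] == 0.40


class TestGaussianSmooth:
    def test_matches_brute_force_on_random_gapped_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            index = np.sort(rng.choice(np.arange(1, 80), size=n,
                                       replace=False))
            vals = rng.normal(0, 1, size=n)
            vals[rng.random(n) < 0.2] = np.nan
            profile = pd.Series(vals, index=index)
            sigma = float(rng.uniform(0.5, 4.0))
            hw = int(rng.integers(1, 10))
            got = gaussian_smooth(profile, sigma, hw)
            want = smooth_oracle(profile, sigma, hw)
            assert np.allclose(got, want, atol=1e-12, equal_nan=True)

    def test_constant_profile_is_conserved(self):
        profile = pd.Series(3.7, index=range(1, 31))
        out = gaussian_smooth(profile, sigma=3.0)
        assert np.allclose(out, 3.7, atol=1e-12)

    def test_halfwidth_zero_is_identity(self):
        profile = pd.Series([1.0, 5.0, -2.0], index=[1, 2, 3])
        out = gaussian_smooth(profile, sigma=0.1, halfwidth=0)
        assert np.allclose(out, profile)

    def test_impulse_response_closed_form(self):
        profile = pd.Series([0, 0, 1.0, 0, 0], index=[1, 2, 3, 4, 5])
        out = gaussian_smooth(profile, sigma=1.0, halfwidth=2)
        norm = 1 + 2 * math.exp(-0.5) + 2 * math.exp(-2.0)
        assert out.loc[3] == pytest.approx(1.0 / norm, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=25),
           st.floats(0.5, 5.0))
    def test_output_within_profile_range(self, values, sigma):
        profile = pd.Series(values, index=range(1, len(values) + 1))
        out = gaussian_smooth(profile, sigma)
        assert out.max() <= profile.max() + 1e-9
        assert out.min() >= profile.min() - 1e-9

    def test_linearity_on_fixed_index(self):
        rng = np.random.default_rng(5)
        idx = range(1, 21)
        u = pd.Series(rng.normal(size=20), index=idx)
        v = pd.Series(rng.normal(size=20), index=idx)
        a, b = 2.5, -1.25
        left = gaussian_smooth(a * u + b * v, 2.0, 6)
        right = a * gaussian_smooth(u, 2.0, 6) + b * gaussian_smooth(v, 2.0, 6)
        assert np.allclose(left, right, atol=1e-10)

    def test_all_nan_profile_gives_empty_output(self):
        profile = pd.Series([np.nan, np.nan], index=[1, 2])
        out = gaussian_smooth(profile, 1.0)
        assert out.isna().all()


class TestShiftNormalize:
    def make_series(self, offset=(0.0, 0.0)):
        ref = PeaklistTable([
            PeakRow(1, "A", "N", "H", 120.0, 8.0),
            PeakRow(2, "L", "N", "H", 118.0, 8.4),
        ])
        tgt = PeaklistTable([
            PeakRow(1, "A", "N", "H", 120.0 + offset[1], 8.0 + offset[0]),
            PeakRow(2, "L", "N", "H", 118.3 + offset[1], 8.45 + offset[0]),
        ])
        return Series(along="x", fixed={"y": "wt", "z": "apo"},
                      labels=("0", "1"), tables=[ref, tgt])

    def test_reference_residue_csp_zeroed_at_all_points(self):
        series = shift_normalize(self.make_series(offset=(0.02, 0.1)), 1)
        dh, dx = delta_shifts(series.reference, series.tables[1])
        assert dh.loc[1] == pytest.approx(0.0, abs=1e-12)
        assert dx.loc[1] == pytest.approx(0.0, abs=1e-12)

    def test_global_artifact_removed(self):
        clean = self.make_series()
        shifted = self.make_series(offset=(0.02, 0.1))
        norm = shift_normalize(shifted, 1)
        dh_clean, dx_clean = delta_shifts(clean.reference, clean.tables[1])
        dh_norm, dx_norm = delta_shifts(norm.reference, norm.tables[1])
        assert np.allclose(dh_clean, dh_norm, atol=1e-12)
        assert np.allclose(dx_clean, dx_norm, atol=1e-12)

    def test_idempotent(self):
        once = shift_normalize(self.make_series(offset=(0.02, 0.1)), 1)
        twice = shift_normalize(once, 1)
        for a, b in zip(once.tables, twice.tables):
            assert np.allclose(a.frame["shift_f1"], b.frame["shift_f1"])

    def test_missing_reference_residue_reports_points(self):
        series = self.make_series()
        frame = series.tables[1].frame
        series.tables[1] = series.tables[1].replace_frame(
            frame[frame["residue_number"] != 1])
        with pytest.raises(ValueError, match=r"\['1'\]"):
            shift_normalize(series, 1)


class TestComputeObservables:
    def test_csp_monotone_along_saturating_titration(self, titration_series,
                                                     noisy_titration):
        from nmrcube import pad_tables
        _, truth = noisy_titration
        padded = pad_tables(titration_series)
        results = compute_observables(padded)
        responders = truth[truth["is_responder"]]["residue_number"]
        csp = pd.DataFrame({
            lbl: t.frame.set_index("residue_number")["csp"]
            for lbl, t in zip(padded.labels, results)
        })
        # fast exchange saturation: CSP non-decreasing along x up to noise
        steps = csp.loc[responders].diff(axis=1).iloc[:, 1:]
        assert (steps.stack() > -0.01).all()

    def test_derived_columns_empty_for_unassigned(self, titration_series,
                                                  noisy_titration):
        from nmrcube import pad_tables, scan_series
        _, truth = noisy_titration
        seq = dict(zip(truth["residue_number"], truth["residue_type"]))
        padded = pad_tables(titration_series,
                            scan_series(titration_series, seq))
        results = compute_observables(padded)
        last = results[-1].frame.set_index("residue_number")
        unassigned = truth[truth["is_unassigned"]]["residue_number"]
        assert last.loc[unassigned, "csp"].isna().all()
        assert (last.loc[unassigned, "status"] == "unassigned").all()
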