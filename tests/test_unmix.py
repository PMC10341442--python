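"""Mixture-model fitting: exact recovery, oracle equivalence, batching."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemospec.basis import ExtinctionBasis, synth_basis
from hemospec.errors import (
    AlignmentError,
    DegenerateFitError,
    UndefinedFractionError,
)
from hemospec.synthetic import make_spectrum
from hemospec.unmix import (
    FitOptions,
    Fractions,
    Spectrum,
    UnmixResult,
    batch_fit,
    design_matrix,
    fit_spectrum,
    fractions,
)

L = 0.1  # cm, the 1 mm cuvette layer


def _toy_result(c_hbo2, c_hb, c_methb):
    return UnmixResult(
        c_hbo2=c_hbo2,
        c_hb=c_hb,
        c_methb=c_methb,
        m_offset=0.0,
        s_rayleigh=0.0,
        se={},
        r_squared=1.0,
        residuals=np.zeros(5),
        path_length_cm=L,
    )


class TestFitSpectrum:
    def test_pure_oxyhemoglobin_recovered_exactly(self, basis):
        spectrum = Spectrum(basis.wavelengths_nm, L * basis.eps_hbo2 * 1.5)
        result = fit_spectrum(spectrum, basis, L)
        assert result.c_hbo2 == pytest.approx(1.5, abs=1e-9)
        assert result.c_hb == 0.0
        assert result.c_methb == 0.0
        assert np.max(np.abs(result.residuals)) < 1e-8
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_forward_inverse_identity(self, basis, seed):
        """Noise-free forward spectra return all five parameters."""
        rng = np.random.default_rng(seed)
        truth = {
            "c_hbo2": rng.uniform(0.05, 2.0),
            "c_hb": rng.uniform(0.05, 2.0),
            "c_methb": rng.uniform(0.05, 2.0),
            "m_offset": rng.uniform(-0.05, 0.05),
            "s_rayleigh": rng.uniform(0.005, 0.05) * 550.0**4,
        }
        fr_total = truth["c_hbo2"] + truth["c_hb"] + truth["c_methb"]
        fr = Fractions(
            100 * truth["c_hbo2"] / fr_total,
            100 * truth["c_hb"] / fr_total,
            100 * truth["c_methb"] / fr_total,
        )
        spectrum = make_spectrum(
            fr, fr_total, basis, L, m=truth["m_offset"], s_au_nm4=truth["s_rayleigh"]
        )
        result = fit_spectrum(spectrum, basis, L)
        for name, value in truth.items():
            assert getattr(result, name) == pytest.approx(value, rel=1e-6)

    def test_homogeneity_in_heme_part(self, basis):
        fr = Fractions(30.0, 50.0, 20.0)
        base = make_spectrum(fr, 0.5, basis, L)
        scaled = Spectrum(base.wavelengths_nm, 3.0 * base.absorbance)
        r1 = fit_spectrum(base, basis, L)
        r2 = fit_spectrum(scaled, basis, L)
        assert r2.c_hbo2 == pytest.approx(3 * r1.c_hbo2, rel=1e-8)
        assert r2.c_hb == pytest.approx(3 * r1.c_hb, rel=1e-8)
        assert r2.c_methb == pytest.approx(3 * r1.c_methb, rel=1e-8)

    def test_grid_mismatch_raises_alignment_error(self, basis):
        spectrum = Spectrum(np.arange(500.0, 700.0, 2.0), np.ones(100))
        with pytest.raises(AlignmentError):
            fit_spectrum(spectrum, basis, L)

    def test_rank_deficiency_names_offending_columns(self, grid):
        shared = np.exp(-0.5 * ((grid - 560) / 20.0) ** 2)
        degenerate = ExtinctionBasis(
            wavelengths_nm=grid,
            eps_hbo2=shared,
            eps_hb=shared,
            eps_methb=np.exp(-0.5 * ((grid - 630) / 12.0) ** 2),
        )
        spectrum = Spectrum(grid, 0.5 * shared + 0.1)
        with pytest.raises(DegenerateFitError) as err:
            fit_spectrum(spectrum, degenerate, L)
        assert "c_hbo2" in err.value.columns and "c_hb" in err.value.columns

    def test_constrained_sse_never_beats_unconstrained(self, basis):
        """Active constraints can only raise the SSE; inactive ones leave it
        equal to the ordinary least-squares optimum."""
        rng = np.random.default_rng(7)
        design = design_matrix(basis.wavelengths_nm, basis, L)
        # infeasible truth (negative Hb coefficient) forces the bound to bind
        y_infeasible = design @ np.array([0.5, -0.3, 0.2, 0.01, 0.02])
        y_infeasible = y_infeasible + rng.normal(0, 0.002, y_infeasible.size)
        spectrum = Spectrum(basis.wavelengths_nm, y_infeasible)
        constrained = fit_spectrum(spectrum, basis, L)
        unconstrained, *_ = np.linalg.lstsq(design, y_infeasible, rcond=None)
        sse_unc = float(np.sum((y_infeasible - design @ unconstrained) ** 2))
        assert constrained.c_hb == 0.0
        assert constrained.sse >= sse_unc - 1e-12

        y_feasible = design @ np.array([0.5, 0.3, 0.2, 0.01, 0.02])
        y_feasible = y_feasible + rng.normal(0, 0.002, y_feasible.size)
        feasible_fit = fit_spectrum(Spectrum(basis.wavelengths_nm, y_feasible), basis, L)
        unc, *_ = np.linalg.lstsq(design, y_feasible, rcond=None)
        sse_unc = float(np.sum((y_feasible - design @ unc) ** 2))
        assert feasible_fit.sse == pytest.approx(sse_unc, rel=1e-9)

    def test_standard_errors_finite_for_free_nan_for_pinned(self, basis):
        fr = Fractions(70.0, 30.0, 0.0)  # no MetHb -> its bound binds
        spectrum = make_spectrum(fr, 0.66, basis, L, m=0.02, noise_sd=0.004, seed=3)
        result = fit_spectrum(spectrum, basis, L)
        assert np.isfinite(result.se["c_hbo2"])
        assert np.isfinite(result.se["c_hb"])
        if result.c_methb == 0.0:
            assert np.isnan(result.se["c_methb"])

    def test_summary_reports_value_pm_se_and_r_squared(self, basis):
        fr = Fractions(50.0, 40.0, 10.0)
        spectrum = make_spectrum(fr, 0.66, basis, L, noise_sd=0.003, seed=1)
        text = fit_spectrum(spectrum, basis, L).summary()
        assert "±" in text and "R²" in text


def _lattice_oracle_2d(design, y, step=1e-3, cmax=2.0):
    """Exhaustive non-negative lattice search, chunked brute force."""
    grid = np.arange(0.0, cmax + step / 2, step)
    best = (np.inf, None)
    for start in range(0, grid.size, 200):
        c1 = grid[start : start + 200]
        resid = (
            y[None, None, :]
            - c1[:, None, None] * design[:, 0][None, None, :]
            - grid[None, :, None] * design[:, 1][None, None, :]
        )
        sse = np.sum(resid**2, axis=2)
        idx = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[idx] < best[0]:
            best = (float(sse[idx]), (float(c1[idx[0]]), float(grid[idx[1]])))
    return best[1]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_two_component_fit_matches_lattice_search(self, seed):
        """Constrained least squares agrees with brute-force lattice search
        on noisy 5-wavelength, 2-component toy problems."""
        rng = np.random.default_rng(100 + seed)
        wl = np.array([520.0, 545.0, 560.0, 590.0, 630.0])
        toy_basis = synth_basis(grid=wl)
        design = design_matrix(wl, toy_basis, L)[:, :2]
        truth = rng.uniform(0.2, 1.8, size=2)
        y = design @ truth + rng.normal(0, 0.01, wl.size)
        spectrum = Spectrum(wl, y)
        options = FitOptions(
            components=("hbo2", "hb"), fit_offset=False, fit_rayleigh=False
        )
        result = fit_spectrum(spectrum, toy_basis, L, options)
        oracle = _lattice_oracle_2d(design, y)
        assert result.c_hbo2 == pytest.approx(oracle[0], abs=2e-3)
        assert result.c_hb == pytest.approx(oracle[1], abs=2e-3)


class TestFractions:
    def test_normalization(self):
        fr = fractions(_toy_result(1.0, 1.0, 2.0))
        assert fr.as_tuple() == pytest.approx((25.0, 25.0, 50.0))

    @pytest.mark.parametrize("c", [0.1, 1.0, 17.3])
    def test_single_component(self, c):
        fr = fractions(_toy_result(c, 0.0, 0.0))
        assert fr.as_tuple() == pytest.approx((100.0, 0.0, 0.0))

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedFractionError):
            fractions(_toy_result(0.0, 0.0, 0.0))

    @given(
        st.tuples(
            st.floats(0, 10, allow_nan=False),
            st.floats(0, 10, allow_nan=False),
            st.floats(0, 10, allow_nan=False),
        ).filter(lambda c: sum(c) > 1e-6)
    )
    def test_percentages_sum_to_100(self, concentrations):
        fr = fractions(_toy_result(*concentrations))
        assert sum(fr.as_tuple()) == pytest.approx(100.0, abs=1e-9)
        assert all(0 <= p <= 100 for p in fr.as_tuple())


class TestBatchFit:
    def _spectra(self, basis, days=(0, 7, 14)):
        out = []
        for day, hb in zip(days, (20.0, 50.0, 80.0)):
            fr = Fractions(100.0 - hb, hb, 0.0)
            sp = make_spectrum(
                fr, 0.66, basis, L,
                meta={"sample_id": f"s{day}", "day": day, "sts_pct": 0.0,
                      "tube": "closed", "kind": "suspension"},
            )
            out.append(sp)
        return out

    def test_noise_free_batch_all_perfect(self, basis):
        table = batch_fit(self._spectra(basis), basis, L)
        assert len(table) == 3
        assert table["error"].isna().all()
        assert np.allclose(table["r_squared"], 1.0, atol=1e-10)

    def test_error_rows_do_not_abort_the_batch(self, basis):
        bad = Spectrum(np.arange(400.0, 600.0), np.ones(200),
                       meta={"sample_id": "bad", "day": 0})
        table = batch_fit(self._spectra(basis) + [bad], basis, L)
        assert len(table) == 4
        assert table["error"].notna().sum() == 1
        assert table["error"].isna().sum() == 3

    def test_cdf_trajectory_is_monotone_after_refit(self, basis):
        from scipy.special import ndtr

        days = np.array([0.0, 7.0, 14.0, 21.0, 29.0])
        hb = 20 + 65 * ndtr((days - 11) / 3)
        spectra = []
        for day, hb_pct in zip(days, hb):
            fr = Fractions(100 - hb_pct, hb_pct, 0.0)
            spectra.append(
                make_spectrum(fr, 0.66, basis, L, meta={"day": day, "tube": "closed",
                                                        "sts_pct": 0.0})
            )
        table = batch_fit(spectra, basis, L)
        assert (np.diff(table["hb_pct"]) >= -1e-9).all()

    def test_empty_input_yields_empty_table(self, basis):
        assert batch_fit([], basis, L).empty

    def test_rows_ordered_by_tube_sts_day(self, basis):
        spectra = []
        for tube, sts, day in [("open", 30.0, 7), ("closed", 0.0, 14),
                               ("closed", 0.0, 0), ("open", 0.0, 0)]:
            fr = Fractions(60.0, 40.0, 0.0)
            spectra.append(make_spectrum(
                fr, 0.5, basis, L,
                meta={"tube": tube, "sts_pct": sts, "day": day, "sample_id": "x"},
            ))
        table = batch_fit(spectra, basis, L)
        keys = list(zip(table["tube"], table["sts_pct"], table["day"]))
        assert keys == [("closed", 0.0, 0), ("closed", 0.0, 14),
                        ("open", 0.0, 0), ("open", 30.0, 7)]
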