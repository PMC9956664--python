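import numpy as np
import pandas as pd
import pytest

from iolopt.cornea import keratometric_power
from iolopt.errors import DegenerateVergenceError
from iolopt.formulas import (
    FORMULAS,
    CastropConstants,
    FormulaSpec,
    HaigisConstants,
    HofferQConstants,
    Holladay1Constants,
    cmal,
    elp_castrop,
    elp_haigis,
    elp_hofferq,
    elp_holladay1,
    nominal_constants,
    predict,
    predict_cohort,
    prediction_error,
    published_index,
    seq_thick_chain,
    seq_thin_chain,
)
from iolopt.preprocess import derive

from .conftest import random_eyes
from .oracles import matrix_seq_thick, matrix_seq_thin


def cohort_from(eyes, sphere=0.0):
    df = pd.DataFrame(eyes)
    df["sphere"] = sphere
    df["cylinder"] = 0.0
    return derive(df)


class TestVergenceChains:
    def test_thin_chain_matches_matrix_oracle(self, rng):
        for _ in range(300):
            al = rng.uniform(20, 29)
            elp = rng.uniform(3.5, 6.5)
            dc = rng.uniform(38, 49)
            piol = rng.uniform(-3, 32)
            got = seq_thin_chain(al, elp, dc, piol)
            want = matrix_seq_thin(al, elp, dc, piol)
            assert got == pytest.approx(want, abs=1e-10)

    def test_thick_chain_matches_matrix_oracle(self, rng):
        for _ in range(300):
            al = rng.uniform(21, 28)
            elp = rng.uniform(3.5, 6.5)
            cct = rng.uniform(430, 640)
            nc = rng.uniform(1.33, 1.41)
            rf = rng.uniform(7.0, 8.6)
            p1 = (nc - 1) / (rf * 1e-3)
            p2 = (1.336 - nc) / (0.834 * rf * 1e-3)
            piol = rng.uniform(-3, 32)
            got = seq_thick_chain(al, elp, p1, p2, cct, nc, piol)
            want = matrix_seq_thick(al, elp, p1, p2, cct, nc, piol)
            assert got == pytest.approx(want, abs=1e-10)

    def test_thick_collapses_to_thin_as_cct_vanishes(self):
        dc = 43.0
        thin = seq_thin_chain(24.0, 5.0, dc, 21.0)
        thick = seq_thick_chain(24.0, 5.0, dc, 0.0, 1e-9, 1.376, 21.0)
        assert thick == pytest.approx(thin, abs=1e-9)

    def test_zero_power_iol_elp_invariance(self):
        a = seq_thin_chain(24.0, 3.0, 43.0, 0.0)
        b = seq_thin_chain(24.0, 6.0, 43.0, 0.0)
        assert a == pytest.approx(b, abs=1e-12)
        c = seq_thick_chain(24.0, 3.0, 48.0, -5.8, 550, 1.376, 0.0)
        d = seq_thick_chain(24.0, 6.0, 48.0, -5.8, 550, 1.376, 0.0)
        assert c == pytest.approx(d, abs=1e-12)

    def test_emmetropic_piol_construction(self):
        """The lens power that exactly images the far point at infinity
        yields a zero predicted refraction, independent of vertex."""
        al, elp, dc, n = 24.0, 5.0, 43.0, 1.336
        z = n / ((al - elp) * 1e-3)
        piol = z - dc / (1 - (elp * 1e-3) * dc / n)
        for vd in (10.0, 12.0, 14.0):
            assert seq_thin_chain(al, elp, dc, piol, vertex_mm=vd) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_degenerate_raises_or_nans(self):
        # ELP equals AL: retina distance zero
        with pytest.raises(DegenerateVergenceError):
            seq_thin_chain(24.0, 24.0, 43.0, 21.0)
        out = seq_thin_chain(24.0, 24.0, 43.0, 21.0, on_degenerate="nan")
        assert np.isnan(out)


class TestElpParts:
    def test_hofferq_clamping_identity(self):
        k = 43.5
        assert elp_hofferq(31.0, k, 5.7) == elp_hofferq(35.0, k, 5.7)
        assert elp_hofferq(18.5, k, 5.7) == elp_hofferq(16.0, k, 5.7)

    def test_hofferq_pacd_additivity(self):
        base = elp_hofferq(24.0, 43.5, 5.0)
        assert elp_hofferq(24.0, 43.5, 5.3) == pytest.approx(base + 0.3)

    def test_hofferq_snapshot_at_cohort_medians(self):
        from iolopt.preprocess import power_mean_radius

        k = keratometric_power(power_mean_radius(7.8473, 7.6735), 1.3375)
        elp = elp_hofferq(23.9026, k, 5.7356)
        assert 4.0 < elp < 7.0
        assert elp == pytest.approx(5.764964667274068, abs=1e-9)

    def test_holladay1_sf_additivity_and_radius_floor(self):
        base = elp_holladay1(24.0, 7.5, 1.8)
        assert elp_holladay1(24.0, 7.5, 2.1) == pytest.approx(base + 0.3)
        assert elp_holladay1(24.0, 7.0, 1.8) == elp_holladay1(24.0, 6.6, 1.8)

    def test_holladay1_snapshot_at_cohort_medians(self):
        elp = elp_holladay1(23.9026, 0.5 * (7.8473 + 7.6735), 1.9618)
        assert 4.0 < elp < 8.0
        assert elp == pytest.approx(5.850620785822974, abs=1e-9)

    def test_haigis_regression(self):
        assert elp_haigis(3.2, 24.0, HaigisConstants(0.4, 0.3, 0.2)) == pytest.approx(
            6.16
        )
        assert elp_haigis(
            3.1864, 24.0980, HaigisConstants(-0.6853, 0.3417, 0.2029)
        ) == pytest.approx(5.2930, abs=5e-5)
        assert elp_haigis(3.2, 24.0, HaigisConstants(0.7, 0.0, 0.0)) == 0.7

    def test_castrop_regression(self):
        assert elp_castrop(3.0, 4.5, 0.0, 0.4) == pytest.approx(3.4)
        assert elp_castrop(3.1864, 4.6176, 0.2746, 0.3905) == pytest.approx(
            3.1864 + 0.2746 * 4.6176 + 0.3905, abs=1e-12
        )
        base = elp_castrop(3.0, 4.5, 0.3, 0.4)
        assert elp_castrop(3.0, 4.5, 0.3, 0.5) == pytest.approx(base + 0.1)

    def test_cmal_linearity_and_snapshot(self):
        base = cmal(24.0, 4.6)
        assert cmal(25.0, 4.6) - base == pytest.approx(cmal(26.0, 4.6) - cmal(25.0, 4.6))
        assert cmal(24.0, 5.6) - base == pytest.approx(cmal(24.0, 6.6) - cmal(24.0, 5.6))
        val = cmal(24.0980, 4.6176)
        assert abs(val - 24.0980) < 1.0
        assert val == pytest.approx(24.085223708, abs=1e-9)


class TestPredictions:
    @pytest.mark.parametrize("formula", FORMULAS)
    def test_matches_matrix_oracle_on_random_eyes(self, formula, rng):
        cohort = cohort_from(random_eyes(rng, 250))
        spec = FormulaSpec(formula=formula)
        constants = nominal_constants(formula)
        res = predict_cohort(spec, cohort, constants, on_degenerate="nan")
        for i in range(len(cohort)):
            row = cohort.iloc[i]
            elp = res["ELP"].iloc[i]
            got = res["SEQ_pred"].iloc[i]
            if not np.isfinite(got):
                continue
            if formula == "hofferq":
                want = matrix_seq_thin(
                    row.AL, elp + 0.05, keratometric_power(row.Rpow, 1.3375), row.PIOL
                )
            elif formula == "holladay1":
                want = matrix_seq_thin(
                    row.AL + 0.2, elp, keratometric_power(row.Rmean, 4 / 3), row.PIOL
                )
            elif formula == "haigis":
                want = matrix_seq_thin(
                    row.AL, elp, keratometric_power(row.Rmean, 1.3315), row.PIOL
                )
            else:
                nc = 1.376
                p1 = (nc - 1) / (row.Rmean * 1e-3)
                p2 = (1.336 - nc) / (0.834 * row.Rmean * 1e-3)
                want = (
                    matrix_seq_thick(
                        cmal(row.AL, row.LT), elp, p1, p2, row.CCT, nc, row.PIOL
                    )
                    + nominal_constants("castrop").r_offset
                )
            assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("formula", FORMULAS)
    def test_zero_power_iol_is_elp_invariant(self, formula, rng):
        cohort = cohort_from(random_eyes(rng, 40))
        cohort["PIOL"] = 0.0
        spec = FormulaSpec(formula=formula)
        lo, hi = _shifted_constants(formula)
        a = predict_cohort(spec, cohort, lo)["SEQ_pred"]
        b = predict_cohort(spec, cohort, hi)["SEQ_pred"]
        if formula == "castrop":
            b = b - 0.0  # same r_offset in both constant sets
        assert np.allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("formula", FORMULAS)
    def test_seq_pred_monotone_decreasing_in_piol(self, formula, rng):
        cohort = cohort_from(random_eyes(rng, 30))
        spec = FormulaSpec(formula=formula)
        constants = nominal_constants(formula)
        prev = None
        for piol in np.arange(4.0, 32.0, 2.0):
            cur = predict_cohort(
                spec, cohort.assign(PIOL=piol), constants
            )["SEQ_pred"].to_numpy()
            if prev is not None:
                assert np.all(cur < prev)
            prev = cur

    @pytest.mark.parametrize("formula", FORMULAS)
    def test_elp_part_frozen_under_index_variation(self, formula, rng):
        cohort = cohort_from(random_eyes(rng, 60))
        constants = nominal_constants(formula)
        base = predict_cohort(FormulaSpec(formula=formula), cohort, constants)
        varied = predict_cohort(
            FormulaSpec(formula=formula, n_main=published_index(formula) - 0.01),
            cohort, constants,
        )
        assert (base["ELP"].to_numpy() == varied["ELP"].to_numpy()).all()
        assert not np.allclose(base["SEQ_pred"], varied["SEQ_pred"])

    def test_published_index_is_situation_a_identity(self, rng):
        cohort = cohort_from(random_eyes(rng, 20))
        for formula in FORMULAS:
            constants = nominal_constants(formula)
            a = predict_cohort(FormulaSpec(formula=formula), cohort, constants)
            b = predict_cohort(
                FormulaSpec(formula=formula, n_main=published_index(formula)),
                cohort, constants,
            )
            assert np.allclose(a["SEQ_pred"], b["SEQ_pred"], atol=0)

    def test_castrop_offset_shifts_prediction(self, rng):
        cohort = cohort_from(random_eyes(rng, 25))
        spec = FormulaSpec(formula="castrop")
        base = predict_cohort(spec, cohort, CastropConstants(0.3, 0.2, 0.0))
        shifted = predict_cohort(spec, cohort, CastropConstants(0.3, 0.2, 0.25))
        assert np.allclose(shifted["SEQ_pred"] - base["SEQ_pred"], 0.25, atol=1e-12)

    def test_single_record_api(self):
        from iolopt.preprocess import BiometryRecord

        rec = BiometryRecord(AL=23.9026, CCT=559, ACD=3.1848, LT=4.5929,
                             R1=7.8473, R2=7.6735, PIOL=21.0,
                             sphere=-0.25, cylinder=0.0)
        pred = predict(FormulaSpec(formula="haigis"), rec,
                       HaigisConstants(-0.6853, 0.3417, 0.2029))
        assert pred.elp_mm == pytest.approx(
            -0.6853 + 0.3417 * 3.1848 + 0.2029 * 23.9026, abs=1e-9
        )
        assert np.isfinite(pred.seq_pred)
        assert pred.pe == pytest.approx(-0.25 - pred.seq_pred)

    def test_prediction_error_definition(self):
        assert prediction_error(-0.5, -0.5) == 0.0
        assert prediction_error(0.0, -0.25) == 0.25
        assert prediction_error(0.3, 0.1) == -prediction_error(0.1, 0.3)


def _shifted_constants(formula):
    """Two constant sets whose only effect is a large ELP shift."""
    if formula == "hofferq":
        return HofferQConstants(4.5), HofferQConstants(6.5)
    if formula == "holladay1":
        return Holladay1Constants(0.8), Holladay1Constants(2.8)
    if formula == "haigis":
        return HaigisConstants(0.0, 0.3, 0.15), HaigisConstants(1.5, 0.3, 0.15)
    return CastropConstants(0.1, 0.0, 0.0), CastropConstants(0.5, 1.0, 0.0)
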