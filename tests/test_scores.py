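"""Scoring rules: clamping, MELD/MELDNa formulas, albumin extensions."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meldkit as mk
from meldkit.scores import (
    CoefficientsUnsetError,
    InvalidLabError,
    MissingDataError,
    _score_one,
    load_models,
    save_models,
    score_frame,
)

MODELS = mk.default_models()


def labs(**kw):
    base = dict(bilirubin=2.5, creatinine=1.0, inr=1.4, albumin=3.0, sodium=137.0)
    base.update(kw)
    return mk.LabPanel(**base)


class TestClamping:
    @pytest.mark.parametrize(
        "field, raw, expected",
        [
            ("creatinine", 6.0, 4.0),  # cap
            ("bilirubin", 0.4, 1.0),  # floor
            ("inr", 0.8, 1.0),
            ("albumin", 0.5, 1.0),
            ("albumin", 4.6, 4.0),
            ("sodium", 120.0, 125.0),
            ("sodium", 148.0, 140.0),
        ],
    )
    def test_bounds(self, field, raw, expected):
        clamped = mk.clamp_labs(labs(**{field: raw}))
        assert getattr(clamped, field) == expected

    def test_dialysis_forces_creatinine_cap(self):
        clamped = mk.clamp_labs(labs(creatinine=0.8, on_dialysis=True))
        assert clamped.creatinine == 4.0

    def test_idempotent(self):
        once = mk.clamp_labs(labs(bilirubin=0.2, creatinine=9.0, albumin=0.6))
        assert mk.clamp_labs(once) == once

    def test_missing_sodium_preserved(self):
        assert mk.clamp_labs(labs(sodium=None)).sodium is None

    def test_nonpositive_lab_rejected(self):
        with pytest.raises(InvalidLabError, match="bilirubin"):
            labs(bilirubin=-1.0)


class TestMeld:
    def test_all_labs_at_floor_gives_six(self):
        # 10 * 0.643 = 6.43 -> rounds down to 6
        sv = mk.meld(labs(bilirubin=1.0, creatinine=1.0, inr=1.0))
        assert sv.score == 6
        assert sv.linear == pytest.approx(6.43)

    def test_sub_floor_labs_score_like_floor(self):
        low = mk.meld(labs(bilirubin=0.3, creatinine=0.5, inr=0.9))
        floor = mk.meld(labs(bilirubin=1.0, creatinine=1.0, inr=1.0))
        assert low.score == floor.score

    def test_upper_constraint(self):
        sv = mk.meld(labs(bilirubin=40.0, creatinine=8.0, inr=6.0))
        assert sv.linear > 40
        assert sv.score == 40


class TestMeldNa:
    @pytest.mark.parametrize(
        "m, na, expected, lin",
        [
            (10, 125.0, 21, 21.25),  # published worked example
            (30, 125.0, 33, 33.75),  # published worked example
            (18, 142.0, 18, 18.0),  # sodium clamped to 140 zeroes the adjustment
        ],
    )
    def test_worked_examples(self, m, na, expected, lin):
        sv = mk.meldna(m, na)
        assert sv.score == expected
        assert sv.linear == pytest.approx(lin)

    def test_missing_sodium_raises(self):
        with pytest.raises(MissingDataError):
            mk.meldna(15, None)

    @given(
        m=st.integers(min_value=6, max_value=40),
        na=st.floats(min_value=125.0, max_value=139.5),
        dna=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_non_increasing_in_sodium(self, m, na, dna):
        hi = min(na + dna, 140.0)
        assert mk.meldna(m, na).linear >= mk.meldna(m, hi).linear
        assert mk.meldna(m, 140.0).score == m


class TestAlbuminExtension:
    def test_published_worked_examples(self):
        # refractory-ascites vignette: Na 125, albumin 2.0 g/dL
        fv = MODELS["5vmeld"]
        base_low = mk.meldna(10, 125.0)
        base_high = mk.meldna(30, 125.0)
        assert mk.apply_albumin_extension(base_low, 2.0, fv).score == 26
        assert mk.apply_albumin_extension(base_high, 2.0, fv).score == 35
        # doubling albumin to 4.0 only trims one point at high base
        assert mk.apply_albumin_extension(base_high, 4.0, fv).score == 34

    def test_zero_coefficients_is_identity(self):
        null = mk.ScoreModel(name="null", base="meldna", albumin_coeff=0.0,
                             interaction_coeff=0.0)
        base = mk.meldna(30, 125.0)
        assert mk.apply_albumin_extension(base, 2.2, null) is base

    def test_unset_coefficients_raise_with_remediation(self):
        blank = mk.ScoreModel(name="5vmeld", base="meldna")
        with pytest.raises(CoefficientsUnsetError, match="derive"):
            mk.apply_albumin_extension(mk.meldna(20, 130.0), 2.5, blank)

    @given(
        base_score=st.integers(min_value=6, max_value=40),
        alb=st.floats(min_value=1.0, max_value=3.9),
        dalb=st.floats(min_value=0.01, max_value=3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_non_increasing_in_albumin(self, base_score, alb, dalb):
        fv = MODELS["5vmeld"]
        base = mk.ScoreValue("meldna", base_score, float(base_score))
        lo = mk.apply_albumin_extension(base, alb, fv)
        hi = mk.apply_albumin_extension(base, min(alb + dalb, 4.0), fv)
        assert lo.linear >= hi.linear


@given(
    bili=st.floats(min_value=0.2, max_value=60.0),
    creat=st.floats(min_value=0.2, max_value=12.0),
    inr=st.floats(min_value=0.5, max_value=12.0),
    alb=st.floats(min_value=0.5, max_value=8.0),
    na=st.floats(min_value=110.0, max_value=155.0),
    dial=st.booleans(),
)
@settings(max_examples=150, deadline=None)
def test_all_models_yield_integers_in_bounds(bili, creat, inr, alb, na, dial):
    """Fuzz: every model maps any valid lab panel to an integer in [6, 40]."""
    panel = mk.LabPanel(bilirubin=bili, creatinine=creat, inr=inr, albumin=alb,
                        sodium=na, on_dialysis=dial)
    for model in MODELS.values():
        sv = _score_one(panel, model)
        assert isinstance(sv.score, int) and 6 <= sv.score <= 40


class TestScoreCohort:
    def make_cohort(self):
        return pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "bili_mgdl": [2.0, 3.0, 1.5],
                "creat_mgdl": [1.0, 2.0, 0.9],
                "inr": [1.2, 1.8, 1.1],
                "alb_gdl": [3.0, 2.2, 3.8],
                "na_mmoll": [135.0, np.nan, 138.0],
                "dialysis": [False, False, False],
            }
        )

    def test_missing_sodium_logged_not_fatal(self):
        scored, excl = mk.score_cohort(self.make_cohort(), MODELS["meldna"])
        assert len(scored) == 2 and len(excl) == 1
        assert excl.iloc[0]["id"] == "b" and "sodium" in excl.iloc[0]["reason"]

    def test_deterministic(self):
        c = self.make_cohort()
        s1, _ = mk.score_cohort(c, MODELS["5vmeld"])
        s2, _ = mk.score_cohort(c, MODELS["5vmeld"])
        pd.testing.assert_frame_equal(s1, s2)

    def test_empty_cohort(self):
        scored, excl = mk.score_cohort(self.make_cohort().iloc[:0], MODELS["meld"])
        assert len(scored) == 0 and len(excl) == 0

    def test_vectorized_matches_scalar_path(self):
        c = self.make_cohort()
        for name in ("meld", "meldna", "5vmeld"):
            sf = score_frame(c, MODELS[name])
            for i, row in c.iterrows():
                if name != "meld" and np.isnan(row["na_mmoll"]):
                    assert np.isnan(sf.loc[i, "score"])
                    continue
                panel = mk.LabPanel(
                    bilirubin=row["bili_mgdl"], creatinine=row["creat_mgdl"],
                    inr=row["inr"], albumin=row["alb_gdl"],
                    sodium=None if np.isnan(row["na_mmoll"]) else row["na_mmoll"],
                )
                assert sf.loc[i, "score"] == _score_one(panel, MODELS[name]).score


def test_coefficient_file_roundtrip(tmp_path):
    path = tmp_path / "models.yaml"
    save_models(MODELS, path)
    loaded = load_models(path)
    assert set(loaded) == set(MODELS)
    fv0, fv1 = MODELS["5vmeld"], loaded["5vmeld"]
    assert fv1.albumin_coeff == fv0.albumin_coeff
    assert fv1.interaction_coeff == fv0.interaction_coeff
    assert fv1.rounding == fv0.rounding
    base = mk.meldna(30, 125.0)
    assert (
        mk.apply_albumin_extension(base, 2.0, fv1).score
        == mk.apply_albumin_extension(base, 2.0, fv0).score
    )
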