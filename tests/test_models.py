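"""Published mapping algorithms: fixtures, hand arithmetic, serialization."""

import numpy as np
import pytest

from headmap.models import (PUBLISHED_MODELS, MappingModel, UnknownModelError,
                            load_model_file, load_published_model,
                            predict_utilities, save_model_file)
from headmap.respondent import Respondent


def test_unknown_name_raises():
    with pytest.raises(UnknownModelError):
        load_published_model("hit6_eq5d_ols9")


def test_hit6_eq5d_clad1_coefficients():
    m = load_published_model("hit6_eq5d_clad1")
    assert m.terms == [("hit6", -0.0198)]
    assert m.constant == 1.9054
    assert m.estimator == "clad" and m.covariate_set == 1


def test_hit6_sf6d_clad2_coefficients():
    m = load_published_model("hit6_sf6d_clad2")
    assert dict(m.terms) == {"hit6": -0.0118, "age": -0.0002, "female": -0.0142}
    assert m.constant == 1.3669


def test_chqlq_sf6d_ols2_coefficients():
    m = load_published_model("chqlq_sf6d_ols2")
    assert dict(m.terms) == {"chqrr": 0.0018, "chqrp": 0.0017, "chqef": 0.0009,
                             "age": -0.0002, "female": -0.0032}
    assert m.constant == 0.3459


def test_chqlq_eq5d_clad3_term_order_and_count():
    m = load_published_model("chqlq_eq5d_clad3")
    assert [t for t, _ in m.terms] == [
        "chqrr", "chqrp", "chqef",
        "chqrr_sq", "chqrp_sq", "chqef_sq",
        "chqrr_x_chqrp", "chqrr_x_chqef", "chqrp_x_chqef",
        "chqrr_x_age", "chqrp_x_age", "chqef_x_age",
        "age", "age_sq", "female",
    ]
    assert m.constant == -0.3964


class TestHandArithmetic:
    def test_hit6_eq5d_clad1_at_66(self):
        m = load_published_model("hit6_eq5d_clad1")
        u, kept, _ = predict_utilities(m, [Respondent(id="a", hit6=66)])
        assert u[0] == pytest.approx(1.9054 - 0.0198 * 66, abs=1e-10)
        assert u[0] == pytest.approx(0.5986, abs=1e-10)

    def test_hit6_sf6d_clad2_example(self):
        m = load_published_model("hit6_sf6d_clad2")
        r = Respondent(id="b", hit6=60, age=50, sex="female")
        u, _, _ = predict_utilities(m, [r])
        assert u[0] == pytest.approx(
            1.3669 - 0.0118 * 60 - 0.0002 * 50 - 0.0142, abs=1e-10)
        assert u[0] == pytest.approx(0.6347, abs=1e-10)

    def test_chqlq_sf6d_ols2_example(self):
        m = load_published_model("chqlq_sf6d_ols2")
        r = Respondent(id="c", chq_rr=50, chq_rp=60, chq_ef=50, age=40,
                       sex="female")
        u, _, _ = predict_utilities(m, [r])
        assert u[0] == pytest.approx(0.5717, abs=1e-10)

    @pytest.mark.parametrize("name", PUBLISHED_MODELS)
    def test_ten_rows_match_independent_arithmetic(self, name):
        """Predictions equal a from-scratch evaluation of the linear rule."""
        from headmap.design import term_value
        m = load_published_model(name)
        rng = np.random.default_rng(99)
        cohort = [
            Respondent(
                id=f"r{i}",
                hit6=int(rng.integers(36, 79)),
                chq_rr=float(rng.uniform(0, 100)),
                chq_rp=float(rng.uniform(0, 100)),
                chq_ef=float(rng.uniform(0, 100)),
                age=int(rng.integers(18, 89)),
                sex="female" if rng.random() < 0.8 else "male",
            )
            for i in range(12)
        ]
        u, kept, dropped = predict_utilities(m, cohort)
        assert len(kept) >= 10 and not dropped
        for ui, ident in zip(u, kept):
            r = next(x for x in cohort if x.id == ident)
            oracle = m.constant + sum(c * term_value(t, r) for t, c in m.terms)
            assert ui == pytest.approx(oracle, abs=1e-10)


def test_zero_coefficients_give_constant():
    m = MappingModel(name="const", estimator="ols",
                     terms=[("hit6", 0.0)], constant=0.42)
    u, _, _ = predict_utilities(m, [Respondent(id="a", hit6=50),
                                    Respondent(id="b", hit6=78)])
    np.testing.assert_allclose(u, 0.42)


def test_missing_ingredient_drops_row_not_imputes():
    m = load_published_model("hit6_sf6d_clad2")
    cohort = [Respondent(id="ok", hit6=60, age=50, sex="female"),
              Respondent(id="noage", hit6=60, sex="female"),
              Respondent(id="unksex", hit6=60, age=50, sex="other_unknown")]
    u, kept, dropped = predict_utilities(m, cohort)
    assert kept == ["ok"]
    assert set(dropped) == {"noage", "unksex"}


def test_prediction_order_invariant():
    m = load_published_model("hit6_eq5d_clad1")
    cohort = [Respondent(id=f"r{i}", hit6=h) for i, h in enumerate((40, 60, 78))]
    u_fwd, k_fwd, _ = predict_utilities(m, cohort)
    u_rev, k_rev, _ = predict_utilities(m, cohort[::-1])
    assert dict(zip(k_fwd, u_fwd)) == dict(zip(k_rev, u_rev))


def test_clad_models_exceed_one_unclipped_but_clip_respects_range():
    m = load_published_model("hit6_eq5d_clad1")
    mild = [Respondent(id="mild", hit6=36)]  # 1.9054 - 0.7128 > 1
    u, _, _ = predict_utilities(m, mild)
    assert u[0] > 1.0
    u_clip, _, _ = predict_utilities(m, mild, clip=True)
    assert u_clip[0] == 1.0


def test_model_file_round_trip(tmp_path):
    m = load_published_model("chqlq_eq5d_clad3")
    p = tmp_path / "m.yaml"
    save_model_file(m, p)
    back = load_model_file(p)
    assert back.terms == m.terms
    assert back.constant == m.constant
    assert back.estimator == m.estimator
    assert back.censor_upper == m.censor_upper
    r = Respondent(id="x", chq_rr=50.0, chq_rp=60.0, chq_ef=50.0, age=40,
                   sex="female")
    u1, _, _ = predict_utilities(m, [r])
    u2, _, _ = predict_utilities(back, [r])
    assert u1[0] == u2[0]


def test_flogit_model_response_transform():
    m = MappingModel(name="fl", estimator="flogit", terms=[("hit6", 0.0)],
                     constant=0.0, bounds=(-0.594, 1.0))
    u, _, _ = predict_utilities(m, [Respondent(id="a", hit6=60)])
    # eta = 0 -> inverse logit 0.5 -> midpoint of the bounds
    assert u[0] == pytest.approx((-0.594 + 1.0) / 2)
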