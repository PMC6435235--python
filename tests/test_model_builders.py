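"""Process matrices: printed-form transcription and conservation accounting.

The monogamy (5-stage) and h=3 harem (7-stage) transition/birth/union
matrices are written out entry-by-entry in these tests, independently of
the builder code, and compared cell-for-cell.  Conservation identities are
checked with multiplicity-weighted column sums: union formation and
divorce move individuals between stages without creating or destroying
them, so the only loss of individuals is the death flux.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmmr import (
    MatingSpec,
    ModelParams,
    apply_harvest,
    build_birth_matrix,
    build_transition_matrix,
    build_union_matrix,
    make_stage_space,
    per_capita_rates,
    polygynous_rates,
    projection_matrix,
)

HARMONIC = MatingSpec()


def params_with(**kw) -> ModelParams:
    base = dict(mu_m1=0.5, mu_f1=0.5, mu_m2=0.1, mu_f2=0.1,
                alpha_m=0.5, alpha_f=0.5, s1=0.5, k=20.0, d=0.1)
    base.update(kw)
    return ModelParams(**base)


class TestUnionMatrix:
    def test_monogamy_equal_singles(self):
        """With m2 = f2, per-capita rates are 1; the printed 5x5 pattern."""
        sp = make_stage_space(1)
        n = np.array([0.3, 0.2, 0.3, 0.2, 0.1])
        U = build_union_matrix(sp, params_with(h=1), HARMONIC, n)
        expected = np.array([
            [0, 0, 0, 0, 0],
            [0, -1.0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, -1.0, 0],
            [0, 0.5, 0, 0.5, 0],
        ])
        np.testing.assert_allclose(U, expected, atol=1e-15)

    def test_harem_pattern_h3(self):
        """Zero pattern and coefficients -U_m, -3U_f, U_m/2, U_f/2 for h=3."""
        sp = make_stage_space(3)
        n = np.array([0.1, 0.25, 0.1, 0.35, 0.1, 0.05, 0.05])
        _, um, uf = polygynous_rates(HARMONIC, 0.25, 0.35, 3)
        U = build_union_matrix(sp, params_with(h=3), HARMONIC, n)
        expected = np.zeros((7, 7))
        expected[1, 1] = -um
        expected[3, 3] = -3 * uf
        expected[6, 1] = 0.5 * um
        expected[6, 3] = 0.5 * uf
        np.testing.assert_allclose(U, expected, atol=1e-15)

    def test_no_available_maters_gives_zero_matrix(self):
        sp = make_stage_space(2)
        n = np.array([1.0, 0.0, 1.0, 0.0, 0.5, 0.5])
        U = build_union_matrix(sp, params_with(h=2), HARMONIC, n)
        np.testing.assert_array_equal(U, np.zeros((6, 6)))

    def test_degree_zero_homogeneity(self):
        sp = make_stage_space(2)
        n = np.array([0.4, 0.15, 0.2, 0.15, 0.05, 0.05])
        p = params_with(h=2)
        U1 = build_union_matrix(sp, p, HARMONIC, n)
        U2 = build_union_matrix(sp, p, HARMONIC, 37.5 * n)
        np.testing.assert_allclose(U1, U2, rtol=1e-12)

    def test_mismatched_composition_rejected(self):
        sp = make_stage_space(2)
        with pytest.raises(ValueError):
            build_union_matrix(sp, params_with(h=2), HARMONIC, np.ones(5))
        with pytest.raises(ValueError):
            build_union_matrix(sp, params_with(h=2), HARMONIC, -np.ones(6))


class TestBirthMatrix:
    def test_monogamy_printed_form(self):
        sp = make_stage_space(1)
        B = build_birth_matrix(sp, params_with(h=1, k=20.0, s1=0.5))
        expected = np.zeros((5, 5))
        expected[0, 4] = 10.0
        expected[2, 4] = 10.0
        np.testing.assert_array_equal(B, expected)

    def test_harem_productivity_scales_with_size(self):
        """A harem with i females reproduces at rate i*k."""
        sp = make_stage_space(3)
        B = build_birth_matrix(sp, params_with(h=3, k=20.0, s1=0.25))
        np.testing.assert_allclose(B[0, 4:], [5.0, 10.0, 15.0])
        np.testing.assert_allclose(B[2, 4:], [15.0, 30.0, 45.0])
        assert np.count_nonzero(B) == 6

    def test_all_male_offspring(self):
        sp = make_stage_space(2)
        B = build_birth_matrix(sp, params_with(h=2, s1=1.0))
        assert (B[2] == 0).all()


class TestTransitionMatrix:
    def test_monogamy_printed_form(self):
        """T for the 5-stage model, transcribed entry-by-entry."""
        p = params_with(h=1, mu_m1=0.4, mu_f1=0.3, mu_m2=0.12, mu_f2=0.08,
                        alpha_m=0.6, alpha_f=0.7, d=0.25)
        sp = make_stage_space(1)
        T = build_transition_matrix(sp, p)
        expected = np.array([
            [-(0.4 + 0.6), 0, 0, 0, 0],
            [0.6, -0.12, 0, 0, 0.08 + 0.25],
            [0, 0, -(0.3 + 0.7), 0, 0],
            [0, 0, 0.7, -0.08, 0.12 + 0.25],
            [0, 0, 0, 0, -(0.12 + 0.08 + 0.25)],
        ])
        np.testing.assert_allclose(T, expected, atol=1e-15)

    def test_harem_printed_form_h3(self):
        """T for h=3: leader death frees i females; unions shrink stepwise."""
        mm2, mf2, d = 0.12, 0.08, 0.25
        p = params_with(h=3, mu_m1=0.4, mu_f1=0.3, mu_m2=mm2, mu_f2=mf2,
                        alpha_m=0.6, alpha_f=0.7, d=d)
        sp = make_stage_space(3)
        T = build_transition_matrix(sp, p)
        diag_u = -(mm2 + mf2 + d)
        expected = np.array([
            [-1.0, 0, 0, 0, 0, 0, 0],
            [0.6, -mm2, 0, 0, mf2 + d, 0, 0],
            [0, 0, -1.0, 0, 0, 0, 0],
            [0, 0, 0.7, -mf2, mm2 + d, 2 * mm2 + d, 3 * mm2 + d],
            [0, 0, 0, 0, diag_u, mf2 + d, 0],
            [0, 0, 0, 0, 0, diag_u, mf2 + d],
            [0, 0, 0, 0, 0, 0, diag_u],
        ])
        np.testing.assert_allclose(T, expected, atol=1e-15)

    def test_all_rates_zero_gives_zero_matrix(self):
        p = ModelParams(mu_m1=0, mu_f1=0, mu_m2=0, mu_f2=0,
                        alpha_m=0, alpha_f=0, d=0, k=0, h=4)
        T = build_transition_matrix(make_stage_space(4), p)
        np.testing.assert_array_equal(T, np.zeros((8, 8)))

    def test_monogamy_is_h1_special_case(self):
        """One code path: the 5-stage matrices are the h=1 harem matrices."""
        p = params_with(h=1)
        sp = make_stage_space(1)
        T = build_transition_matrix(sp, p)
        # u_1 column dissolves the union: male to m2, female to f2
        assert T[1, 4] == pytest.approx(p.mu_f2 + p.d)
        assert T[3, 4] == pytest.approx(p.mu_m2 + p.d)

    def test_per_female_mortality_variant(self):
        p = params_with(h=3, per_female_union_mortality=True)
        T = build_transition_matrix(make_stage_space(3), p)
        # u_3 loses females at 3*mu_f2 + d instead of mu_f2 + d
        assert T[5, 6] == pytest.approx(3 * p.mu_f2 + p.d)
        assert T[6, 6] == pytest.approx(-(p.mu_m2 + 3 * p.mu_f2 + p.d))


class TestHarvest:
    def test_no_harvest_is_identity(self):
        p = params_with(h=2, E=0.0, s_h=0.7)
        assert apply_harvest(p) is p

    def test_male_only_harvest(self):
        p = apply_harvest(params_with(h=1, E=1.0, s_h=1.0, mu_m2=0.1, mu_f2=0.1))
        assert p.mu_m2 == pytest.approx(1.1)
        assert p.mu_f2 == pytest.approx(0.1)

    def test_unbiased_harvest_splits_evenly(self):
        p = apply_harvest(params_with(h=1, E=1.0, s_h=0.5, mu_m2=0.1, mu_f2=0.1))
        assert p.mu_m2 == pytest.approx(0.6)
        assert p.mu_f2 == pytest.approx(0.6)

    def test_idempotent_after_application(self):
        p = apply_harvest(params_with(h=1, E=1.0, s_h=1.0))
        assert apply_harvest(p).mu_m2 == p.mu_m2

    @pytest.mark.parametrize("kw", [{"E": -0.5}, {"s_h": 1.5}, {"s_h": -0.1}])
    def test_out_of_range_harvest_rejected(self, kw):
        with pytest.raises(ValueError):
            params_with(h=1, **kw)


rate = st.floats(min_value=0.0, max_value=3.0)
freq = st.floats(min_value=0.0, max_value=1.0)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    h=st.integers(min_value=1, max_value=10),
    mu_m1=rate, mu_f1=rate, mu_m2=rate, mu_f2=rate,
    alpha_m=rate, alpha_f=rate, d=rate,
    k=st.floats(min_value=0.0, max_value=30.0), s1=freq,
    raw_n=st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=14, max_size=14),
)
def test_conservation_identities(h, mu_m1, mu_f1, mu_m2, mu_f2,
                                 alpha_m, alpha_f, d, k, s1, raw_n):
    """Multiplicity-weighted fluxes: mating and divorce conserve
    individuals; T loses exactly the death flux; B adds i*k per harem."""
    sp = make_stage_space(h)
    params = ModelParams(mu_m1=mu_m1, mu_f1=mu_f1, mu_m2=mu_m2, mu_f2=mu_f2,
                         alpha_m=alpha_m, alpha_f=alpha_f, d=d, k=k, s1=s1, h=h)
    n = np.asarray(raw_n[: sp.s])
    w = sp.multiplicity.astype(float)

    mats = projection_matrix(sp, params, HARMONIC, n)
    scale = max(1.0, float(n.sum()))

    # union formation moves individuals, never creates or destroys them
    assert abs(w @ mats.U @ n) <= 1e-12 * scale * 10

    # transitions lose exactly the death flux (maturation/divorce conserve)
    m1, m2, f1, f2 = n[0], n[1], n[2], n[3]
    deaths = (mu_m1 * m1 + mu_f1 * f1 + mu_m2 * m2 + mu_f2 * f2
              + (mu_m2 + mu_f2) * n[4:].sum())
    assert w @ mats.T @ n == pytest.approx(-deaths, abs=1e-12 * scale * 30)

    # total birth flux is k * sum_i i*u_i
    harem_sizes = np.arange(1, h + 1)
    births = k * float(harem_sizes @ n[4:])
    assert w @ mats.B @ n == pytest.approx(births, abs=1e-12 * scale * 30)

    # structural sign pattern of the assembled projection matrix
    off = mats.A - np.diag(np.diag(mats.A))
    assert (off >= 0).all()


def test_closed_system_conserves_individuals():
    """All mortality, birth, and divorce off: d(w'n)/dt = 0."""
    h = 3
    sp = make_stage_space(h)
    params = ModelParams(mu_m1=0, mu_f1=0, mu_m2=0, mu_f2=0,
                         alpha_m=0.5, alpha_f=0.4, d=0, k=0, h=h)
    n = np.array([0.3, 0.2, 0.1, 0.2, 0.1, 0.05, 0.05])
    A = projection_matrix(sp, params, HARMONIC, n).A
    assert abs(sp.multiplicity @ A @ n) < 1e-14


def test_projection_matrix_is_process_average():
    sp = make_stage_space(2)
    params = params_with(h=2)
    n = np.array([0.3, 0.2, 0.1, 0.2, 0.1, 0.1])
    mats = projection_matrix(sp, params, HARMONIC, n)
    np.testing.assert_allclose(mats.A, (mats.T + mats.B + mats.U) / 3.0, atol=1e-16)


def test_projection_matrix_zero_processes():
    sp = make_stage_space(1)
    params = ModelParams(mu_m1=0, mu_f1=0, mu_m2=0, mu_f2=0,
                         alpha_m=0, alpha_f=0, d=0, k=0, h=1)
    n = np.array([1.0, 0.0, 1.0, 0.0, 0.0])  # no single adults: U = 0 too
    mats = projection_matrix(sp, params, HARMONIC, n)
    np.testing.assert_array_equal(mats.A, np.zeros((5, 5)))
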