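"""Sequential-chain forward model: Bateman solutions and the bilinear map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import flavokin as fk
from flavokin.exceptions import InvalidInputError, InvalidMechanismError


def ode_oracle(rates, times, method="LSODA"):
    """High-accuracy numerical ODE integration of the chain (independent
    oracle).  LSODA copes with stiff rate ratios; DOP853 gives tighter
    dense output for mildly separated rates."""
    rates = np.asarray(rates, dtype=float)
    n = rates.size + 1

    def rhs(_, y):
        dy = np.zeros(n)
        dy[:-1] -= rates * y[:-1]
        dy[1:] += rates * y[:-1]
        return dy

    y0 = np.zeros(n)
    y0[0] = 1.0
    tol = dict(rtol=1e-13, atol=1e-16) if method == "DOP853" else dict(
        rtol=1e-12, atol=1e-14
    )
    # integrate segment to segment so every reported time is a solver
    # endpoint (dense-output interpolation error would dominate otherwise)
    out, y, t0 = [], y0, 0.0
    for tn in np.asarray(times, dtype=float):
        if tn > t0:
            sol = solve_ivp(rhs, (t0, tn), y, method=method, **tol)
            y, t0 = sol.y[:, -1], tn
        out.append(y.copy())
    return np.asarray(out)


class TestChainConcentrations:
    def test_single_species_is_constant(self):
        prof = fk.chain_concentrations(fk.SequentialMechanism([]), np.array([0.0, 1.0, 10.0]))
        assert np.allclose(prof.matrix, 1.0)

    def test_single_step_half_life(self):
        k = 3.7
        t = np.array([0.0, np.log(2) / k, 50.0 / k])
        prof = fk.chain_concentrations(fk.SequentialMechanism([k]), t)
        assert prof.matrix[0] == pytest.approx([1.0, 0.0])
        assert prof.matrix[1] == pytest.approx([0.5, 0.5])
        assert prof.matrix[2] == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_two_step_matches_ode_oracle(self):
        # fast/slow separation typical of a biphasic flavin bleach
        t = np.array([0.001, 0.01, 0.1, 1.0])
        prof = fk.chain_concentrations(fk.SequentialMechanism([78.0, 8.9]), t)
        expected = ode_oracle([78.0, 8.9], t)
        rel = np.abs(prof.matrix - expected) / np.maximum(np.abs(expected), 1e-12)
        assert rel.max() < 1e-8

    def test_equal_rates_use_confluent_limit(self):
        # repeated root: B(t) = k t e^{-kt}
        k = 5.0
        t = np.array([0.05, 0.2, 1.0])
        prof = fk.chain_concentrations(
            fk.SequentialMechanism([k, k * (1 + 1e-9)]), t
        )
        assert prof.matrix[:, 0] == pytest.approx(np.exp(-k * t), rel=1e-8)
        assert prof.matrix[:, 1] == pytest.approx(k * t * np.exp(-k * t), rel=1e-7)

    def test_invalid_inputs_raise(self):
        with pytest.raises(InvalidMechanismError):
            fk.SequentialMechanism([1.0, -2.0])
        with pytest.raises(InvalidMechanismError):
            fk.SequentialMechanism([0.0])
        with pytest.raises(InvalidInputError):
            fk.chain_concentrations(fk.SequentialMechanism([1.0]), np.array([1.0, 0.5]))
        with pytest.raises(InvalidInputError):
            fk.chain_concentrations(fk.SequentialMechanism([1.0]), np.array([-1.0, 0.5]))


@st.composite
def random_mechanisms(draw):
    n_steps = draw(st.integers(min_value=1, max_value=3))
    logs = draw(
        st.lists(
            st.floats(min_value=-3.0, max_value=3.0),
            min_size=n_steps, max_size=n_steps,
        )
    )
    rates = [10.0**x for x in logs]
    if draw(st.booleans()) and n_steps >= 2:
        rates[1] = rates[0] * (1 + 1e-8)  # equal to 8 significant digits
    return rates


@settings(max_examples=30, deadline=None, derandomize=True)
@given(rates=random_mechanisms())
def test_conservation_monotonicity_and_oracle(rates):
    """Mass conservation, endpoint monotonicity and ODE-oracle agreement."""
    t = np.geomspace(1e-3 / max(rates), 10.0 / min(rates), 40)
    prof = fk.chain_concentrations(fk.SequentialMechanism(rates), t)
    assert np.abs(prof.matrix.sum(axis=1) - 1.0).max() < 1e-10
    assert prof.matrix.min() > -1e-12 and prof.matrix.max() < 1 + 1e-12
    assert np.all(np.diff(prof.matrix[:, 0]) <= 1e-12)   # A non-increasing
    assert np.all(np.diff(prof.matrix[:, -1]) >= -1e-12)  # Z non-decreasing
    expected = ode_oracle(rates, t)
    # relative to populations above 1e-6; below that the oracle's own
    # dense-output error dominates the comparison
    rel = np.abs(prof.matrix - expected) / np.maximum(np.abs(expected), 1e-6)
    assert rel.max() < 1e-7


class TestPredictAbsorbance:
    def test_identity_profile_returns_scaled_spectrum(self, visible_grid):
        sp = fk.make_flavin_spectra(2, visible_grid)
        single = fk.SpeciesSpectrumSet(visible_grid, sp.matrix[:1])
        prof = fk.chain_concentrations(fk.SequentialMechanism([]), np.array([0.0, 1.0]))
        out = fk.predict_absorbance(prof, single, scale=7.5)
        assert np.allclose(out, 7.5 * sp.matrix[0])

    def test_linearity_in_scale(self, visible_grid):
        sp = fk.make_flavin_spectra(3, visible_grid)
        prof = fk.chain_concentrations(
            fk.SequentialMechanism([78.0, 8.9]), np.geomspace(1e-3, 1.0, 20)
        )
        assert np.allclose(
            fk.predict_absorbance(prof, sp, 2.0),
            2.0 * fk.predict_absorbance(prof, sp, 1.0),
        )

    def test_matches_brute_force_summation(self, visible_grid):
        sp = fk.make_flavin_spectra(3, visible_grid)
        t = np.geomspace(1e-3, 1.0, 15)
        prof = fk.chain_concentrations(fk.SequentialMechanism([78.0, 8.9]), t)
        out = fk.predict_absorbance(prof, sp, scale=7.5)
        brute = np.zeros_like(out)
        for i in range(t.size):
            for j in range(3):
                brute[i] += 7.5 * prof.matrix[i, j] * sp.matrix[j]
        assert np.allclose(out, brute, atol=1e-14)

    def test_bilinear_rank_bounded_by_species(self, visible_grid):
        sp = fk.make_flavin_spectra(3, visible_grid)
        prof = fk.chain_concentrations(
            fk.SequentialMechanism([78.0, 8.9]), np.geomspace(1e-3, 10.0, 60)
        )
        s = np.linalg.svd(fk.predict_absorbance(prof, sp, 7.5), compute_uv=False)
        assert np.all(s[3:] < 1e-9 * s[0])

    def test_shape_mismatch_raises(self, visible_grid):
        sp = fk.make_flavin_spectra(2, visible_grid)
        prof = fk.chain_concentrations(
            fk.SequentialMechanism([78.0, 8.9]), np.array([0.0, 0.1])
        )
        with pytest.raises(InvalidInputError):
            fk.predict_absorbance(prof, sp)
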