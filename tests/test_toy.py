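"""Softcore pair interactions, the coupled Hamiltonian, Metropolis MC and
the closed-form / brute-force oracles."""

import numpy as np
import pytest

from alchemcycle import (
    DataValidationError,
    SoftcoreParams,
    ToySystem,
    UsageError,
    analytic_dg_harmonic,
    enumerate_dg,
    run_mc,
    run_protocol,
    softcore_pair_rf,
    softcore_pair_vdw,
    ti_reference_means,
    total_hamiltonian,
)
from alchemcycle.toy import (
    F_COULOMB,
    R_GAS,
    confined_pair_system,
    crf_constant,
    exact_dg_confined_pair,
    forward_backward,
    harmonic_system,
)
from alchemcycle.ti import TICurve, integrate, integrate_run

C12, C6 = 4.35e-5, 1.45e-2  # methane-like LJ parameters
RT = R_GAS * 298.0


def plain_lj(r, c12=C12, c6=C6):
    return c12 / r**12 - c6 / r**6


class TestSoftcoreVdw:
    def test_end_state_is_plain_lj(self):
        r = 0.4
        e, _ = softcore_pair_vdw(r, 0.0, C12, C6, 0.0, 0.0, alpha_vdw=1.0)
        assert e == pytest.approx(plain_lj(r))

    def test_softening_vanishes_at_large_separation(self):
        r = 3 * 0.38
        e, _ = softcore_pair_vdw(r, 0.5, C12, C6, 2 * C12, 2 * C6, alpha_vdw=1.0)
        hard = 0.5 * plain_lj(r) + 0.5 * plain_lj(r, 2 * C12, 2 * C6)
        assert e == pytest.approx(hard, rel=0.01)

    def test_overlap_regularized_only_with_softness(self):
        soft, _ = softcore_pair_vdw(0.05, 0.5, C12, C6, 0.0, 0.0, alpha_vdw=1.0)
        hard, _ = softcore_pair_vdw(0.05, 0.5, C12, C6, 0.0, 0.0, alpha_vdw=0.0)
        assert np.isfinite(soft) and soft < 1e6
        assert hard > 1e6

    def test_derivative_matches_central_difference(self):
        for lam in (0.2, 0.5, 0.8):
            _, de = softcore_pair_vdw(0.3, lam, C12, C6, 2 * C12, 0.5 * C6, 1.0)
            eps = 1e-7
            ep, _ = softcore_pair_vdw(0.3, lam + eps, C12, C6, 2 * C12, 0.5 * C6, 1.0)
            em, _ = softcore_pair_vdw(0.3, lam - eps, C12, C6, 2 * C12, 0.5 * C6, 1.0)
            assert de == pytest.approx((ep - em) / (2 * eps), rel=1e-5)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(UsageError):
            softcore_pair_vdw(0.0, 0.5, C12, C6, 0.0, 0.0, 1.0)


class TestSoftcoreRf:
    def test_end_state_is_plain_reaction_field(self):
        r, qq, cutoff, eps_rf = 0.5, 0.25, 1.4, 61.0
        e, _ = softcore_pair_rf(r, 0.0, qq, 0.0, alpha_crf=1.0, eps_rf=eps_rf, cutoff=cutoff)
        crf = crf_constant(eps_rf)
        hand = F_COULOMB * qq * (1 / r - crf * r**2 / (2 * cutoff**3) - (1 - crf / 2) / cutoff)
        assert e == pytest.approx(hand)

    def test_zero_charges_zero_everywhere(self):
        for lam in (0.0, 0.3, 1.0):
            e, de = softcore_pair_rf(0.5, lam, 0.0, 0.0, 1.0, 61.0, 1.4)
            assert e == 0.0 and de == 0.0

    def test_softened_midpoint_matches_hand_formula(self):
        # q: +1·? → state A product 0.5·(−1) etc. chosen scalar products
        r, lam, alpha, cutoff, eps_rf = 0.5, 0.5, 1.0, 1.4, 61.0
        qq_a, qq_b = -0.5, 0.0
        crf = crf_constant(eps_rf)

        def v(qq, a):
            s2 = r**2 + a
            return F_COULOMB * qq * (
                s2**-0.5 - crf * s2 / (2 * cutoff**3) - (1 - crf / 2) / cutoff
            )

        expected = (1 - lam) * v(qq_a, alpha * lam**2) + lam * v(qq_b, alpha * (1 - lam) ** 2)
        e, _ = softcore_pair_rf(r, lam, qq_a, qq_b, alpha, eps_rf, cutoff)
        assert e == pytest.approx(expected)

    def test_energy_vanishes_at_cutoff_end_state(self):
        e, _ = softcore_pair_rf(1.4, 0.0, 0.3, 0.3, 1.0, 61.0, 1.4)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_beyond_cutoff_zero(self):
        e, de = softcore_pair_rf(1.5, 0.5, 0.3, 0.1, 1.0, 61.0, 1.4)
        assert e == 0.0 and de == 0.0

    def test_derivative_matches_central_difference(self):
        _, de = softcore_pair_rf(0.4, 0.6, 0.3, -0.2, 0.7, 61.0, 1.4)
        eps = 1e-7
        ep, _ = softcore_pair_rf(0.4, 0.6 + eps, 0.3, -0.2, 0.7, 61.0, 1.4)
        em, _ = softcore_pair_rf(0.4, 0.6 - eps, 0.3, -0.2, 0.7, 61.0, 1.4)
        assert de == pytest.approx((ep - em) / (2 * eps), rel=1e-5)


def _two_particle_system(**overrides):
    kwargs = dict(
        positions=np.array([[1.0, 1.0, 1.0], [1.4, 1.0, 1.0]]),
        box=np.full(3, 3.0),
        c12_a=np.full(2, C12),
        c6_a=np.full(2, C6),
        q_a=np.array([0.3, -0.3]),
        c12_b=np.array([0.0, C12]),
        c6_b=np.array([0.0, C6]),
        q_b=np.zeros(2),
        cutoff=1.4,
    )
    kwargs.update(overrides)
    return ToySystem(**kwargs)


class TestTotalHamiltonian:
    def test_single_particle_zero(self):
        sys_ = ToySystem(
            positions=np.array([[1.0, 1.0, 1.0]]),
            box=np.full(3, 3.0),
            c12_a=np.array([C12]), c6_a=np.array([C6]), q_a=np.array([0.5]),
            c12_b=np.array([0.0]), c6_b=np.array([0.0]), q_b=np.array([0.0]),
        )
        for lam in (0.0, 0.5, 1.0):
            e, de = total_hamiltonian(sys_, lam)
            assert e == 0.0 and de == 0.0

    def test_two_particle_end_state_exact(self):
        sys_ = _two_particle_system()
        e, _ = total_hamiltonian(sys_, 0.0)
        r = 0.4
        crf = crf_constant(sys_.eps_rf)
        expected = plain_lj(r) + F_COULOMB * (0.3 * -0.3) * (
            1 / r - crf * r**2 / (2 * 1.4**3) - (1 - crf / 2) / 1.4
        )
        assert e == pytest.approx(expected)

    def test_end_states_independent_of_softness(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pos = rng.uniform(0.5, 2.5, (4, 3))
            base = dict(
                positions=pos, box=np.full(3, 3.0),
                c12_a=rng.uniform(0, 2 * C12, 4), c6_a=rng.uniform(0, 2 * C6, 4),
                q_a=rng.uniform(-0.5, 0.5, 4),
                c12_b=rng.uniform(0, 2 * C12, 4), c6_b=rng.uniform(0, 2 * C6, 4),
                q_b=rng.uniform(-0.5, 0.5, 4),
            )
            for lam in (0.0, 1.0):
                energies = {
                    alpha: total_hamiltonian(ToySystem(softcore=SoftcoreParams(alpha, alpha), **base), lam)[0]
                    for alpha in (0.0, 0.5, 1.0)
                }
                vals = list(energies.values())
                assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_derivative_matches_central_difference(self):
        sys_ = _two_particle_system()
        eps = 1e-6
        _, de = total_hamiltonian(sys_, 0.3)
        ep, _ = total_hamiltonian(sys_, 0.3 + eps)
        em, _ = total_hamiltonian(sys_, 0.3 - eps)
        assert de == pytest.approx((ep - em) / (2 * eps), abs=1e-4)

    def test_overlap_with_zero_softness_raises(self):
        sys_ = _two_particle_system(
            positions=np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]),
            softcore=SoftcoreParams(0.0, 0.0),
            q_a=np.zeros(2),
        )
        with pytest.raises((DataValidationError, UsageError)):
            total_hamiltonian(sys_, 0.5)

    def test_oversized_cutoff_truncated_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="alchemcycle"):
            sys_ = _two_particle_system(box=np.full(3, 2.0))
        assert sys_.cutoff == pytest.approx(1.0)
        assert any("truncated" in r.message for r in caplog.records)


class TestRunMc:
    def test_zero_interaction_system_all_zero(self):
        sys_ = ToySystem(
            positions=np.zeros((2, 3)) + 1.0,
            box=np.full(3, 3.0),
            c12_a=np.zeros(2), c6_a=np.zeros(2), q_a=np.zeros(2),
            c12_b=np.zeros(2), c6_b=np.zeros(2), q_b=np.zeros(2),
        )
        res = run_mc(sys_, 0.5, 200, seed=1)
        assert np.all(res.series.samples == 0.0)

    def test_same_seed_bit_identical(self):
        sys_ = _two_particle_system()
        a = run_mc(sys_, 0.4, 500, seed=42)
        b = run_mc(sys_, 0.4, 500, seed=42)
        assert np.array_equal(a.series.samples, b.series.samples)
        assert np.array_equal(a.final_positions, b.final_positions)

    def test_harmonic_mean_dhdl_matches_gaussian_expectation(self):
        # ⟨∂H/∂λ⟩ = ½(k_B−k_A)·⟨r²⟩ with ⟨r²⟩ = 3RT/k(λ) at the coupled k
        k_a, k_b, lam = 500.0, 2000.0, 0.5
        sys_ = harmonic_system(k_a, k_b)
        res = run_mc(sys_, lam, 40_000, max_displacement=0.15, seed=9, record_interval=5)
        k_eff = (1 - lam) * k_a + lam * k_b
        expect = 0.5 * (k_b - k_a) * 3 * RT / k_eff
        x = res.series.samples
        sem = x.std(ddof=1) / np.sqrt(x.size) * 6  # generous autocorrelation margin
        assert x.mean() == pytest.approx(expect, abs=3 * sem)

    def test_detailed_balance_boltzmann_statistics(self):
        # Metropolis sampling of a harmonic well must reproduce Boltzmann
        # statistics: ⟨r²⟩ = 3RT/k, and the two "states" r² below/above the
        # χ²(3) median are equally occupied.  dH/dλ = ½(k_B−k_A)r² exposes r².
        from alchemcycle import block_error

        k = 800.0
        sys_ = harmonic_system(k, 3 * k)
        res = run_mc(sys_, 0.0, 40_000, max_displacement=0.2, seed=13, record_interval=5)
        r2 = res.series.samples / (0.5 * 2 * k)
        sem = block_error(res.series, discard=0.0) / (0.5 * 2 * k)
        assert r2.mean() == pytest.approx(3 * RT / k, abs=3 * sem)
        chi2_3_median = 2.3660
        occ = np.mean(r2 < chi2_3_median * RT / k)
        assert occ == pytest.approx(0.5, abs=0.05)


class TestOracles:
    def test_harmonic_closed_form(self):
        assert analytic_dg_harmonic(1.0, 1.0) == 0.0
        assert analytic_dg_harmonic(1.0, np.e**2, temperature=298.0, dims=1) == pytest.approx(
            R_GAS * 298.0
        )
        assert analytic_dg_harmonic(2.0, 5.0) == pytest.approx(-analytic_dg_harmonic(5.0, 2.0))
        with pytest.raises(UsageError):
            analytic_dg_harmonic(-1.0, 1.0)

    def test_enumerate_identical_tables_zero(self):
        e = np.array([0.0, 1.0, 2.0])
        assert enumerate_dg(e, e) == pytest.approx(0.0)

    def test_enumerate_constant_shift(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(0, 5, 50)
        assert enumerate_dg(e, e + 3.25) == pytest.approx(3.25)

    def test_ti_dense_grid_matches_partition_sum(self):
        rng = np.random.default_rng(8)
        e_a = rng.uniform(0, 5, 100)
        e_b = rng.uniform(0, 5, 100)
        exact = enumerate_dg(e_a, e_b)
        lams = np.linspace(0, 1, 201)
        curve = TICurve(lams, ti_reference_means(e_a, e_b, lams), np.zeros_like(lams))
        assert integrate(curve).value == pytest.approx(exact, abs=0.01 * RT)


class TestProtocol:
    def test_null_transformation_zero_within_error(self):
        sys_ = _two_particle_system(
            c12_b=np.full(2, C12), c6_b=np.full(2, C6), q_b=np.array([0.3, -0.3])
        )
        fwd = run_protocol(sys_, np.linspace(0, 1, 5), production_steps=400,
                           equilibration_steps=50, seed=2)
        est = integrate_run(fwd.run, discard=0.0)
        assert abs(est.value) <= max(3 * est.uncertainty, 0.05)

    def test_harmonic_mutation_recovers_closed_form(self):
        k_a, k_b = 500.0, 2000.0
        sys_ = harmonic_system(k_a, k_b)
        fwd, bwd = forward_backward(
            sys_, np.linspace(0, 1, 11), seed=3,
            production_steps=3000, equilibration_steps=300, max_displacement=0.12,
        )
        truth = analytic_dg_harmonic(k_a, k_b)
        f = integrate_run(fwd.run, discard=0.0)
        b = integrate_run(bwd.run, discard=0.0)
        assert f.value == pytest.approx(truth, abs=3 * max(f.uncertainty, 0.05))
        assert -b.value == pytest.approx(truth, abs=3 * max(b.uncertainty, 0.05))

    def test_backward_run_executed_frame(self):
        sys_ = harmonic_system(500.0, 2000.0)
        bwd = run_protocol(sys_, np.linspace(0, 1, 3), direction="backward",
                           production_steps=100, equilibration_steps=10, seed=4)
        assert (bwd.run.state_from, bwd.run.state_to) == ("B", "A")
        assert bwd.run.direction_tag == "backward"

    def test_schedule_must_cover_unit_interval(self):
        with pytest.raises(UsageError):
            run_protocol(harmonic_system(1.0, 2.0), np.linspace(0.2, 1, 5), production_steps=10)


class TestConfinedPairOracle:
    def test_exact_dg_matches_independent_quadrature(self):
        from scipy.integrate import quad

        sys_ = confined_pair_system()
        k = sys_.tether_k_a[0]
        c12, c6 = sys_._c12a_mat[0, 1], sys_._c6a_mat[0, 1]

        def za_int(s):
            return s * s * np.exp(-((k / 4) * s * s + c12 / s**12 - c6 / s**6) / RT)

        def zb_int(s):
            return s * s * np.exp(-((k / 4) * s * s) / RT)

        za = quad(za_int, 1e-6, 1.4, limit=300)[0]
        zb = quad(zb_int, 1e-6, 1.4, limit=300)[0]
        independent = -RT * np.log(zb / za)
        assert exact_dg_confined_pair(sys_) == pytest.approx(independent, abs=1e-4)

    def test_exact_dg_independent_of_softness_parameters(self):
        # end states carry no softcore, so the oracle value cannot depend on α
        a = exact_dg_confined_pair(confined_pair_system(alpha_vdw=0.5, alpha_crf=0.5))
        b = exact_dg_confined_pair(confined_pair_system(alpha_vdw=1.0, alpha_crf=1.0))
        assert a == pytest.approx(b)
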