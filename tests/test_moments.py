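"""Moment-system checks against population-genetic closed forms.

The independent oracles here are textbook structured-coalescent results:
a panmictic deme equilibrates at pi = 4*N*mu, and a symmetric two-deme
system has within/between coalescence times E[T_w] = 4N and
E[T_b] = 4N + 1/(2m) generations, hence pi = 2*mu*E[T].
"""

import numpy as np
import pytest

from gdforecast import (
    DiversityMatrix,
    Params,
    SingularSystemError,
    apply_habitat_loss,
    build_lattice,
    equilibrium_diversity,
    evolve_diversity,
    local_pi,
    pairwise_fst,
    species_pi,
    tune_migration,
)


@pytest.mark.parametrize("N, mu", [(250_000, 1e-8), (1000, 1e-6), (50, 1e-5)])
def test_single_deme_equilibrium_is_4Nmu(N, mu):
    land = build_lattice(1, 1)
    eq = equilibrium_diversity(land, Params(mu=mu, deme_size=N, mig=0.0))
    assert eq.pi[0, 0] == pytest.approx(4 * N * mu, rel=1e-10)


@pytest.mark.parametrize(
    "N, mu, m",
    [(1000, 1e-6, 0.01), (500, 1e-7, 0.1), (2000, 1e-8, 0.001), (100, 1e-5, 0.25)],
)
def test_two_deme_equilibrium_closed_form(N, mu, m):
    land = build_lattice(1, 2)
    eq = equilibrium_diversity(land, Params(mu=mu, deme_size=N, mig=m))
    pi_w = 8 * N * mu  # 2*mu*E[T_same], E[T_same] = 4N
    pi_b = 8 * N * mu + mu / m  # E[T_diff] = 4N + 1/(2m)
    assert eq.pi[0, 0] == pytest.approx(pi_w, rel=1e-8)
    assert eq.pi[1, 1] == pytest.approx(pi_w, rel=1e-8)
    assert eq.pi[0, 1] == pytest.approx(pi_b, rel=1e-8)


def test_symmetric_landscape_wahlund_ordering(eq4):
    pi = eq4.pi
    assert np.allclose(pi, pi.T)
    assert (pi >= 0).all()
    diag = np.diag(pi)
    off = pi[~np.eye(len(pi), dtype=bool)]
    assert diag.max() <= off.min() + 1e-18  # within <= between at equilibrium


def test_equilibrium_disconnected_raises():
    land = build_lattice(1, 5).remove([2])
    with pytest.raises(SingularSystemError, match="components"):
        equilibrium_diversity(land, Params(mu=1e-7, deme_size=50, mig=0.05))


# ------------------------------------------------------------------ evolve


def test_evolve_zero_time_is_identity(grid4, params_small, eq4):
    out = evolve_diversity(eq4, grid4, params_small, 0.0)
    assert np.array_equal(out.pi, eq4.pi)


def test_equilibrium_is_fixed_point(grid4, params_small, eq4):
    out = evolve_diversity(eq4, grid4, params_small, 500.0)
    assert np.allclose(out.pi, eq4.pi, rtol=1e-7)


@pytest.mark.parametrize("t", [10.0, 200.0, 5000.0])
def test_single_deme_transient_matches_scalar_ode(t):
    # dpi/dt = 2*mu - pi/(2N)  =>  pi(t) = 4*N*mu * (1 - exp(-t/(2N)))
    N, mu = 200.0, 1e-6
    land = build_lattice(1, 1)
    p = Params(mu=mu, deme_size=N, mig=0.0)
    zero = DiversityMatrix(land.deme_ids, np.zeros((1, 1)))
    out = evolve_diversity(zero, land, p, t)
    expected = 4 * N * mu * (1.0 - np.exp(-t / (2 * N)))
    assert out.pi[0, 0] == pytest.approx(expected, rel=1e-7)
    assert out.pi[0, 0] < 4 * N * mu  # approaches equilibrium from below


def test_evolve_converges_to_equilibrium(grid4, params_small, eq4):
    D = grid4.n_demes
    zero = DiversityMatrix(grid4.deme_ids, np.zeros((D, D)))
    t = 100 * 2 * params_small.deme_size * D
    out = evolve_diversity(zero, grid4, params_small, t)
    assert np.allclose(out.pi, eq4.pi, rtol=1e-6)


def test_evolve_negative_time_rejected(grid4, params_small, eq4):
    with pytest.raises(ValueError):
        evolve_diversity(eq4, grid4, params_small, -1.0)


def test_evolve_mismatched_demes_rejected(grid4, params_small, eq4):
    reduced = grid4.remove([0])
    with pytest.raises(ValueError, match="demes"):
        evolve_diversity(eq4, reduced, params_small, 1.0)


# --------------------------------------------------------------- summaries


def test_species_pi_constant_matrix():
    state = DiversityMatrix([0, 1, 2], np.full((3, 3), 0.42))
    assert species_pi(state) == pytest.approx(0.42)
    assert local_pi(state) == pytest.approx(0.42)
    assert species_pi(state) == pytest.approx(local_pi(state))


def test_species_pi_two_deme_average():
    state = DiversityMatrix([0, 1], np.array([[0.008, 0.0081], [0.0081, 0.008]]))
    # (2*0.008 + 2*0.0081) / 4
    assert species_pi(state) == pytest.approx(0.00805)
    assert local_pi(state) == pytest.approx(0.008)
    assert pairwise_fst(state) == pytest.approx(1 - 0.008 / 0.0081)


def test_species_pi_single_deme_and_weights():
    state = DiversityMatrix([7], np.array([[0.01]]))
    assert species_pi(state) == pytest.approx(0.01)
    two = DiversityMatrix([0, 1], np.array([[0.1, 0.3], [0.3, 0.5]]))
    assert species_pi(two, weights=[1.0, 0.0]) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        species_pi(two, weights=[0.5, 0.4])  # does not sum to 1
    with pytest.raises(ValueError):
        species_pi(two, weights=[1.0])  # length mismatch


def test_fst_edge_cases():
    flat = DiversityMatrix([0, 1], np.full((2, 2), 0.3))
    assert pairwise_fst(flat) == pytest.approx(0.0)
    fixed = DiversityMatrix([0, 1], np.array([[0.0, 0.2], [0.2, 0.0]]))
    assert pairwise_fst(fixed) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pairwise_fst(DiversityMatrix([0], np.array([[0.1]])))


# ------------------------------------------------------------ habitat loss


def test_habitat_loss_empty_removal_is_identity(grid4, params_small, eq4):
    state, land = apply_habitat_loss(eq4, grid4, [])
    assert land is grid4
    assert np.array_equal(state.pi, eq4.pi)


def test_habitat_loss_restricts_submatrix():
    land = build_lattice(10, 10)
    p = Params(mu=1e-8, deme_size=100, mig=0.1)
    eq = equilibrium_diversity(land, p)
    removed = [r * 10 + c for r in range(10) for c in range(3)]
    state, reduced = apply_habitat_loss(eq, land, removed)
    assert reduced.n_demes == 70
    assert state.pi.shape == (70, 70)
    keep = [i for i, d in enumerate(land.deme_ids) if int(d) not in set(removed)]
    assert np.array_equal(state.pi, eq.pi[np.ix_(keep, keep)])


def test_habitat_loss_two_deme_species_pi_drop():
    land = build_lattice(1, 2)
    p = Params(mu=1e-6, deme_size=1000, mig=0.01)
    eq = equilibrium_diversity(land, p)
    before = species_pi(eq)  # (2*pi_w + 2*pi_b)/4 = 0.00805
    state, _ = apply_habitat_loss(eq, land, [1])
    after = species_pi(state)  # pi_w = 0.008
    assert before == pytest.approx(0.00805, rel=1e-6)
    assert after == pytest.approx(0.008, rel=1e-6)
    assert 1 - after / before == pytest.approx(0.0062, abs=2e-4)


def test_habitat_loss_errors(grid4, eq4):
    with pytest.raises(ValueError):
        apply_habitat_loss(eq4, grid4, grid4.deme_ids.tolist())
    with pytest.raises(ValueError):
        apply_habitat_loss(eq4, grid4, [999])


# ----------------------------------------------------------------- tuning


def test_fst_monotone_decreasing_in_migration(grid4):
    p = Params(mu=1e-7, deme_size=50, mig=0.01)
    fsts = [
        pairwise_fst(equilibrium_diversity(grid4, p.with_mig(m)))
        for m in (1e-4, 1e-3, 1e-2, 0.1, 0.25)
    ]
    assert all(a > b for a, b in zip(fsts, fsts[1:]))


def test_tune_migration_round_trip(grid4):
    p = Params(mu=1e-7, deme_size=500, mig=0.01)
    res = tune_migration(grid4, p, 0.3)
    assert res.converged
    achieved = pairwise_fst(equilibrium_diversity(grid4, p.with_mig(res.mig)))
    assert achieved == pytest.approx(0.3, abs=1e-3)


def test_tune_migration_panmictic_target(grid4):
    p = Params(mu=1e-7, deme_size=5000, mig=0.01)
    res = tune_migration(grid4, p, 0.0)
    assert res.mig == pytest.approx(0.25)  # upper search bound
    assert res.achieved_fst < 0.01


def test_tune_migration_invalid_target(grid4, params_small):
    with pytest.raises(ValueError):
        tune_migration(grid4, params_small, 1.0)
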