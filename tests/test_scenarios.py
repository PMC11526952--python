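import numpy as np
import pytest

from gdforecast import (
    Horizons,
    Params,
    ScenarioSpec,
    build_lattice,
    equilibrium_diversity,
    fragmentation_mask,
    landscape_metrics,
    local_pi,
    restore_habitat,
    run_scenario,
    species_pi,
    edge_contraction_demes,
)
from gdforecast.landscape import Landscape

FAST_HORIZONS = Horizons(medium=200, long=2000)


# ------------------------------------------------------------ removal sets


@pytest.mark.parametrize(
    "loss, expected_n",
    [(0.30, 30), (0.35, 35), (0.0, 0), (0.5, 50)],
)
def test_edge_contraction_counts(loss, expected_n):
    land = build_lattice(10, 10)
    removed = edge_contraction_demes(land, loss)
    assert len(removed) == expected_n
    if expected_n:
        cols = sorted({land.cell_of(d)[1] for d in removed})
        assert cols == list(range(cols[-1] + 1))  # contiguous from the west edge


def test_edge_contraction_partial_column_top_down():
    land = build_lattice(10, 10)
    removed = edge_contraction_demes(land, 0.35)
    fourth_col = [d for d in removed if land.cell_of(d)[1] == 3]
    assert [land.cell_of(d)[0] for d in fourth_col] == [0, 1, 2, 3, 4]


def test_edge_contraction_rejects_full_loss():
    with pytest.raises(ValueError):
        edge_contraction_demes(build_lattice(10, 10), 1.0)


def test_fragmentation_mask_counts_and_determinism():
    land = build_lattice(10, 10)
    frag = fragmentation_mask(land, 0.5, seed=11)
    assert len(frag.removed) == 50
    assert frag.realized_loss == pytest.approx(0.5)
    again = fragmentation_mask(land, 0.5, seed=11)
    assert np.array_equal(frag.mask, again.mask)
    other = fragmentation_mask(land, 0.5, seed=12)
    assert not np.array_equal(frag.mask, other.mask)


def test_fragmentation_zero_loss_keeps_full_mask():
    land = build_lattice(10, 10)
    frag = fragmentation_mask(land, 0.0, seed=0)
    assert frag.mask.all()
    assert frag.removed == []


def test_fragmentation_block_size():
    land = build_lattice(12, 12)
    frag = fragmentation_mask(land, 0.5, cell_block=1.0 / 16.0, seed=0)
    # 144/16 = 9-cell blocks, side 3: removal count is a multiple of 9
    assert len(frag.removed) % 9 == 0
    with pytest.raises(ValueError):
        fragmentation_mask(build_lattice(2, 2), 0.5, block_size=5)


# ----------------------------------------------------------------- metrics


def test_metrics_full_grid():
    m = landscape_metrics(build_lattice(10, 10).mask)
    assert m.patch_count == 1
    assert m.core_area_total == 64  # interior 8x8
    assert m.connectedness == pytest.approx(1.0)
    assert m.perimeter_total == 40


def test_metrics_single_cell():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    m = landscape_metrics(mask)
    assert (m.patch_count, m.core_area_total, m.perimeter_total) == (1, 0, 4)


def test_metrics_checkerboard_patches():
    # brute-force expectation: 4-neighbor adjacency never joins same-color
    # checkerboard cells, so each of the 50 occupied cells is its own patch
    mask = np.indices((10, 10)).sum(axis=0) % 2 == 0
    m = landscape_metrics(mask)
    assert m.patch_count == 50
    assert m.connectedness == 0.0


def test_metrics_ring_removal_monotonicity():
    full = landscape_metrics(build_lattice(6, 6).mask)
    mask = build_lattice(6, 6).mask.copy()
    mask[2:4, 2:4] = False  # punch a hole
    holed = landscape_metrics(mask)
    assert holed.perimeter_total > full.perimeter_total
    assert holed.core_area_total < full.core_area_total


# ---------------------------------------------------------------- scenario


def test_zero_loss_scenario_is_flat(grid4, params_small):
    spec = ScenarioSpec(loss_fraction=0.0, horizons=FAST_HORIZONS)
    traj = run_scenario(spec, grid4, params_small)
    for h in ("short", "medium", "long"):
        assert traj.summaries[h]["species_loss"] == pytest.approx(0.0, abs=1e-9)
        assert traj.summaries[h]["local_loss"] == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("loss", [0.25, 0.5, 0.75])
def test_edge_contraction_losses_ordered_through_time(grid4, params_small, loss):
    """Connected survivors lose diversity monotonically: short <= medium <= long."""
    spec = ScenarioSpec(loss_fraction=loss, horizons=FAST_HORIZONS)
    traj = run_scenario(spec, grid4, params_small)
    s = traj.summaries
    assert traj.n_components == 1
    assert (
        s["short"]["species_loss"]
        <= s["medium"]["species_loss"] + 1e-12
        <= s["long"]["species_loss"] + 1e-12
    )
    # species-pi series is non-increasing toward the reduced equilibrium
    assert (np.diff(traj.species_pi) <= 1e-15).all()


def test_fragmentation_wahlund_divergence():
    """Isolated fragments inflate pooled pi while local pi declines."""
    land = build_lattice(5, 5)
    p = Params(mu=1e-7, deme_size=40, mig=0.02)
    # horizons scaled to the same multiples of 2*N_total as the 2,200- and
    # 13,800-generation study horizons are of their N_e = 2,500 landscape
    horizons = Horizons(medium=880, long=5520)
    seen_multi = 0
    for seed in range(4):
        spec = ScenarioSpec(
            scenario="fragmentation", loss_fraction=0.8, seed=seed, horizons=horizons
        )
        traj = run_scenario(spec, land, p)
        if traj.n_components >= 2:
            seen_multi += 1
            assert traj.summaries["long"]["species_loss"] <= 0  # inflation
            assert traj.summaries["long"]["local_loss"] > 0
    assert seen_multi >= 2  # 80% random loss almost always fragments a 5x5


def test_gradual_and_instant_loss_share_long_term_equilibrium(grid4, params_small):
    inst = run_scenario(
        ScenarioSpec(loss_fraction=0.5, horizons=FAST_HORIZONS), grid4, params_small
    )
    grad = run_scenario(
        ScenarioSpec(scenario="gradual", loss_fraction=0.5, rate=0.05,
                     horizons=FAST_HORIZONS),
        grid4,
        params_small,
    )
    assert grad.summaries["long"]["species_loss"] == pytest.approx(
        inst.summaries["long"]["species_loss"], abs=1e-9
    )
    # gradual loss is gentler than instantaneous at the moment loss completes
    assert grad.summaries["short"]["species_loss"] >= inst.summaries["short"][
        "species_loss"
    ] - 1e-12


def test_trajectory_frame_and_json(grid4, params_small):
    traj = run_scenario(
        ScenarioSpec(loss_fraction=0.5, horizons=FAST_HORIZONS), grid4, params_small
    )
    df = traj.to_frame()
    assert set(df["metric"]) == {"species_pi", "local_pi"}
    assert len(df) == 2 * len(traj.times)
    assert "losses" in traj.summary_json()


# ------------------------------------------------------------- restoration


def test_restore_single_deme_duplication_keeps_species_pi():
    land = build_lattice(1, 2).remove([1])
    p = Params(mu=1e-6, deme_size=500, mig=0.01)
    eq = equilibrium_diversity(land, p)
    for mode in ("natural", "translocation"):
        state, bigger = restore_habitat(eq, land, [1], mode)
        assert bigger.n_demes == 2
        assert species_pi(state) == pytest.approx(species_pi(eq), rel=1e-12)


def test_translocation_seeds_more_local_diversity_than_natural():
    # two-deme closed form: between-pi exceeds within-pi, so landscape-wide
    # founders carry more diversity than founders from the nearest deme
    land2 = build_lattice(1, 3).remove([2])
    p = Params(mu=1e-6, deme_size=500, mig=0.005)
    eq = equilibrium_diversity(land2, p)
    nat, _ = restore_habitat(eq, land2, [2], "natural")
    tra, _ = restore_habitat(eq, land2, [2], "translocation")
    assert local_pi(tra) > local_pi(nat)


def test_restoration_relaxes_to_enlarged_equilibrium():
    land = build_lattice(1, 2).remove([1])
    p = Params(mu=1e-6, deme_size=100, mig=0.05)
    eq = equilibrium_diversity(land, p)
    state, full = restore_habitat(eq, land, [1], "natural")
    from gdforecast import evolve_diversity

    target = equilibrium_diversity(full, p)
    evolved = evolve_diversity(state, full, p, 50 * 2 * 200)
    assert species_pi(evolved) == pytest.approx(species_pi(target), rel=1e-6)
    assert species_pi(state) <= species_pi(target)  # approach from below


def test_restore_rejects_occupied_cell(grid4, eq4):
    with pytest.raises(ValueError):
        restore_habitat(eq4, grid4, [0], "natural")
    with pytest.raises(ValueError):
        restore_habitat(eq4, grid4, [], "bad_mode")
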