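import numpy as np
import pandas as pd
import pytest

from gdforecast import (
    Horizons,
    LossTable,
    Params,
    build_lattice,
    build_loss_table,
    category_to_area_loss,
    combine_gbf_indicators,
    display_percent,
    lpi_decline,
    project_species,
    synth_species_table,
)
from gdforecast.projection import HORIZON_NAMES, SamplingDistributions


# -------------------------------------------------------------- indicators


@pytest.mark.parametrize(
    "category, expected",
    [
        ("CR", (0.80, 0.95, 0.875)),
        ("VU", (0.30, 0.50, 0.40)),
        ("EN", (0.50, 0.80, 0.65)),
        ("LC", (0.0, 0.25, 0.125)),
        ("Least Concern", (0.0, 0.25, 0.125)),
        ("Extinct", (0.95, 1.0, 0.975)),
    ],
)
def test_category_area_loss_mapping(category, expected):
    assert category_to_area_loss(category) == pytest.approx(expected)


def test_unknown_category_rejected():
    with pytest.raises(KeyError):
        category_to_area_loss("MYTHICAL")


def test_lpi_decline_examples():
    one = lpi_decline([[(1970, 100), (2020, 36)]])
    assert one.decline == pytest.approx(0.64)
    assert not one.excluded
    two = lpi_decline([[(0, 10), (1, 6)], [(0, 10), (1, 2)]])
    assert two.decline == pytest.approx(0.6)
    grew = lpi_decline([[(0, 50), (1, 80)]])
    assert grew.decline == pytest.approx(0.0)
    assert grew.excluded
    with pytest.raises(ValueError):
        lpi_decline([])
    with pytest.raises(ValueError):
        lpi_decline([[(0, 10)]])


def test_gbf_combination_and_display():
    combined = combine_gbf_indicators(0.176, 0.267)
    assert combined == pytest.approx(0.396008)
    assert display_percent(combined) == 39  # truncated, not rounded
    assert combine_gbf_indicators(0.0, 0.0) == 0.0
    assert combine_gbf_indicators(1.0, 0.5) == 1.0
    with pytest.raises(ValueError):
        combine_gbf_indicators(1.2, 0.0)


# --------------------------------------------------------------- loss table


@pytest.fixture(scope="module")
def small_table():
    land = build_lattice(4, 4)
    p = Params(mu=1e-7, deme_size=200, mig=0.05)
    return build_loss_table(
        [0.05, 0.4], [0.0, 0.25, 0.5, 0.75], land, p,
        horizons=Horizons(medium=200, long=2000),
    )


def test_table_zero_loss_row_is_zero(small_table):
    for fst in small_table.fst_grid:
        for h in HORIZON_NAMES:
            assert small_table.lookup(fst, 0.0, h) == pytest.approx(0.0, abs=1e-9)


def test_table_monotone_in_loss_and_horizon(small_table):
    for i, fst in enumerate(small_table.fst_grid):
        for k in range(3):
            vals = small_table.values[i, :, k]
            assert (np.diff(vals) >= -1e-9).all()  # non-decreasing in area loss
        # short <= long at every loss level
        assert (small_table.values[i, :, 0] <= small_table.values[i, :, 2] + 1e-9).all()


def test_table_node_lookup_exact(small_table):
    for i, fst in enumerate(small_table.fst_grid):
        for j, loss in enumerate(small_table.loss_grid):
            assert small_table.lookup(fst, loss, "long") == pytest.approx(
                small_table.values[i, j, 2]
            )


def test_table_round_trip(tmp_path, small_table):
    path = tmp_path / "table.csv"
    small_table.to_csv(path)
    back = LossTable.from_csv(path)
    assert np.allclose(back.values, small_table.values)
    assert np.allclose(back.fst_grid, small_table.fst_grid)
    assert back.metric == small_table.metric


# --------------------------------------------------------------- projection


def test_projection_monotone_in_category_severity(small_table):
    records = synth_species_table({"LC": 1, "VU": 1, "EN": 1, "CR": 1}, seed=0)
    records["fst"] = 0.2
    records["z_mar"] = 0.3
    res = project_species(records, small_table, seed=0)
    df = res.per_species.set_index(
        records["category"].to_numpy()
    )
    for col in ["richness_loss_mid"] + [f"pi_loss_{h}_mid" for h in HORIZON_NAMES]:
        vals = df.loc[["LC", "VU", "EN", "CR"], col].to_numpy()
        assert (np.diff(vals) > 0).all(), col


def test_projection_bounds_ordered_and_worked_example(small_table):
    records = synth_species_table({"VU": 1}, seed=0)
    records["z_mar"] = 0.3
    res = project_species(records, small_table, seed=0)
    row = res.per_species.iloc[0]
    # MAR richness bounds for a vulnerable species with z = 0.3:
    # 1-0.7^0.3 = 10.1% and 1-0.5^0.3 = 18.8%
    assert row["richness_loss_min"] == pytest.approx(0.1015, abs=5e-4)
    assert row["richness_loss_max"] == pytest.approx(0.1877, abs=5e-4)
    assert row["richness_loss_min"] <= row["richness_loss_mid"] <= row["richness_loss_max"]
    for h in HORIZON_NAMES:
        assert row[f"pi_loss_{h}_min"] <= row[f"pi_loss_{h}_mid"] <= row[f"pi_loss_{h}_max"] + 1e-12


def test_projection_zero_loss_records_project_zero(small_table):
    records = pd.DataFrame(
        [{"species_id": "a", "source": "lpi", "decline_fraction": 0.0},
         {"species_id": "b", "source": "gbf", "pops_lost": 0.0,
          "frac_below_ne500": 0.0}]
    )
    res = project_species(records, small_table, seed=0)
    loss_cols = [c for c in res.per_species.columns if "loss" in c and "area" not in c]
    assert np.allclose(res.per_species[loss_cols].to_numpy(dtype=float), 0.0, atol=1e-9)


def test_projection_seeded_determinism(small_table):
    records = synth_species_table({"VU": 5, "EN": 5}, n_lpi=5, seed=1)
    a = project_species(records, small_table, seed=42)
    b = project_species(records, small_table, seed=42)
    pd.testing.assert_frame_equal(a.per_species, b.per_species)
    c = project_species(records, small_table, seed=43)
    assert not a.per_species["fst"].equals(c.per_species["fst"])


def test_sampling_distribution_bounds():
    s = SamplingDistributions()
    rng = np.random.default_rng(0)
    fst = s.draw_fst(rng, 500)
    assert fst.min() >= 0.01 and fst.max() <= 0.99
    # truncating the lower tail at 0.01 pulls the mean above 0.270
    assert 0.27 < fst.mean() < 0.40


# ------------------------------------------------------------ synth fixture


def test_synth_table_default_counts_match_printed_composition():
    df = synth_species_table(seed=0)
    counts = df["category"].value_counts()
    assert counts["VU"] == 2240
    assert counts["EN"] == 1621
    assert counts["CR"] == 916
    assert counts["LC"] == 1688
    assert len(df) == 6465


def test_synth_table_empty_and_deterministic():
    assert len(synth_species_table({}, seed=0)) == 0
    a = synth_species_table({"VU": 3}, n_lpi=5, n_gbf=5, seed=9)
    b = synth_species_table({"VU": 3}, n_lpi=5, n_gbf=5, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert ((a.loc[a.source == "lpi", "decline_fraction"] >= 0)
            & (a.loc[a.source == "lpi", "decline_fraction"] <= 1)).all()
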