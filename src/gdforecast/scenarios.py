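"""Habitat-destruction and restoration scenarios on moment states.

A scenario takes a landscape at migration-drift-mutation equilibrium, applies
a habitat-loss event (edge contraction, random fragmentation, or gradual
stepwise loss), and summarizes the diversity trajectory at three horizons:

* short   — immediately after loss (survivors keep their allele frequencies);
* medium  — 2,200 generations after loss;
* long    — the reduced system's equilibrium when the survivors form a single
  connected component, else 13,800 generations (between-fragment diversity
  grows without bound under infinite sites, so no equilibrium exists).

Losses are fractions of the pre-loss species-wide and within-deme (local)
diversity; negative losses are inflation (the Wahlund effect of pooling
diverged, isolated fragments).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .landscape import Landscape
from .moments import (
    DiversityMatrix,
    apply_habitat_loss,
    equilibrium_diversity,
    evolve_diversity,
    local_pi,
    species_pi,
)
from .params import Params

__all__ = [
    "Horizons",
    "ScenarioSpec",
    "Trajectory",
    "FragMetrics",
    "edge_contraction_demes",
    "fragmentation_mask",
    "run_scenario",
    "restore_habitat",
    "landscape_metrics",
]

#: Post-loss sampling horizons, in generations.
DEFAULT_MEDIUM = 2200
DEFAULT_LONG = 13800

SCENARIOS = ("edge_contraction", "fragmentation", "gradual", "restoration")


@dataclass(frozen=True)
class Horizons:
    short: float = 0.0
    medium: float = DEFAULT_MEDIUM
    long: float = DEFAULT_LONG

    def __post_init__(self):
        if not (0 <= self.short <= self.medium <= self.long):
            raise ValueError("horizons must be non-decreasing and non-negative")


@dataclass
class ScenarioSpec:
    """Configuration of a habitat-loss scenario.

    ``cell_block`` is the fragmentation block resolution as a fraction of the
    landscape (1/100 by default; 1/400 and 1/12 also supported); ``rate`` is
    the per-generation loss (fraction of the original habitat) for gradual
    scenarios.
    """

    scenario: str = "edge_contraction"
    loss_fraction: float = 0.5
    cell_block: float = 1.0 / 100.0
    rate: float = 0.01
    seed: int = 0
    horizons: Horizons = field(default_factory=Horizons)
    edge: str = "west"
    restore_mode: str = "natural"

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class Trajectory:
    """Time series of diversity after a habitat-loss event.

    ``times`` are generations since the loss event (time 0 = immediately
    after); ``summaries`` maps horizon name to fractional losses of
    species-wide and local diversity relative to the pre-loss equilibrium
    (negative = inflation).
    """

    times: np.ndarray
    species_pi: np.ndarray
    local_pi: np.ndarray
    pre_species_pi: float
    pre_local_pi: float
    summaries: dict
    n_components: int
    realized_loss: float
    removed: list
    landscape_after: Landscape

    def __post_init__(self):
        if not (len(self.times) == len(self.species_pi) == len(self.local_pi)):
            raise ValueError("trajectory series must have equal lengths")
        if 0.0 not in np.asarray(self.times):
            raise ValueError("trajectory must include time 0")

    def to_frame(self):
        """Tidy (time, metric, value) DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": np.repeat(self.times, 2),
                "metric": ["species_pi", "local_pi"] * len(self.times),
                "value": np.column_stack([self.species_pi, self.local_pi]).ravel(),
            }
        )

    def summary_json(self) -> str:
        return json.dumps(
            {
                "pre_species_pi": self.pre_species_pi,
                "pre_local_pi": self.pre_local_pi,
                "n_components": self.n_components,
                "realized_loss": self.realized_loss,
                "losses": self.summaries,
            },
            indent=2,
        )


# ------------------------------------------------------------- removal sets


def edge_contraction_demes(
    landscape: Landscape, loss_fraction: float, edge: str = "west"
) -> list[int]:
    """Demes removed by contracting the range from one geographic edge.

    Removes whole columns (or rows, for north/south edges) starting at the
    chosen edge until ``floor(loss_fraction * n_occupied)`` cells are gone,
    completing any partial column from that edge top-down.  Deterministic.
    """
    if not (0 <= loss_fraction < 1):
        raise ValueError("loss_fraction must be in [0, 1)")
    total = landscape.n_demes
    n_remove = math.floor(loss_fraction * total)
    if n_remove == 0:
        return []
    mask = landscape.mask
    order: list[int] = []
    if edge in ("west", "east"):
        cols = range(landscape.cols) if edge == "west" else reversed(range(landscape.cols))
        for c in cols:
            for r in range(landscape.rows):
                if mask[r, c]:
                    order.append(landscape.id_of(r, c))
    elif edge in ("north", "south"):
        rows = range(landscape.rows) if edge == "north" else reversed(range(landscape.rows))
        for r in rows:
            for c in range(landscape.cols):
                if mask[r, c]:
                    order.append(landscape.id_of(r, c))
    else:
        raise ValueError(f"unknown edge {edge!r}")
    return order[:n_remove]


@dataclass
class FragmentationResult:
    mask: np.ndarray
    removed: list[int]
    realized_loss: float


def fragmentation_mask(
    landscape: Landscape,
    loss_fraction: float,
    cell_block: float = 1.0 / 100.0,
    seed: int = 0,
    block_size: Optional[int] = None,
) -> FragmentationResult:
    """Random-block habitat removal (fragmentation).

    The grid is partitioned into square blocks of ``block_size`` cells per
    side (derived from ``cell_block``, the block area as a fraction of the
    landscape, when not given explicitly).  Blocks are removed uniformly at
    random without replacement until the target fraction of occupied cells is
    met; because blocks are discrete the realized loss can differ from the
    target and is recorded.  At least one deme always survives.
    """
    if not (0 <= loss_fraction < 1):
        raise ValueError("loss_fraction must be in [0, 1)")
    total_cells = landscape.rows * landscape.cols
    if block_size is None:
        block_cells = cell_block * total_cells
        block_size = max(1, int(round(math.sqrt(block_cells))))
    if block_size > min(landscape.rows, landscape.cols):
        raise ValueError(
            f"block size {block_size} incompatible with "
            f"{landscape.rows}x{landscape.cols} grid"
        )
    rng = np.random.default_rng(seed)
    nbr = math.ceil(landscape.rows / block_size)
    nbc = math.ceil(landscape.cols / block_size)
    blocks = [(br, bc) for br in range(nbr) for bc in range(nbc)]
    rng.shuffle(blocks)

    n_occ = landscape.n_demes
    target = loss_fraction * n_occ
    mask = landscape.mask.copy()
    removed: list[int] = []
    for br, bc in blocks:
        if len(removed) >= target:
            break
        cells = [
            (r, c)
            for r in range(br * block_size, min((br + 1) * block_size, landscape.rows))
            for c in range(bc * block_size, min((bc + 1) * block_size, landscape.cols))
            if mask[r, c]
        ]
        if not cells:
            continue
        if mask.sum() - len(cells) < 1:
            continue  # never remove the last deme
        for r, c in cells:
            mask[r, c] = False
            removed.append(landscape.id_of(r, c))
    realized = len(removed) / n_occ
    return FragmentationResult(mask, removed, realized)


# ---------------------------------------------------------------- scenario


def _sample_times(h: Horizons, n_extra: int = 6) -> np.ndarray:
    """Time grid: 0, a few geometric intermediates, and both horizons."""
    pts = {0.0, float(h.medium), float(h.long)}
    if h.long > 1 and n_extra > 0:
        for t in np.geomspace(max(1.0, h.long / 1000.0), h.long, n_extra):
            pts.add(float(round(t)))
    return np.array(sorted(pts))


def run_scenario(
    spec: ScenarioSpec, landscape: Landscape, params: Params
) -> Trajectory:
    """Equilibrate, apply the loss event, and track diversity at the horizons.

    The pre-loss landscape must be connected (its equilibrium is computed
    internally).  For the gradual scenario, removal steps (in edge-contraction
    order, ``rate`` of the original habitat per generation) are interleaved
    with one-generation evolution; time 0 of the trajectory is the end of the
    loss phase, making summaries comparable with instantaneous scenarios.
    """
    eq = equilibrium_diversity(landscape, params)
    pre_sp = species_pi(eq)
    pre_loc = local_pi(eq)

    if spec.scenario == "restoration":
        return _run_restoration(spec, landscape, params, eq, pre_sp, pre_loc)

    if spec.scenario == "fragmentation":
        frag = fragmentation_mask(
            landscape, spec.loss_fraction, spec.cell_block, spec.seed
        )
        removed = frag.removed
        realized = frag.realized_loss
        state, land = apply_habitat_loss(eq, landscape, removed)
    elif spec.scenario == "edge_contraction":
        removed = edge_contraction_demes(landscape, spec.loss_fraction, spec.edge)
        realized = len(removed) / landscape.n_demes
        state, land = apply_habitat_loss(eq, landscape, removed)
    elif spec.scenario == "gradual":
        removed_all = edge_contraction_demes(landscape, spec.loss_fraction, spec.edge)
        realized = len(removed_all) / landscape.n_demes
        per_gen = spec.rate * landscape.n_demes
        state, land = eq, landscape
        taken = 0
        acc = 0.0
        while taken < len(removed_all):
            acc += per_gen
            k = min(int(acc) - taken, len(removed_all) - taken)
            if k > 0:
                state, land = apply_habitat_loss(
                    state, land, removed_all[taken : taken + k]
                )
                taken += k
            if taken < len(removed_all):
                state = evolve_diversity(state, land, params, 1.0)
        removed = removed_all
    else:  # pragma: no cover
        raise ValueError(spec.scenario)

    ncomp, _ = land.component_labels()
    h = spec.horizons

    times = _sample_times(h)
    sp_series, loc_series = [], []
    cur = state
    prev_t = 0.0
    for t in times:
        if t > prev_t:
            cur = evolve_diversity(cur, land, params, t - prev_t)
            prev_t = t
        sp_series.append(species_pi(cur))
        loc_series.append(local_pi(cur))

    def at_time(t: float) -> tuple[float, float]:
        k = int(np.argmin(np.abs(times - t)))
        if times[k] == t:
            return sp_series[k], loc_series[k]
        s = evolve_diversity(state, land, params, t)
        return species_pi(s), local_pi(s)

    sp_short, loc_short = at_time(h.short)
    sp_med, loc_med = at_time(h.medium)
    if ncomp == 1:
        red_eq = equilibrium_diversity(land, params)
        sp_long, loc_long = species_pi(red_eq), local_pi(red_eq)
    else:
        sp_long, loc_long = at_time(h.long)

    summaries = {
        name: {
            "species_loss": 1.0 - sp / pre_sp,
            "local_loss": 1.0 - lo / pre_loc,
        }
        for name, sp, lo in (
            ("short", sp_short, loc_short),
            ("medium", sp_med, loc_med),
            ("long", sp_long, loc_long),
        )
    }
    return Trajectory(
        times=times,
        species_pi=np.array(sp_series),
        local_pi=np.array(loc_series),
        pre_species_pi=pre_sp,
        pre_local_pi=pre_loc,
        summaries=summaries,
        n_components=ncomp,
        realized_loss=realized,
        removed=list(removed),
        landscape_after=land,
    )


def _run_restoration(spec, landscape, params, eq, pre_sp, pre_loc):
    """Contract, equilibrate the reduced range, then restore and track recovery.

    Losses in the summaries are relative to the intact landscape's
    equilibrium, so they start positive and relax toward 0 as the restored
    landscape re-equilibrates.
    """
    removed = edge_contraction_demes(landscape, spec.loss_fraction, spec.edge)
    _, land_red = apply_habitat_loss(eq, landscape, removed)
    eq_red = equilibrium_diversity(land_red, params)
    state, land = restore_habitat(eq_red, land_red, removed, spec.restore_mode)
    h = spec.horizons
    times = _sample_times(h)
    sp_series, loc_series = [], []
    cur = state
    prev_t = 0.0
    for t in times:
        if t > prev_t:
            cur = evolve_diversity(cur, land, params, t - prev_t)
            prev_t = t
        sp_series.append(species_pi(cur))
        loc_series.append(local_pi(cur))
    idx = {float(t): k for k, t in enumerate(times)}
    summaries = {}
    for name, t in (("short", h.short), ("medium", h.medium), ("long", h.long)):
        k = idx[float(t)]
        summaries[name] = {
            "species_loss": 1.0 - sp_series[k] / pre_sp,
            "local_loss": 1.0 - loc_series[k] / pre_loc,
        }
    ncomp, _ = land.component_labels()
    return Trajectory(
        times=times,
        species_pi=np.array(sp_series),
        local_pi=np.array(loc_series),
        pre_species_pi=pre_sp,
        pre_local_pi=pre_loc,
        summaries=summaries,
        n_components=ncomp,
        realized_loss=len(removed) / landscape.n_demes,
        removed=list(removed),
        landscape_after=land,
    )


# ------------------------------------------------------------- restoration


def restore_habitat(
    state: DiversityMatrix,
    landscape: Landscape,
    new_cells: Sequence[int],
    mode: str = "natural",
) -> tuple[DiversityMatrix, Landscape]:
    """Re-occupy cells and initialize their diversity rows.

    natural
        Each new deme is founded from its nearest occupied deme: its pi row
        (and diagonal) copies that source deme's.  Between two new demes, the
        value is the pi between their source demes.
    translocation
        Founders are drawn landscape-wide: the new deme's within-pi is the
        current species-wide pi, and its pi against any other deme is the
        (uniform) mean of that deme's pi against all occupied demes.
    """
    if mode not in ("natural", "translocation"):
        raise ValueError(f"mode must be 'natural' or 'translocation', got {mode!r}")
    new_cells = [int(c) for c in new_cells]
    occ = set(int(d) for d in landscape.deme_ids)
    for c in new_cells:
        if c in occ:
            raise ValueError(f"cell {c} is already occupied")
    land_new = landscape.add(new_cells)
    old_ids = state.demes
    old_pos = {int(d): k for k, d in enumerate(old_ids)}
    new_ids = land_new.deme_ids
    D = len(new_ids)
    pi = np.zeros((D, D))

    if mode == "natural":
        def source_of(cell: int) -> int:
            r, c = landscape.cell_of(cell)
            best, best_d = None, None
            for d in old_ids:
                rr, cc = landscape.cell_of(int(d))
                dist = abs(rr - r) + abs(cc - c)
                if best_d is None or dist < best_d or (dist == best_d and d < best):
                    best, best_d = int(d), dist
            return best

        src = {c: source_of(c) for c in new_cells}
        proxy = {int(d): int(d) for d in old_ids}
        proxy.update(src)
        for a, da in enumerate(new_ids):
            for b in range(a, D):
                db = new_ids[b]
                pa, pb = proxy[int(da)], proxy[int(db)]
                pi[a, b] = pi[b, a] = state.pi[old_pos[pa], old_pos[pb]]
    else:
        sp = species_pi(state)
        col_mean = state.pi.mean(axis=0)
        newset = set(new_cells)
        for a, da in enumerate(new_ids):
            for b in range(a, D):
                db = new_ids[b]
                a_new, b_new = int(da) in newset, int(db) in newset
                if a_new and b_new:
                    pi[a, b] = pi[b, a] = sp
                elif a_new:
                    pi[a, b] = pi[b, a] = col_mean[old_pos[int(db)]]
                elif b_new:
                    pi[a, b] = pi[b, a] = col_mean[old_pos[int(da)]]
                else:
                    pi[a, b] = pi[b, a] = state.pi[old_pos[int(da)], old_pos[int(db)]]

    return DiversityMatrix(new_ids, pi), land_new


# ---------------------------------------------------------------- metrics


@dataclass
class FragMetrics:
    """Binary-landscape fragmentation metrics (4-neighbor patch definition)."""

    patch_count: int
    mean_patch_size: float
    core_area_total: int
    perimeter_total: int
    edge_density: float
    connectedness: float


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def landscape_metrics(mask: np.ndarray) -> FragMetrics:
    """Patch, core-area, perimeter, and connectedness metrics of a 0/1 mask.

    A core cell is an occupied cell whose four neighbors are all occupied
    (grid-boundary cells are never core); perimeter counts exposed cell
    edges; connectedness is the fraction of occupied-occupied pairs among
    grid-adjacent pairs that involve at least one occupied cell.
    """
    mask = np.asarray(mask, dtype=bool)
    occupied = int(mask.sum())
    if occupied == 0:
        return FragMetrics(0, 0.0, 0, 0, 0.0, 0.0)
    labels, n_patches = ndimage.label(mask, structure=_STRUCT4)
    core = ndimage.binary_erosion(mask, structure=_STRUCT4, border_value=0)
    # adjacent pairs
    h_both = int((mask[:, :-1] & mask[:, 1:]).sum())
    v_both = int((mask[:-1, :] & mask[1:, :]).sum())
    h_any = int((mask[:, :-1] | mask[:, 1:]).sum())
    v_any = int((mask[:-1, :] | mask[1:, :]).sum())
    occ_pairs = h_both + v_both
    any_pairs = h_any + v_any
    perimeter = 4 * occupied - 2 * occ_pairs
    rows, cols = mask.shape
    return FragMetrics(
        patch_count=int(n_patches),
        mean_patch_size=occupied / n_patches,
        core_area_total=int(core.sum()),
        perimeter_total=int(perimeter),
        edge_density=perimeter / (rows * cols),
        connectedness=occ_pairs / any_pairs if any_pairs else 0.0,
    )
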