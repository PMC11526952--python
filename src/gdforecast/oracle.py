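"""Discrete-deme multi-locus Wright-Fisher forward simulator.

A Monte Carlo check on the moment system: L independent biallelic loci evolve
on the occupied demes of a lattice by (1) deterministic mixing of allele
frequencies by the backward migration matrix, (2) binomial resampling of 2N
gametes per deme, and (3) symmetric recurrent mutation at rate mu per gamete.
Recurrent biallelic mutation approximates infinite sites while per-locus
theta = 4*N_total*mu remains well below 1; at very long horizons high-theta
loci saturate (frequency pushed toward 1/2), biasing diversity upward.

Segregating-site (allelic richness) trajectories come from the same state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import Landscape
from .moments import (
    apply_habitat_loss,
    equilibrium_diversity,
    evolve_diversity,
    local_pi as moment_local_pi,
    species_pi as moment_species_pi,
)
from .params import Params
from .scenarios import ScenarioSpec, edge_contraction_demes, fragmentation_mask

__all__ = [
    "SimState",
    "WrightFisherSim",
    "simulate_forward",
    "sim_pi",
    "sim_segregating_sites",
    "run_oracle_scenario",
]

#: Default burn-in length, in multiples of 2*N_total generations.
BURN_IN_RELAX_TIMES = 20


@dataclass
class SimState:
    """Allele frequencies of a forward simulation at one time point."""

    freqs: np.ndarray  # (n_demes, loci)
    landscape: Landscape
    params: Params
    generation: int
    seed: int

    @property
    def loci(self) -> int:
        return self.freqs.shape[1]

    @property
    def n_demes(self) -> int:
        return self.freqs.shape[0]


class WrightFisherSim:
    """Forward-in-time lattice Wright-Fisher simulation of allele frequencies."""

    def __init__(
        self,
        landscape: Landscape,
        params: Params,
        loci: int,
        seed: int,
        init_freq: float = 0.5,
    ):
        if loci < 1:
            raise ValueError("loci must be >= 1")
        self.landscape = landscape
        self.params = params
        self.loci = int(loci)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.generation = 0
        self.freqs = np.full((landscape.n_demes, loci), float(init_freq))
        self._mig_matrix = self._build_migration()

    def _build_migration(self) -> np.ndarray:
        ids = self.landscape.deme_ids
        pos = {int(d): k for k, d in enumerate(ids)}
        D = len(ids)
        m = self.params.mig
        M = np.eye(D)
        for d in ids:
            i = pos[int(d)]
            for nb in self.landscape.neighbors(int(d)):
                j = pos[nb]
                M[i, j] += m
                M[i, i] -= m
        if (M < -1e-12).any():
            raise ValueError("migration probabilities overflow: 4*m exceeds 1")
        return M

    def step(self, generations: int = 1) -> None:
        """Advance: migration mixing, binomial drift, symmetric mutation."""
        two_n = int(round(2 * self.params.deme_size))
        u = self.params.mu
        f = self.freqs
        M = self._mig_matrix
        for _ in range(int(generations)):
            f = M @ f
            f = self.rng.binomial(two_n, np.clip(f, 0.0, 1.0)) / two_n
            f = f * (1.0 - u) + (1.0 - f) * u
        self.freqs = f
        self.generation += int(generations)

    def remove_demes(self, removed: Sequence[int]) -> None:
        """Habitat loss: survivors keep their frequencies."""
        ids = self.landscape.deme_ids
        keep = ~np.isin(ids, np.asarray(list(removed), dtype=int))
        if not keep.any():
            raise ValueError("cannot remove all demes")
        self.landscape = self.landscape.remove(removed)
        self.freqs = self.freqs[keep]
        self._mig_matrix = self._build_migration()

    def state(self) -> SimState:
        return SimState(
            freqs=self.freqs.copy(),
            landscape=self.landscape,
            params=self.params,
            generation=self.generation,
            seed=self.seed,
        )

    def copy(self, seed: Optional[int] = None) -> "WrightFisherSim":
        """Clone the current state, optionally re-seeding the RNG stream."""
        new = object.__new__(WrightFisherSim)
        new.landscape = self.landscape
        new.params = self.params
        new.loci = self.loci
        new.seed = self.seed if seed is None else int(seed)
        new.rng = np.random.default_rng(new.seed)
        new.generation = self.generation
        new.freqs = self.freqs.copy()
        new._mig_matrix = self._mig_matrix.copy()
        return new


# ------------------------------------------------------------- estimators


def _sample_freqs(
    state: SimState, sample_n: int, rng: np.random.Generator, demes=None
) -> np.ndarray:
    """Per-locus sample allele frequencies of ``sample_n`` individuals.

    Individuals are drawn uniformly across the given demes (default: all);
    each contributes a Binomial(2, p_deme) dosage.
    """
    D = state.n_demes
    sel = np.arange(D) if demes is None else np.asarray(demes, dtype=int)
    total = int(state.params.deme_size * len(sel))
    if sample_n > total:
        raise ValueError(
            f"sample_n={sample_n} exceeds the {total} available individuals"
        )
    which = rng.choice(sel, size=sample_n, replace=True)
    dosages = rng.binomial(2, np.clip(state.freqs[which, :], 0.0, 1.0))
    return dosages.sum(axis=0) / (2.0 * sample_n)


def sim_pi(
    state: SimState,
    scope: str = "species",
    sample_n: int = 50,
    seed: int = 0,
) -> float:
    """Sample-based nucleotide diversity of the simulation state.

    Applies the unbiased estimator (n/(n-1)) * mean_l 2*p_hat*(1-p_hat) to a
    sample of ``sample_n`` individuals drawn species-wide, or per deme and
    averaged for the local scope.
    """
    if sample_n < 2:
        raise ValueError("sample_n must be >= 2")
    rng = np.random.default_rng(seed)
    n = sample_n
    corr = n / (n - 1.0)
    if scope == "species":
        p = _sample_freqs(state, sample_n, rng)
        return float(corr * np.mean(2.0 * p * (1.0 - p)))
    if scope == "local":
        if sample_n > state.params.deme_size:
            raise ValueError("sample_n exceeds individuals available per deme")
        vals = []
        for d in range(state.n_demes):
            p = _sample_freqs(state, sample_n, rng, demes=[d])
            vals.append(corr * np.mean(2.0 * p * (1.0 - p)))
        return float(np.mean(vals))
    raise ValueError(f"scope must be 'species' or 'local', got {scope!r}")


def frequency_pi(state: SimState, scope: str = "species") -> float:
    """Expected diversity computed from deme allele frequencies (no sampling).

    Species scope: mean over loci of 2*p_bar*(1-p_bar) with p_bar the
    across-deme mean frequency — identical in expectation to the
    deme-pair-averaged pairwise diversity tracked by the moment system.
    """
    f = state.freqs
    if scope == "species":
        p = f.mean(axis=0)
        return float(np.mean(2.0 * p * (1.0 - p)))
    if scope == "local":
        return float(np.mean(2.0 * f * (1.0 - f)))
    raise ValueError(f"scope must be 'species' or 'local', got {scope!r}")


def frequencies_table(state: SimState) -> pd.DataFrame:
    """Tidy (locus, deme, frequency) export of the current allele frequencies."""
    D, L = state.freqs.shape
    ids = state.landscape.deme_ids
    return pd.DataFrame(
        {
            "locus": np.repeat(np.arange(L), D),
            "deme": np.tile(ids, L),
            "frequency": state.freqs.T.ravel(),
        }
    )


def sim_segregating_sites(
    state: SimState,
    sample_n: int,
    scope: str = "species",
    demes: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> int:
    """Number of loci polymorphic in a sample (allelic richness).

    ``demes`` restricts sampling to the given deme positions (e.g. the
    survivors of an area subset) for mutations-area curves.
    """
    if sample_n < 2:
        raise ValueError("sample_n must be >= 2")
    if scope not in ("species", "area"):
        raise ValueError("scope must be 'species' or 'area'")
    rng = np.random.default_rng(seed)
    p = _sample_freqs(state, sample_n, rng, demes=demes)
    return int(np.count_nonzero((p > 0.0) & (p < 1.0)))


# --------------------------------------------------------------- pipelines


def simulate_forward(
    landscape: Landscape,
    params: Params,
    loci: int,
    generations: int,
    seed: int = 0,
    burn_in: Optional[int] = None,
    sample_every: Optional[int] = None,
    sample_n: int = 50,
) -> pd.DataFrame:
    """Burn in to stationarity, then record a diversity trajectory.

    Returns a tidy table of (generation, species_pi, local_pi,
    segregating_sites) where generation 0 is the end of the burn-in.  The
    default burn-in is 20 relaxation times (20 * 2 * N_total generations).
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    n_total = params.deme_size * landscape.n_demes
    if burn_in is None:
        burn_in = int(BURN_IN_RELAX_TIMES * 2 * n_total)
    if sample_every is None:
        sample_every = max(1, generations // 10)
    sim = WrightFisherSim(landscape, params, loci, seed)
    sim.step(burn_in)
    rows = []
    g = 0
    while True:
        st = sim.state()
        rows.append(
            {
                "generation": g,
                "species_pi": sim_pi(st, "species", sample_n, seed=seed + 7919 + g),
                "local_pi": sim_pi(
                    st, "local", min(sample_n, int(params.deme_size)), seed=seed + 104729 + g
                ),
                "segregating_sites": sim_segregating_sites(
                    st, sample_n, seed=seed + 1299709 + g
                ),
            }
        )
        if g >= generations:
            break
        step = min(sample_every, generations - g)
        sim.step(step)
        g += step
    return pd.DataFrame(rows)


def run_oracle_scenario(
    spec: ScenarioSpec,
    landscape: Landscape,
    params: Params,
    loci: int = 2000,
    reps: int = 9,
    seed: int = 0,
    loss_levels: Optional[Sequence[float]] = None,
    burn_in: Optional[int] = None,
    decorrelate: Optional[int] = None,
    include_long: bool = True,
) -> pd.DataFrame:
    """Replicated habitat-loss simulations matched to moment predictions.

    For each (loss level, replicate) the simulation is restricted to the
    surviving demes and evolved to the medium (and optionally long) horizon;
    frequency-based species/local diversity and sampled segregating sites are
    recorded next to the moment-system prediction for the same landscape.

    One shared burn-in feeds all replicates; each replicate then evolves an
    independent ``decorrelate`` generations (default 2*N_total) before the
    loss event under its own RNG stream.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if loss_levels is None:
        loss_levels = np.round(np.arange(0.1, 0.91, 0.1), 2)
    n_total = params.deme_size * landscape.n_demes
    if decorrelate is None:
        decorrelate = int(2 * n_total)

    base = WrightFisherSim(landscape, params, loci, seed)
    if burn_in is None:
        burn_in = int(BURN_IN_RELAX_TIMES * 2 * n_total)
    base.step(burn_in)

    eq = equilibrium_diversity(landscape, params)
    h = spec.horizons
    rows = []
    for rep in range(reps):
        sim0 = base.copy(seed=seed + 1000003 * (rep + 1))
        sim0.step(decorrelate)
        pre_state = sim0.state()
        pre_sp = frequency_pi(pre_state, "species")
        for level in loss_levels:
            if spec.scenario == "fragmentation":
                frag = fragmentation_mask(
                    landscape, level, spec.cell_block, seed=seed + 7 * rep + int(level * 100)
                )
                removed = frag.removed
            else:
                removed = edge_contraction_demes(landscape, level, spec.edge)
            sim = sim0.copy(seed=seed + 104729 * (rep + 1) + int(level * 100))
            if removed:
                sim.remove_demes(removed)
            mstate, mland = apply_habitat_loss(eq, landscape, removed)

            horizons = [("short", 0.0), ("medium", float(h.medium))]
            if include_long:
                horizons.append(("long", float(h.long)))
            prev_t = 0.0
            mcur = mstate
            for name, t in horizons:
                if t > prev_t:
                    sim.step(int(t - prev_t))
                    mcur = evolve_diversity(mcur, mland, params, t - prev_t)
                    prev_t = t
                st = sim.state()
                rows.append(
                    {
                        "loss_level": float(level),
                        "replicate": rep,
                        "horizon": name,
                        "generations_after": t,
                        "sim_species_pi": frequency_pi(st, "species"),
                        "sim_local_pi": frequency_pi(st, "local"),
                        "sim_segregating_sites": sim_segregating_sites(
                            st,
                            sample_n=min(50, int(params.deme_size * st.n_demes)),
                            seed=seed + 15485863 + rep + int(level * 100) + int(t),
                        ),
                        "sim_pre_species_pi": pre_sp,
                        "moment_species_pi": moment_species_pi(mcur),
                        "moment_local_pi": moment_local_pi(mcur),
                    }
                )
    return pd.DataFrame(rows)
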