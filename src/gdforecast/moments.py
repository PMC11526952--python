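"""Linear moment equations for expected pairwise nucleotide diversity.

For a metapopulation of demes connected by backward migration, the expected
per-site pairwise diversity pi_ij between a lineage sampled in deme i and one
sampled in deme j obeys a linear system of ordinary differential equations:

    d pi_ij / dt = 2 mu
                   - delta_ij * pi_ii / (2 N_i)
                   + sum_k m_ik (pi_kj - pi_ij)
                   + sum_k m_jk (pi_ik - pi_ij)

under the infinite-sites assumption (constant mutational influx ``2 mu``, no
back mutation).  ``m_ik`` is the probability that a lineage currently in deme
i had its parent in adjacent deme k; migration mass directed at unoccupied
cells stays in place.  The system is linear in the D(D+1)/2 distinct entries
of the symmetric matrix pi, so equilibria come from one sparse direct solve
and transients from the action of the matrix exponential.

Sanity anchors: a single deme equilibrates at pi = 4*N*mu, and a symmetric
two-deme system at pi_within = 8*N*mu, pi_between = 8*N*mu + mu/m (the
structured-coalescent closed forms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import coo_matrix, csc_matrix, csr_matrix
from scipy.sparse.linalg import expm_multiply, spsolve

from .landscape import Landscape
from .params import Params

__all__ = [
    "DiversityMatrix",
    "SingularSystemError",
    "equilibrium_diversity",
    "evolve_diversity",
    "apply_habitat_loss",
    "species_pi",
    "local_pi",
    "pairwise_fst",
    "tune_migration",
    "TuneResult",
]


class SingularSystemError(RuntimeError):
    """The stationary moment system has no solution (disconnected landscape)."""


@dataclass
class DiversityMatrix:
    """Symmetric matrix of expected pairwise diversity between demes.

    Attributes
    ----------
    demes : ndarray of int
        Ordered deme ids (flattened lattice cell indices).
    pi : ndarray, shape (D, D)
        Expected per-site pairwise nucleotide diversity; ``pi[i, j]`` refers
        to one lineage from ``demes[i]`` and one from ``demes[j]``.
    """

    demes: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.demes = np.asarray(self.demes, dtype=int)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(self.demes), len(self.demes)):
            raise ValueError("pi must be a square matrix aligned with demes")
        if not np.allclose(self.pi, self.pi.T, rtol=1e-10, atol=1e-20):
            raise ValueError("pi must be symmetric")
        if (self.pi < -1e-15).any():
            raise ValueError("pi entries must be non-negative")
        self.pi = 0.5 * (self.pi + self.pi.T)

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    def copy(self) -> "DiversityMatrix":
        return DiversityMatrix(self.demes.copy(), self.pi.copy())

    def restrict(self, keep_ids: Sequence[int]) -> "DiversityMatrix":
        """Submatrix over the given deme ids (order-preserving)."""
        keep = set(int(k) for k in keep_ids)
        sel = np.array([k for k, d in enumerate(self.demes) if int(d) in keep])
        if len(sel) == 0:
            raise ValueError("restriction would remove all demes")
        return DiversityMatrix(self.demes[sel], self.pi[np.ix_(sel, sel)])

    def to_csv(self, path) -> None:
        """Write as CSV with deme ids as header and index."""
        import pandas as pd

        pd.DataFrame(self.pi, index=self.demes, columns=self.demes).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DiversityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(dtype=int), df.to_numpy(dtype=float))


# ---------------------------------------------------------------- system ---


def _pair_system(landscape: Landscape, params: Params):
    """Sparse generator (A, b) of the moment ODE dx/dt = A x + b.

    The state x is the upper triangle (i <= j) of pi over the occupied demes
    in ``landscape.deme_ids`` order.
    """
    ids = landscape.deme_ids
    D = len(ids)
    pos = {int(d): k for k, d in enumerate(ids)}
    P = D * (D + 1) // 2

    # pair index for i <= j (local indices): p = i*D - i*(i-1)/2 + (j - i)
    def pidx(i, j):
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        return lo * D - lo * (lo - 1) // 2 + (hi - lo)

    m = params.mig
    rows_l, cols_l, vals_l = [], [], []
    alljs = np.arange(D)
    for a_id in ids:
        a = pos[int(a_id)]
        for b_id in landscape.neighbors(int(a_id)):
            b = pos[int(b_id)]
            # coordinate "a" of pair (a, j) migrates to b, for every j
            tgt = pidx(a, alljs)
            src = pidx(b, alljs)
            w = np.where(alljs == a, 2.0 * m, m)  # both coordinates when j == a
            rows_l.append(tgt)
            cols_l.append(src)
            vals_l.append(w)
            rows_l.append(tgt)
            cols_l.append(tgt)
            vals_l.append(-w)
    # coalescence on diagonal pairs
    diag_idx = pidx(alljs, alljs)
    rows_l.append(diag_idx)
    cols_l.append(diag_idx)
    vals_l.append(np.full(D, -1.0 / (2.0 * params.deme_size)))

    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    vals = np.concatenate(vals_l)
    A = coo_matrix((vals, (rows, cols)), shape=(P, P)).tocsr()
    b = np.full(P, 2.0 * params.mu)
    return A, b


def _condensed_to_matrix(x: np.ndarray, D: int) -> np.ndarray:
    out = np.empty((D, D))
    iu = np.triu_indices(D)
    out[iu] = x
    out.T[iu] = x
    return out


def _matrix_to_condensed(pi: np.ndarray) -> np.ndarray:
    return pi[np.triu_indices(len(pi))]


def equilibrium_diversity(landscape: Landscape, params: Params) -> DiversityMatrix:
    """Stationary expected pairwise diversity of the moment system.

    Solves ``A x = -b`` for the upper triangle of pi by a sparse direct
    solve.  The landscape must be connected: between-component diversity has
    no stationary point under infinite sites (it grows by 2*mu per
    generation), so disconnected landscapes raise
    :class:`SingularSystemError` naming the components.
    """
    ncomp, labels = landscape.component_labels()
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise SingularSystemError(
            f"stationary system is singular: landscape has {ncomp} disconnected "
            f"components (sizes {sizes.tolist()}); between-component diversity "
            "grows without bound — evolve to a finite horizon instead"
        )
    A, b = _pair_system(landscape, params)
    x = spsolve(csc_matrix(A), -b)
    D = landscape.n_demes
    return DiversityMatrix(landscape.deme_ids, _condensed_to_matrix(x, D))


def evolve_diversity(
    state: DiversityMatrix,
    landscape: Landscape,
    params: Params,
    t: float,
) -> DiversityMatrix:
    """Integrate the moment ODE forward ``t`` generations from ``state``.

    Uses the action of the matrix exponential on the affine system
    ``dx/dt = A x + b`` via the standard augmented-matrix trick, which is
    exact for this linear system (to Krylov tolerance) and handles
    disconnected landscapes, where some modes grow linearly.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if not np.array_equal(state.demes, landscape.deme_ids):
        raise ValueError("state demes do not match landscape demes")
    if t == 0:
        return state.copy()
    A, b = _pair_system(landscape, params)
    P = A.shape[0]
    x0 = _matrix_to_condensed(state.pi)
    # augmented generator [[A, b], [0, 0]] acting on [x; 1]
    aug = coo_matrix(
        (
            np.concatenate([A.tocoo().data, b]),
            (
                np.concatenate([A.tocoo().row, np.arange(P)]),
                np.concatenate([A.tocoo().col, np.full(P, P)]),
            ),
        ),
        shape=(P + 1, P + 1),
    ).tocsr()
    v = np.concatenate([x0, [1.0]])
    out = expm_multiply(aug * float(t), v)
    x = np.maximum(out[:P], 0.0)
    return DiversityMatrix(state.demes, _condensed_to_matrix(x, len(state.demes)))


# ------------------------------------------------------------- summaries ---


def species_pi(state: DiversityMatrix, weights: Optional[np.ndarray] = None) -> float:
    """Species-wide diversity: weighted average over all ordered deme pairs.

    ``sum_ij w_i w_j pi_ij`` with uniform weights by default — the expected
    pairwise difference between two individuals drawn at random from the
    whole (equally sized demes) landscape.
    """
    D = state.n_demes
    if weights is None:
        w = np.full(D, 1.0 / D)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != D:
            raise ValueError("weights length must match number of demes")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("weights must sum to 1")
    return float(w @ state.pi @ w)


def local_pi(state: DiversityMatrix) -> float:
    """Within-deme diversity: mean of the diagonal of pi."""
    return float(np.mean(np.diag(state.pi)))


def pairwise_fst(state: DiversityMatrix) -> float:
    """Mean pairwise Hudson-style F_ST across deme pairs.

    For each pair i < j:  F_ST = 1 - ((pi_ii + pi_jj)/2) / pi_ij.
    Pairs with pi_ij = 0 are excluded.
    """
    D = state.n_demes
    if D < 2:
        raise ValueError("pairwise F_ST is undefined for a single deme")
    iu, ju = np.triu_indices(D, k=1)
    between = state.pi[iu, ju]
    within = 0.5 * (state.pi[iu, iu] + state.pi[ju, ju])
    ok = between > 0
    if not ok.any():
        raise ValueError("all between-deme diversities are zero")
    return float(np.mean(1.0 - within[ok] / between[ok]))


# ----------------------------------------------------------- habitat loss ---


def apply_habitat_loss(
    state: DiversityMatrix, landscape: Landscape, removed
) -> tuple[DiversityMatrix, Landscape]:
    """Instantaneously remove demes; survivors keep their allele frequencies.

    Returns the restriction of pi to the surviving demes (the short-term
    state) and the updated landscape.  Migration mass formerly directed at
    removed cells stays in place, which is implicit: the generator is rebuilt
    from the surviving adjacency.
    """
    removed = [int(d) for d in removed]
    if not removed:
        return state.copy(), landscape
    occupied = set(int(d) for d in landscape.deme_ids)
    bad = [d for d in removed if d not in occupied]
    if bad:
        raise ValueError(f"cannot remove unoccupied demes: {bad}")
    if len(removed) >= len(occupied):
        raise ValueError("cannot remove all demes")
    new_land = landscape.remove(removed)
    new_state = state.restrict(new_land.deme_ids)
    return new_state, new_land


# ------------------------------------------------------------ F_ST tuning ---


class TuneResult(NamedTuple):
    mig: float
    achieved_fst: float
    converged: bool


#: Migration search bracket: below ``MIG_MIN`` demes are effectively isolated;
#: above ``MIG_MAX`` the 4-neighbor outflow would exceed 1.
MIG_MIN = 1e-8
MIG_MAX = 0.25


def tune_migration(
    landscape: Landscape,
    params: Params,
    target_fst: float,
    tol: float = 1e-3,
) -> TuneResult:
    """Migration rate whose equilibrium mean pairwise F_ST matches a target.

    Root-finds on log10(m) over [1e-8, 0.25] (F_ST is monotone decreasing in
    m on a fixed landscape).  If the target lies outside the achievable range
    the nearest bracket endpoint is returned with ``converged=False``.
    """
    if not (0 <= target_fst < 1):
        raise ValueError(f"target_fst must be in [0, 1), got {target_fst}")

    def fst_at(m: float) -> float:
        return pairwise_fst(equilibrium_diversity(landscape, params.with_mig(m)))

    hi = fst_at(MIG_MIN)  # largest achievable F_ST (weakest migration)
    lo = fst_at(MIG_MAX)  # smallest achievable F_ST
    if target_fst <= lo:
        return TuneResult(MIG_MAX, lo, abs(lo - target_fst) <= tol)
    if target_fst >= hi:
        return TuneResult(MIG_MIN, hi, abs(hi - target_fst) <= tol)

    def f(logm: float) -> float:
        return fst_at(10.0**logm) - target_fst

    logm = brentq(f, np.log10(MIG_MIN), np.log10(MIG_MAX), xtol=1e-6)
    m = 10.0**logm
    achieved = fst_at(m)
    return TuneResult(float(m), float(achieved), abs(achieved - target_fst) <= tol)
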