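"""Lattice landscapes: occupancy masks on a rectangular grid of demes.

A landscape is a ``rows x cols`` grid in which each cell may hold one deme.
Demes are identified by their flattened cell index ``r * cols + c``, which is
stable under habitat removal, and are connected by 4-neighbor (rook) adjacency
restricted to occupied cells.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["Landscape", "build_lattice"]


class Landscape:
    """An occupancy mask over a rectangular lattice of demes.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions (>= 1).
    mask : array-like of bool, optional
        Occupancy per cell, shape ``(rows, cols)``.  Defaults to fully
        occupied.  At least one cell must be occupied.
    """

    def __init__(self, rows: int, cols: int, mask=None):
        if rows < 1 or cols < 1:
            raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
        self.rows = int(rows)
        self.cols = int(cols)
        if mask is None:
            mask = np.ones((rows, cols), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise ValueError(f"mask shape {mask.shape} != ({rows}, {cols})")
        if not mask.any():
            raise ValueError("landscape must contain at least one occupied cell")
        self.mask = mask

    # ------------------------------------------------------------------ ids
    @property
    def deme_ids(self) -> np.ndarray:
        """Sorted flattened indices of occupied cells."""
        return np.flatnonzero(self.mask.ravel())

    @property
    def n_demes(self) -> int:
        return int(self.mask.sum())

    def cell_of(self, deme_id: int) -> tuple[int, int]:
        return divmod(int(deme_id), self.cols)

    def id_of(self, r: int, c: int) -> int:
        return r * self.cols + c

    # ------------------------------------------------------------ adjacency
    def edges(self) -> np.ndarray:
        """Undirected adjacency edges between occupied cells, shape (E, 2).

        Each row is a pair of deme ids (a, b) with a < b, grid-adjacent
        (4-neighbor) and both occupied.
        """
        m = self.mask
        out = []
        # horizontal
        h = m[:, :-1] & m[:, 1:]
        rr, cc = np.nonzero(h)
        out.append(np.stack([rr * self.cols + cc, rr * self.cols + cc + 1], axis=1))
        # vertical
        v = m[:-1, :] & m[1:, :]
        rr, cc = np.nonzero(v)
        out.append(
            np.stack([rr * self.cols + cc, (rr + 1) * self.cols + cc], axis=1)
        )
        return np.concatenate(out, axis=0) if out else np.empty((0, 2), dtype=int)

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def neighbors(self, deme_id: int) -> list[int]:
        """Occupied 4-neighbors of a deme."""
        r, c = self.cell_of(deme_id)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.rows and 0 <= cc < self.cols and self.mask[rr, cc]:
                out.append(self.id_of(rr, cc))
        return out

    def component_labels(self) -> tuple[int, np.ndarray]:
        """Connected components of the occupied subgraph.

        Returns ``(n_components, labels)`` where ``labels`` is aligned with
        ``deme_ids``.
        """
        ids = self.deme_ids
        pos = {d: k for k, d in enumerate(ids)}
        e = self.edges()
        if len(e):
            i = np.array([pos[a] for a in e[:, 0]])
            j = np.array([pos[b] for b in e[:, 1]])
            data = np.ones(len(e))
            g = coo_matrix((data, (i, j)), shape=(len(ids), len(ids)))
        else:
            g = coo_matrix((len(ids), len(ids)))
        n, labels = connected_components(g, directed=False)
        return n, labels

    # ------------------------------------------------------------- editing
    def remove(self, deme_ids: Iterable[int]) -> "Landscape":
        """New landscape with the given demes unoccupied."""
        ids = list(deme_ids)
        mask = self.mask.copy()
        for d in ids:
            r, c = self.cell_of(d)
            if not mask[r, c]:
                raise ValueError(f"deme {d} is not occupied")
            mask[r, c] = False
        if not mask.any():
            raise ValueError("cannot remove all demes")
        return Landscape(self.rows, self.cols, mask)

    def add(self, deme_ids: Iterable[int]) -> "Landscape":
        """New landscape with the given cells occupied."""
        mask = self.mask.copy()
        for d in deme_ids:
            r, c = self.cell_of(d)
            if mask[r, c]:
                raise ValueError(f"cell {d} is already occupied")
            mask[r, c] = True
        return Landscape(self.rows, self.cols, mask)

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "mask": ["".join("1" if x else "0" for x in row) for row in self.mask],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landscape":
        rows, cols = int(d["rows"]), int(d["cols"])
        if "mask" in d and d["mask"] is not None:
            mask = np.array(
                [[ch == "1" for ch in row] for row in d["mask"]], dtype=bool
            )
        else:
            mask = None
        return cls(rows, cols, mask)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def mask_text(self) -> str:
        """Plain-text 0/1 grid rendering of the occupancy mask."""
        return "\n".join("".join("1" if x else "0" for x in row) for row in self.mask)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Landscape({self.rows}x{self.cols}, {self.n_demes} demes, "
            f"{self.n_edges} edges)"
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Landscape)
            and self.rows == other.rows
            and self.cols == other.cols
            and bool(np.array_equal(self.mask, other.mask))
        )


def build_lattice(rows: int, cols: int, params=None) -> Landscape:
    """Fully occupied ``rows x cols`` lattice with 4-neighbor adjacency."""
    return Landscape(rows, cols)
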