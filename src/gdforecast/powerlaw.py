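"""Mutations-area (MAR) and genetic-diversity-area (GDAR) power laws.

Allelic richness M (segregating sites) and nucleotide diversity pi relate to
geographic range area A through power laws M = c * A**z.  The exponent z is
estimated by ordinary least squares of log(diversity) on log(area), and the
rearranged law 1 - (A_present / A_past)**z converts a fractional area loss
into a predicted fractional diversity loss.

This module also implements the in-silico extinction procedure on
geo-referenced genotype panels: individuals are binned into map cells, cells
are removed iteratively (at random, or north-to-south to mimic a moving
climate edge), and the diversity of survivors traces an empirical
extinction curve to which the power law is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "GridAssignment",
    "PowerLawFit",
    "grid_from_coords",
    "pi_from_genotypes",
    "segregating_sites_from_genotypes",
    "extinction_curve",
    "fit_powerlaw",
    "predict_loss",
]

#: Loci cap; larger panels are randomly downsampled.
MAX_LOCI = 10_000


@dataclass
class GenotypePanel:
    """Biallelic dosage genotypes (0/1/2, -1 = missing) with coordinates.

    ``coords`` columns are (x, y) — longitude/latitude treated as planar —
    one row per individual, aligned with ``genotypes`` rows.
    """

    genotypes: np.ndarray
    coords: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.genotypes.shape[0]
        if n < 2:
            raise ValueError("panel needs at least 2 individuals")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_individuals, 2) aligned with genotypes")
        if not self.ids:
            self.ids = [f"ind{i}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids must align with genotypes")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be dosages 0/1/2 or -1 for missing")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def downsample_loci(self, max_loci: int = MAX_LOCI, seed: int = 0) -> "GenotypePanel":
        if self.n_loci <= max_loci:
            return self
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(self.n_loci, size=max_loci, replace=False))
        return GenotypePanel(self.genotypes[:, keep], self.coords, list(self.ids))

    # ------------------------------------------------------------- readers
    @classmethod
    def from_vcf(cls, vcf_path, coords: pd.DataFrame) -> "GenotypePanel":
        """Read biallelic SNPs from a VCF; ``coords`` has columns id, lon, lat."""
        from cyvcf2 import VCF

        vcf = VCF(str(vcf_path), gts012=True)
        samples = list(vcf.samples)
        rows = []
        for var in vcf:
            if len(var.ALT) != 1:
                continue  # biallelic only
            g = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
            g[g == 3] = -1
            rows.append(g)
        if not rows:
            raise ValueError(f"no biallelic SNPs in {vcf_path}")
        genotypes = np.stack(rows, axis=1)
        return cls._with_coords(genotypes, samples, coords)

    @classmethod
    def from_plink(cls, ped_path, map_path, coords: pd.DataFrame) -> "GenotypePanel":
        """Read PLINK text .ped/.map (whitespace-separated, ACGT or 1/2 alleles)."""
        n_loci = sum(1 for line in open(map_path) if line.strip())
        samples, geno_rows = [], []
        with open(ped_path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 6 + 2 * n_loci:
                    raise ValueError(
                        f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields, "
                        f"got {len(parts)}"
                    )
                samples.append(parts[1])
                alleles = np.array(parts[6:]).reshape(n_loci, 2)
                geno_rows.append(alleles)
        alleles = np.stack(geno_rows)  # (n, L, 2)
        n, L, _ = alleles.shape
        genotypes = np.full((n, L), -1, dtype=np.int8)
        for l in range(L):
            col = alleles[:, l, :]
            obs = np.unique(col[col != "0"])
            if len(obs) > 2:
                raise ValueError(f"{map_path}: locus {l} has >2 alleles: {obs}")
            ref = obs[0] if len(obs) else "0"
            missing = (col == "0").any(axis=1)
            dos = (col != ref).sum(axis=1).astype(np.int8)
            dos[missing] = -1
            genotypes[:, l] = dos
        return cls._with_coords(genotypes, samples, coords)

    @classmethod
    def _with_coords(cls, genotypes, samples, coords: pd.DataFrame) -> "GenotypePanel":
        coords = coords.set_index(coords.columns[0])
        missing = [s for s in samples if s not in coords.index]
        if missing:
            raise ValueError(f"coordinates missing for samples: {missing[:5]}")
        xy = coords.loc[samples].iloc[:, :2].to_numpy(dtype=float)
        return cls(genotypes, xy, list(samples))


# ----------------------------------------------------------------- gridding


@dataclass
class GridAssignment:
    """Bounding-box grid over coordinates with individual->cell assignment."""

    resolution: int
    cell_of_individual: np.ndarray  # (n,) flattened cell index
    occupied_cells: np.ndarray  # sorted unique occupied flattened indices
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def n_occupied(self) -> int:
        return len(self.occupied_cells)

    def individuals_in(self, cells: Sequence[int]) -> np.ndarray:
        return np.flatnonzero(np.isin(self.cell_of_individual, np.asarray(cells)))

    def cell_row(self, cell: int) -> int:
        """Grid row (y / latitude bin, 0 = lowest latitude) of a cell."""
        return int(cell) // self.resolution


def grid_from_coords(coords: np.ndarray, resolution: int) -> GridAssignment:
    """Bin coordinates into a ``resolution x resolution`` bounding-box grid.

    Cells are half-open [lo, hi) on each axis with the last cell closed, so
    the assignment is a partition.  A degenerate bounding box (all points
    identical on an axis) collapses to a single cell on that axis.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 1:
        raise ValueError("coords must be a non-empty (n, 2) array")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")

    def bin_axis(v):
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(len(v), dtype=int), np.array([lo, lo])
        edges = np.linspace(lo, hi, resolution + 1)
        idx = np.minimum(((v - lo) / (hi - lo) * resolution).astype(int), resolution - 1)
        return idx, edges

    cx, x_edges = bin_axis(coords[:, 0])
    cy, y_edges = bin_axis(coords[:, 1])
    flat = cy * resolution + cx
    return GridAssignment(
        resolution=resolution,
        cell_of_individual=flat,
        occupied_cells=np.unique(flat),
        x_edges=x_edges,
        y_edges=y_edges,
    )


def default_resolution(coords: np.ndarray, min_cells: int = 10, max_resolution: int = 20):
    """Smallest grid resolution yielding >= ``min_cells`` occupied cells."""
    for res in range(2, max_resolution + 1):
        g = grid_from_coords(coords, res)
        if g.n_occupied >= min_cells:
            logger.info("grid resolution %d gives %d occupied cells", res, g.n_occupied)
            return res
    logger.warning(
        "no resolution up to %d reaches %d occupied cells; using %d",
        max_resolution, min_cells, max_resolution,
    )
    return max_resolution


# --------------------------------------------------------------- estimators


def pi_from_genotypes(genotypes: np.ndarray) -> float:
    """Unbiased nucleotide diversity from a dosage matrix.

    pi = (1/L) * sum_l (n_l/(n_l - 1)) * 2 * p_l * (1 - p_l) with per-locus
    sample sizes n_l counting non-missing individuals (pairwise-complete
    allele frequencies); loci with fewer than 2 genotyped individuals are
    excluded from L.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a (n>=2, L) genotype matrix")
    obs = g >= 0
    n_l = obs.sum(axis=0)
    usable = n_l >= 2
    if not usable.any():
        raise ValueError("no locus has 2 or more genotyped individuals")
    g = np.where(obs, g, 0.0)
    p = g.sum(axis=0)[usable] / (2.0 * n_l[usable])
    n = n_l[usable]
    return float(np.mean(n / (n - 1.0) * 2.0 * p * (1.0 - p)))


def segregating_sites_from_genotypes(genotypes: np.ndarray) -> int:
    """Loci polymorphic among the non-missing genotypes."""
    g = np.asarray(genotypes, dtype=float)
    obs = g >= 0
    n_l = obs.sum(axis=0)
    tot = np.where(obs, g, 0.0).sum(axis=0)
    seg = (n_l > 0) & (tot > 0) & (tot < 2 * n_l)
    return int(np.count_nonzero(seg))


# --------------------------------------------------------- extinction curve


def extinction_curve(
    panel: GenotypePanel,
    scheme: str = "random",
    resolution: Optional[int] = None,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """In-silico extinction on a geo-referenced panel.

    Map cells are removed one at a time — uniformly at random, or strictly by
    descending latitude (northernmost cells first, ties broken by a seeded
    shuffle) for the south-north scheme — and individuals in removed cells go
    extinct.  Each row records the remaining area fraction (surviving cells /
    total occupied cells), surviving sample size, pi (NaN once n < 2), and
    segregating sites, per replicate.
    """
    if scheme not in ("random", "south_north"):
        raise ValueError("scheme must be 'random' or 'south_north'")
    if resolution is None:
        resolution = default_resolution(panel.coords)
    grid = grid_from_coords(panel.coords, resolution)
    cells = grid.occupied_cells
    total = len(cells)
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        order = cells.copy()
        rng.shuffle(order)
        if scheme == "south_north":
            # stable sort by descending latitude row keeps the shuffled
            # order as the tie-break within a row
            lat_rank = np.array([grid.cell_row(c) for c in order])
            order = order[np.argsort(-lat_rank, kind="stable")]
        alive = np.ones(panel.n_individuals, dtype=bool)
        removed_cells = 0

        def record():
            n = int(alive.sum())
            sub = panel.genotypes[alive]
            pi = pi_from_genotypes(sub) if n >= 2 else float("nan")
            s = segregating_sites_from_genotypes(sub) if n >= 1 else 0
            rows.append(
                {
                    "area_fraction_remaining": 1.0 - removed_cells / total,
                    "n_individuals": n,
                    "pi": pi,
                    "segregating_sites": s,
                    "replicate": rep,
                    "scheme": scheme,
                }
            )

        record()
        for cell in order[:-1]:  # keep the last cell so survivors remain
            alive[grid.individuals_in([cell])] = False
            removed_cells += 1
            record()
    return pd.DataFrame(rows)


# ------------------------------------------------------------ power-law fit


@dataclass
class PowerLawFit:
    """Result of a log-log least-squares fit of diversity on area."""

    z: float
    c: float
    r2: float
    n_used: int
    n_dropped: int = 0

    def predict(self, area: float) -> float:
        return self.c * area**self.z

    def to_dict(self) -> dict:
        return {
            "z": self.z,
            "c": self.c,
            "r2": self.r2,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
        }


def fit_powerlaw(areas, diversity) -> PowerLawFit:
    """OLS of log(diversity) on log(area); z is the slope.

    Rows with non-positive or missing diversity (or area) are dropped and
    counted; at least 3 usable points are required.
    """
    a = np.asarray(areas, dtype=float)
    d = np.asarray(diversity, dtype=float)
    if a.shape != d.shape:
        raise ValueError("areas and diversity must align")
    ok = np.isfinite(a) & np.isfinite(d) & (a > 0) & (d > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("fit_powerlaw: dropped %d rows with zero/missing diversity", n_dropped)
    a, d = a[ok], d[ok]
    if len(a) < 3:
        raise ValueError(f"need >= 3 usable (area, diversity) points, have {len(a)}")
    la, ld = np.log(a), np.log(d)
    z, intercept = np.polyfit(la, ld, 1)
    resid = ld - (z * la + intercept)
    ss_tot = float(np.sum((ld - ld.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(
        z=float(z), c=float(np.exp(intercept)), r2=float(r2),
        n_used=int(len(a)), n_dropped=n_dropped,
    )


def predict_loss(z: float, remaining_fraction: float) -> float:
    """Fractional diversity loss predicted by the power law.

    loss = 1 - remaining_fraction**z; e.g. z = 0.3 at 50% of the range
    remaining predicts 1 - 0.5**0.3 = 0.188 (~19%).
    """
    if not (0 < remaining_fraction <= 1):
        raise ValueError("remaining_fraction must be in (0, 1]")
    if z < 0:
        raise ValueError("z must be non-negative")
    return 1.0 - remaining_fraction**z
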