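"""Synthetic geo-referenced genotype panels and fixture writers.

Panels emulate a spatially structured species sampled across its range: demes
on a coarse geographic grid receive allele frequencies from the
Balding-Nichols model (deme frequency ~ Beta with differentiation F around an
ancestral frequency), individuals are placed uniformly inside their deme's
cell, and dosages are Binomial(2, p_deme) draws.  This reproduces the
features the extinction-curve machinery depends on — spatial clustering,
between-cell differentiation scaling with F, missing data — but not linkage,
isolation-by-distance gradients, or ascertainment of real SNP panels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .powerlaw import GenotypePanel

__all__ = ["synth_genotype_panel", "write_vcf", "write_plink", "write_coords"]


def synth_genotype_panel(
    n_individuals: int = 200,
    n_loci: int = 1000,
    grid: tuple = (5, 5),
    fst: float = 0.2,
    missing_rate: float = 0.0,
    seed: int = 0,
    latitude_cline: float = 0.0,
) -> GenotypePanel:
    """Balding-Nichols panel on a ``grid`` of demes.

    ``latitude_cline`` adds a north-south allele-frequency gradient (logit
    shift per grid row) so that south-north extinction schemes see
    directional structure.  ``fst`` is the Balding-Nichols differentiation
    parameter, not a promised realized Hudson F_ST.
    """
    if not (0 < fst < 1):
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    gr, gc = grid
    n_cells = gr * gc
    cells = rng.integers(0, n_cells, size=n_individuals)
    anc = rng.uniform(0.05, 0.95, size=n_loci)
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst
    deme_freqs = np.clip(rng.beta(a, b, size=(n_cells, n_loci)), 1e-9, 1 - 1e-9)
    if latitude_cline:
        row_of = np.arange(n_cells) // gc
        logit = np.log(deme_freqs / (1 - deme_freqs))
        logit += latitude_cline * (row_of[:, None] - (gr - 1) / 2.0)
        deme_freqs = 1.0 / (1.0 + np.exp(-logit))
    geno = rng.binomial(2, deme_freqs[cells, :]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    rows, cols = np.divmod(cells, gc)
    # y grows with grid row: row 0 = southernmost latitude
    x = cols + rng.random(n_individuals)
    y = rows + rng.random(n_individuals)
    coords = np.column_stack([x, y])
    ids = [f"ind{i:04d}" for i in range(n_individuals)]
    return GenotypePanel(geno, coords, ids)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal uncompressed VCF 4.2 with GT fields for the panel."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.ids),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for l in range(panel.n_loci):
        gts = "\t".join(gt_map[int(d)] for d in panel.genotypes[:, l])
        lines.append(f"1\t{l + 1}\tsnp{l}\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def write_plink(panel: GenotypePanel, ped_path, map_path) -> None:
    """PLINK text .ped/.map (alleles A/T, 0 = missing)."""
    allele_map = {0: ("A", "A"), 1: ("A", "T"), 2: ("T", "T"), -1: ("0", "0")}
    with open(map_path, "w") as fh:
        for l in range(panel.n_loci):
            fh.write(f"1 snp{l} 0 {l + 1}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.ids):
            alleles = []
            for d in panel.genotypes[i]:
                alleles.extend(allele_map[int(d)])
            fh.write(f"FAM {sid} 0 0 0 -9 " + " ".join(alleles) + "\n")


def write_coords(panel: GenotypePanel, path) -> None:
    """Coordinates CSV (id, lon, lat)."""
    pd.DataFrame(
        {"id": panel.ids, "lon": panel.coords[:, 0], "lat": panel.coords[:, 1]}
    ).to_csv(path, index=False)
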