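"""Population-genetic parameters for lattice metapopulations.

The model is parameterized by a per-site, per-generation mutation rate ``mu``,
a diploid deme size ``deme_size`` (N), and a backward migration probability
``mig`` (m): the per-generation probability that a lineage's parent lived in a
given adjacent deme.  The compound parameter theta = 4 * N_total * mu equals
the equilibrium nucleotide diversity of a panmictic population under infinite
sites, and is the natural reporting scale for diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["Params", "DEFAULT_THETA", "DEFAULT_MU"]

#: Species-wide scaled mutation rate used throughout as the default study
#: condition (theta = 4 N_total mu).
DEFAULT_THETA = 1e-4
#: Per-site per-generation mutation rate default.
DEFAULT_MU = 1e-8

#: Maximum number of lattice neighbors (4-neighbor migration scheme).
MAX_NEIGHBORS = 4


@dataclass(frozen=True)
class Params:
    """Mutation, drift, and migration rates for a lattice metapopulation.

    Parameters
    ----------
    mu : float
        Per-site per-generation mutation rate (> 0).
    deme_size : float
        Diploid individuals per occupied deme, N (>= 1).
    mig : float
        Backward migration probability per adjacent occupied deme, m.
        Constrained so that ``MAX_NEIGHBORS * mig <= 1``.
    """

    mu: float = DEFAULT_MU
    deme_size: float = 25.0
    mig: float = 0.01

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.deme_size < 1:
            raise ValueError(f"deme_size must be >= 1, got {self.deme_size}")
        if self.mig < 0 or MAX_NEIGHBORS * self.mig > 1 + 1e-12:
            raise ValueError(
                f"mig must satisfy 0 <= mig and {MAX_NEIGHBORS}*mig <= 1, got {self.mig}"
            )

    def theta(self, n_demes: int) -> float:
        """Scaled mutation rate 4*N_total*mu for ``n_demes`` occupied demes."""
        return 4.0 * self.deme_size * n_demes * self.mu

    def with_mig(self, mig: float) -> "Params":
        """Copy of these parameters with a different migration rate."""
        return replace(self, mig=mig)

    def to_dict(self) -> dict:
        return {"mu": self.mu, "deme_size": self.deme_size, "mig": self.mig}

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        return cls(
            mu=float(d.get("mu", DEFAULT_MU)),
            deme_size=float(d.get("deme_size", 25.0)),
            mig=float(d.get("mig", 0.01)),
        )


def params_for_theta(
    theta: float = DEFAULT_THETA,
    n_demes: int = 100,
    deme_size: float = 25.0,
    mig: float = 0.01,
) -> Params:
    """Params with ``mu`` chosen so that 4*N_total*mu equals ``theta``."""
    mu = theta / (4.0 * deme_size * n_demes)
    return Params(mu=mu, deme_size=deme_size, mig=mig)
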