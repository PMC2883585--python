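"""Model parameters and elementary domain types.

The model describes a population of asexual haploid cells that grow into
undifferentiated colonies of ``S = 2**n_divisions`` cells by binary division.
Each cell carries four heritable allelic effects in [0, 1]:

``x``
    fertility gene effect (reproductive function),
``y``
    viability gene effect (somatic function),
``g``
    germ-suppressor effect, expressed only in proto-germ cells, where it
    suppresses the viability gene,
``s``
    soma-suppressor effect, expressed only in proto-soma cells, where it
    suppresses the fertility gene.

Fertility and viability trade off against each other with strength ``beta``;
``alpha`` sets the curvature of the direct gene effects. Developmental
plasticity (the conditional suppression) carries a Gaussian fitness cost
scaled by ``cost_scale`` (larger = cheaper).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple

__all__ = [
    "GERM",
    "SOMA",
    "ModelParams",
    "Genotype",
    "FitnessComponents",
    "ParameterError",
]

#: Role label for cells assigned to the reproductive caste by the
#: environmental cue (position/size dichotomy within the colony).
GERM = "proto-germ"
#: Role label for cells assigned to the somatic caste.
SOMA = "proto-soma"


class ParameterError(ValueError):
    """A model parameter or trait value is outside its admissible range."""


class Genotype(NamedTuple):
    """Heritable allelic effects of the two major and two regulatory loci."""

    x: float
    y: float
    g: float = 0.0
    s: float = 0.0

    def validate(self) -> "Genotype":
        for name, value in zip(self._fields, self):
            if not (0.0 <= value <= 1.0):
                raise ParameterError(
                    f"allelic effect {name}={value!r} outside [0, 1]"
                )
        return self


class FitnessComponents(NamedTuple):
    """Realized per-cell fitness components, both probabilities in [0, 1]."""

    fertility: float
    viability: float


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the colony life-cycle model.

    Parameters
    ----------
    alpha : float
        Shape of the relationship between a direct gene effect and the
        corresponding fitness component (dimensionless, > 0).
    beta : float
        Strength of the fertility/viability trade-off (dimensionless, >= 0);
        trade-offs are completely absent when ``beta == 0``. Direct effects
        are expected to be at least as strong as indirect ones, so
        ``beta > alpha`` triggers a warning (not an error).
    cost_scale : float
        Scale ``c`` of the Gaussian plasticity cost ``exp(-(effect/c)**2)``;
        larger values correspond to smaller costs (> 0).
    p : float
        Proportion of proto-germ cells in every colony, in (0, 1).
    n_divisions : int
        Number of binary divisions a founder cell goes through; the colony
        size is ``S = 2**n_divisions`` (>= 1).
    mu : float
        Per-gene, per-cell-division mutation probability, in [0, 1].
    sigma_m : float
        Standard deviation of the (truncated) Gaussian mutational step,
        in trait units (>= 0).
    K0 : float
        Maximum carrying capacity of the population of colonies (> 0).
    b : float
        Beverton-Holt "offspring number" parameter of the density-dependent
        colony survival probability (> 1).
    """

    alpha: float = 2.0
    beta: float = 1.0
    cost_scale: float = 2.0
    p: float = 0.5
    n_divisions: int = 4
    mu: float = 1e-4
    sigma_m: float = 0.05
    K0: float = 1000.0
    b: float = 2.0
    max_colonies_factor: float = field(default=10.0, repr=False)

    def __post_init__(self) -> None:
        checks = [
            ("alpha", self.alpha > 0, "must be > 0"),
            ("beta", self.beta >= 0, "must be >= 0"),
            ("cost_scale", self.cost_scale > 0, "must be > 0"),
            ("p", 0.0 < self.p < 1.0, "must be in (0, 1)"),
            ("n_divisions", int(self.n_divisions) == self.n_divisions
             and self.n_divisions >= 1, "must be an integer >= 1"),
            ("mu", 0.0 <= self.mu <= 1.0, "must be in [0, 1]"),
            ("sigma_m", self.sigma_m >= 0.0, "must be >= 0"),
            ("K0", self.K0 > 0, "must be > 0"),
            ("b", self.b > 1.0, "must be > 1"),
            ("max_colonies_factor", self.max_colonies_factor > 0,
             "must be > 0"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ParameterError(
                    f"{name}={getattr(self, name)!r} {msg}"
                )
        if self.beta > self.alpha:
            # Direct gene effects should be at least as strong as the
            # indirect trade-off effects; the model remains well defined
            # beyond this point, so warn rather than fail.
            warnings.warn(
                f"beta={self.beta} exceeds alpha={self.alpha}; the model "
                "assumes direct effects at least as strong as indirect "
                "ones (beta <= alpha)",
                stacklevel=2,
            )

    @property
    def S(self) -> int:
        """Colony size, exactly ``2**n_divisions``."""
        return 2 ** int(self.n_divisions)

    @property
    def n_germ(self) -> int:
        """Number of proto-germ cells per colony, ``round(p * S)``."""
        return round(self.p * self.S)

    @property
    def max_colonies(self) -> int:
        """Hard cap on the number of colonies (guards runaway demography).

        The deterministic model can never exceed ``K0 * (S-1)/(b-1)``
        colonies (the carrying capacity at f = v = 1), so the cap is a
        multiple of that bound.
        """
        bound = self.K0 * max(1.0, (self.S - 1.0) / (self.b - 1.0))
        return int(math.ceil(self.max_colonies_factor * bound))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "max_colonies_factor"}
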