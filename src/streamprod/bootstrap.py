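"""Bootstrap replicate containers.

Every uncertain quantity in the pipeline (growth rate, biomass, production,
P:B, slope coefficients) is carried as an ordered vector of bootstrap
replicates.  The replicate *index* is the pairing key: replicate ``i`` of a
population's growth rate pairs with replicate ``i`` of its biomass and of
every quantity derived from them, so sums and ratios stay internally
consistent (community production is the replicate-wise sum of population
production, P:B times B reproduces P exactly, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BootstrapDistribution"]


@dataclass(frozen=True)
class BootstrapDistribution:
    """An ordered vector of bootstrap replicate estimates.

    Parameters
    ----------
    replicates
        One estimate per bootstrap iteration.  Order matters: it is the
        pairing key across quantities sharing a seed.
    seed
        Seed of the generator that produced the replicates, if known.
    """

    replicates: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        reps = np.asarray(self.replicates, dtype=float)
        if reps.ndim != 1 or reps.size == 0:
            raise ValueError("replicates must be a non-empty 1-d vector")
        object.__setattr__(self, "replicates", reps)

    # -- summary statistics -------------------------------------------------
    @property
    def n_boot(self) -> int:
        return int(self.replicates.size)

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def ci_low(self) -> float:
        return float(np.percentile(self.replicates, 2.5))

    @property
    def ci_high(self) -> float:
        return float(np.percentile(self.replicates, 97.5))

    def quantile(self, q) -> np.ndarray:
        return np.percentile(self.replicates, np.asarray(q) * 100.0)

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    # -- replicate-wise arithmetic (pairing preserved) ----------------------
    def _coerce(self, other) -> np.ndarray:
        if isinstance(other, BootstrapDistribution):
            if other.n_boot != self.n_boot:
                raise ValueError(
                    f"pairing violation: n_boot {self.n_boot} != {other.n_boot}"
                )
            return other.replicates
        return np.asarray(other, dtype=float)

    def __add__(self, other) -> "BootstrapDistribution":
        return BootstrapDistribution(self.replicates + self._coerce(other), self.seed)

    __radd__ = __add__

    def __sub__(self, other) -> "BootstrapDistribution":
        return BootstrapDistribution(self.replicates - self._coerce(other), self.seed)

    def __mul__(self, other) -> "BootstrapDistribution":
        return BootstrapDistribution(self.replicates * self._coerce(other), self.seed)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "BootstrapDistribution":
        return BootstrapDistribution(self.replicates / self._coerce(other), self.seed)

    @staticmethod
    def degenerate(value: float, n_boot: int, seed: int | None = None) -> "BootstrapDistribution":
        """A zero-width distribution: every replicate equals ``value``."""
        return BootstrapDistribution(np.full(n_boot, float(value)), seed)

    @staticmethod
    def sum(dists: list["BootstrapDistribution"]) -> "BootstrapDistribution":
        """Replicate-wise sum of paired distributions."""
        if not dists:
            raise ValueError("nothing to sum")
        n = dists[0].n_boot
        for d in dists[1:]:
            if d.n_boot != n:
                raise ValueError("mismatched n_boot across distributions")
        total = np.sum([d.replicates for d in dists], axis=0)
        return BootstrapDistribution(total, dists[0].seed)
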