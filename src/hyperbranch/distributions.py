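"""Chain-length (degree of polymerization) distributions.

Polydisperse hyperbranched ensembles are parameterized by an average degree
of polymerization ``ADP`` and a polydispersity index ``PDI`` = Mw/Mn.  Two
classical single-site polymerization statistics are provided, plus the
degenerate monodisperse case:

* **Schulz-Zimm** — number density f(δ) ∝ δ^(u-1) e^(-uδ) with δ = DP/ADP
  and shape parameter u = 1/(PDI-1), so that PDI = (u+1)/u.
* **Poisson** — number fraction e^(-λ) λ^(DP-1) / (DP-1)! with λ = ADP-1,
  for which PDI is not free: PDI = 1 + (ADP-1)/ADP².

The continuous Schulz-Zimm density is evaluated on the integer DP grid
[dp_min, dp_max] and renormalized; moments converge to the analytic values
as the grid widens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "DistributionSpec",
    "DPAllocation",
    "number_fraction",
    "grid_weights",
    "allocate_counts",
    "sample_dps",
    "sample_pdi",
    "poisson_pdi",
]

MODES = ("schulz_zimm", "poisson", "monodisperse")


def poisson_pdi(adp: int) -> float:
    """Polydispersity implied by a Poisson chain-length distribution."""
    return 1.0 + (adp - 1) / adp**2


@dataclass(frozen=True)
class DistributionSpec:
    """One chain-length distribution: mode, ADP, PDI and the DP grid.

    Parameters
    ----------
    mode:
        ``"schulz_zimm"``, ``"poisson"`` or ``"monodisperse"``.
    adp:
        Average degree of polymerization (repeat units), >= 1.
    pdi:
        Polydispersity index Mw/Mn, > 1 for Schulz-Zimm.  Ignored (with a
        warning) for Poisson, where it is fixed to 1 + (ADP-1)/ADP²; ignored
        silently for monodisperse where it is 1 by definition.
    dp_min, dp_max:
        Truncation bounds of the integer DP grid.  ``dp_max`` defaults to
        20·ADP, wide enough that the truncated moments agree with the
        analytic ones to well under a percent.
    """

    mode: str
    adp: int
    pdi: float | None = None
    dp_min: int = 3
    dp_max: int | None = field(default=None)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not isinstance(self.adp, (int, np.integer)) or self.adp < 1:
            raise ValidationError(f"adp must be an integer >= 1, got {self.adp!r}")
        if self.dp_max is None:
            object.__setattr__(self, "dp_max", 20 * self.adp)
        if self.dp_min < 1:
            raise ValidationError(f"dp_min must be >= 1, got {self.dp_min}")
        if not (self.dp_min <= self.adp <= self.dp_max):
            raise ValidationError(
                f"require dp_min <= adp <= dp_max, got {self.dp_min} <= {self.adp} <= {self.dp_max}"
            )
        if self.mode == "schulz_zimm":
            if self.pdi is None or self.pdi <= 1.0:
                raise ValidationError(
                    f"pdi must be > 1 for schulz_zimm mode, got {self.pdi!r}"
                )
        elif self.mode == "poisson":
            implied = poisson_pdi(self.adp)
            if self.pdi is not None and not math.isclose(self.pdi, implied):
                warnings.warn(
                    f"Poisson mode fixes PDI = 1 + (ADP-1)/ADP^2 = {implied:.6f}; "
                    f"ignoring user-supplied pdi={self.pdi}",
                    stacklevel=2,
                )
            object.__setattr__(self, "pdi", implied)
        else:  # monodisperse
            object.__setattr__(self, "pdi", 1.0)

    @property
    def u(self) -> float:
        """Schulz-Zimm shape parameter u = 1/(PDI - 1)."""
        if self.mode != "schulz_zimm":
            raise ValidationError("shape parameter u is defined only for schulz_zimm")
        return 1.0 / (self.pdi - 1.0)

    def grid(self) -> np.ndarray:
        """Integer DP grid [dp_min, dp_max]."""
        return np.arange(self.dp_min, self.dp_max + 1)


@dataclass(frozen=True)
class DPAllocation:
    """How many molecules to build at each DP; counts sum to the total RNP."""

    entries: tuple[tuple[int, int], ...]
    total: int

    def __post_init__(self):
        if sum(c for _, c in self.entries) != self.total:
            raise ValidationError("allocation counts do not sum to the total")


def grid_weights(spec: DistributionSpec) -> np.ndarray:
    """Normalized number fractions over the spec's DP grid."""
    dps = spec.grid()
    if spec.mode == "monodisperse":
        w = (dps == spec.adp).astype(float)
    elif spec.mode == "poisson":
        # number fraction e^(-λ) λ^(dp-1)/(dp-1)!  with λ = ADP-1
        w = stats.poisson.pmf(dps - 1, mu=spec.adp - 1)
    else:
        u = spec.u
        delta = dps / spec.adp
        logw = (u - 1.0) * np.log(delta) - u * delta
        w = np.exp(logw - logw.max())
    s = w.sum()
    if s <= 0:
        raise ValidationError("distribution has zero mass on the DP grid")
    return w / s


def number_fraction(spec: DistributionSpec, dp: int) -> float:
    """Normalized number fraction of chains of length ``dp``.

    DPs outside [dp_min, dp_max] have zero weight (truncation, not an error).
    """
    if dp < 1:
        raise ValidationError(f"dp must be >= 1, got {dp}")
    if dp < spec.dp_min or dp > spec.dp_max:
        return 0.0
    return float(grid_weights(spec)[dp - spec.dp_min])


def allocate_counts(spec: DistributionSpec, rnp: int) -> DPAllocation:
    """Deterministically split ``rnp`` molecules over the DP grid.

    Largest-remainder rounding of rnp·weight so the counts sum exactly to
    rnp; remainder ties go to the smaller DP.
    """
    if not isinstance(rnp, (int, np.integer)) or rnp < 1:
        raise ValidationError(f"rnp must be an integer >= 1, got {rnp!r}")
    dps = spec.grid()
    quota = rnp * grid_weights(spec)
    base = np.floor(quota).astype(int)
    short = rnp - int(base.sum())
    frac = quota - base
    # stable sort by (-fraction, dp): ties broken by smaller dp
    order = np.lexsort((dps, -frac))
    base[order[:short]] += 1
    entries = tuple((int(d), int(c)) for d, c in zip(dps, base) if c > 0)
    return DPAllocation(entries=entries, total=rnp)


def sample_dps(spec: DistributionSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` chain lengths from the truncated grid distribution."""
    return rng.choice(spec.grid(), size=size, p=grid_weights(spec))


def sample_pdi(dps) -> float:
    """Realized polydispersity Mw/Mn of a sample of chain lengths.

    Mw = Σdp²/Σdp and Mn = Σdp/n with unit repeat-unit mass.
    """
    arr = np.asarray(dps, dtype=float)
    if arr.size == 0:
        raise ValidationError("sample_pdi requires a non-empty sample")
    if np.any(arr <= 0):
        raise ValidationError("chain lengths must be positive")
    mw = (arr**2).sum() / arr.sum()
    mn = arr.mean()
    return float(mw / mn)
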