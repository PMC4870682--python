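"""Grafting linear arms onto hyperbranched cores (HBP -> HBMC).

Eligible attachment sites are the free B-groups of the core: one per linear
unit and ``brt`` per terminal unit (dendritic units and the root have none).
The number of arms is the graft ratio GRA times the number of eligible
sites (an alternative per-unit counting is available); arm lengths are
drawn from their own chain-length distribution; sites are sampled uniformly
without replacement.  Grafting never changes the core's D/L/T counts or DB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import DistributionSpec, sample_dps
from .errors import HyperbranchError, ValidationError
from .topology import CGTopology

__all__ = ["ArmSpec", "eligible_sites", "attach_arms"]


@dataclass(frozen=True)
class ArmSpec:
    """Arm generation parameters.

    ``gra`` — graft ratio: fraction of eligible sites carrying an arm.
    ``brt`` — allowed linking positions per terminal unit (1 or 2 in AB2
    chemistry).  ``arms`` — the arm-length distribution (ADPA/PDI_arm);
    its ``dp_min`` must be >= 1 so every drawn arm has at least one bead.
    ``per_unit`` switches GRA to count grafted *units* (linear + terminal)
    instead of sites, relevant only when brt = 2.
    """

    gra: float
    arms: DistributionSpec
    brt: int = 1
    per_unit: bool = False

    def __post_init__(self):
        if not 0.0 <= self.gra <= 1.0:
            raise ValidationError(f"gra must lie in [0, 1], got {self.gra}")
        if self.brt < 1 or self.brt > 2:
            raise ValidationError(f"brt must be 1 or 2 in AB2 chemistry, got {self.brt}")
        if self.arms.dp_min < 1:
            raise ValidationError("arm distribution must have dp_min >= 1")


def eligible_sites(core: CGTopology, brt: int) -> list[tuple[int, int]]:
    """All (node id, site index) pairs that may host an arm.

    Linear units contribute one site (their remaining B-group); terminal
    units contribute ``brt`` sites; dendritic units and the root contribute
    none.
    """
    if brt < 1:
        raise ValidationError(f"brt must be >= 1, got {brt}")
    core.classify()
    sites: list[tuple[int, int]] = []
    for n in core.nodes:
        if n.role == "linear":
            sites.append((n.id, 0))
        elif n.role == "terminal":
            sites.extend((n.id, s) for s in range(brt))
    return sites


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def attach_arms(core: CGTopology, spec: ArmSpec, rng: np.random.Generator) -> CGTopology:
    """Return a new topology with arms grafted onto a classified core.

    n_arms = round(GRA x number of eligible sites) (round half up); each arm
    is a simple path of arm-role beads rooted at its site.  GRA = 0 returns
    an unchanged copy of the core.
    """
    core.classify()
    new = core.copy()
    if spec.gra == 0.0:
        return new
    sites = eligible_sites(new, spec.brt)
    if spec.per_unit:
        n_units = len({nid for nid, _ in sites})
        n_arms = _round_half_up(spec.gra * n_units)
    else:
        n_arms = _round_half_up(spec.gra * len(sites))
    n_arms = min(n_arms, len(sites))
    if n_arms == 0:
        return new
    chosen = rng.choice(len(sites), size=n_arms, replace=False)
    lengths = sample_dps(spec.arms, rng, n_arms)
    for idx, length in zip(chosen, lengths):
        nid, _slot = sites[int(idx)]
        if int(length) < 1:  # dp_min >= 1 makes this unreachable
            raise HyperbranchError("drew a zero-length arm")
        at = nid
        for _ in range(int(length)):
            at = new.add_child(at, role="arm")
    return new
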