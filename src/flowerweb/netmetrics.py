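"""Network-level descriptors of quantitative bipartite webs."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .matrix import InteractionMatrix
from .species import dependencies, dprime

__all__ = [
    "NetworkMetrics",
    "web_asymmetry",
    "interaction_strength_asymmetry",
    "specialization_asymmetry",
    "interaction_shannon",
    "network_metrics",
]


def web_asymmetry(M: InteractionMatrix) -> float:
    """WBAS = (C - R)/(C + R): positive when the higher (visitor) guild is
    the richer one."""
    return (M.C - M.R) / (M.C + M.R)


def interaction_strength_asymmetry(M: InteractionMatrix) -> float:
    """ISA: mean over realised links of the normalised dependence asymmetry
    (visitor's dependence on the plant minus the plant's dependence on the
    visitor, scaled by the larger of the two).  Positive values mean the
    higher trophic level depends more on its partners than vice versa.

    Links are weighted equally, not by interaction frequency.
    """
    dep = dependencies(M)
    present = M.counts > 0
    bigger = np.maximum(dep.d_lower, dep.d_upper)
    with np.errstate(invalid="ignore", divide="ignore"):
        asym = np.where(present, (dep.d_upper - dep.d_lower) / bigger, 0.0)
    return float(asym.sum() / present.sum())


def specialization_asymmetry(M: InteractionMatrix) -> float:
    """SA: mean d' of the higher guild minus mean d' of the lower guild;
    negative values mean plants are the more specialized guild."""
    d_lo, d_hi = dprime(M)
    return float(d_hi.mean() - d_lo.mean())


def interaction_shannon(M: InteractionMatrix) -> float:
    """Shannon diversity of interactions: H = -sum p_ij ln p_ij over realised
    links, with p_ij the share of all visits made up by link (i, j)."""
    p = M.counts[M.counts > 0] / M.m
    return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class NetworkMetrics:
    habitat: str
    size: int
    R: int
    C: int
    m: int
    links: int
    WBAS: float
    ISA: float
    SA: float
    H_int: float

    def to_row(self) -> dict:
        return asdict(self)


def network_metrics(M: InteractionMatrix) -> NetworkMetrics:
    """All network-level descriptors of one web."""
    return NetworkMetrics(
        habitat=M.habitat or "",
        size=M.size,
        R=M.R,
        C=M.C,
        m=M.m,
        links=M.links,
        WBAS=web_asymmetry(M),
        ISA=interaction_strength_asymmetry(M),
        SA=specialization_asymmetry(M),
        H_int=interaction_shannon(M),
    )
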