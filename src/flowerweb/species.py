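"""Species-level network roles derived from dependencies.

The dependence of species *x* on partner *y* is the fraction of *x*'s total
interactions that involve *y*.  Both normalised views of a web (plant-wise
and visitor-wise) are held in :class:`DependencyTables`; species degree,
strength, interaction push/pull, d' specialization and the Gc core-periphery
score all derive from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import InteractionMatrix

__all__ = [
    "DependencyTables",
    "dependencies",
    "degree",
    "species_strength",
    "push_pull",
    "dprime",
    "core_periphery",
    "species_table",
]

GUILDS = ("lower", "higher")


@dataclass(frozen=True)
class DependencyTables:
    """The two row/column-normalised views of a quantitative web.

    ``d_lower[i, j]`` is plant *i*'s dependence on visitor *j* (rows sum
    to 1); ``d_upper[i, j]`` is visitor *j*'s dependence on plant *i*
    (columns sum to 1).  Zeros sit exactly where the web has no link.
    """

    d_lower: np.ndarray
    d_upper: np.ndarray


def dependencies(M: InteractionMatrix) -> DependencyTables:
    A = M.counts.astype(float)
    d_lower = A / A.sum(axis=1, keepdims=True)
    d_upper = A / A.sum(axis=0, keepdims=True)
    return DependencyTables(d_lower=d_lower, d_upper=d_upper)


def _series(values: np.ndarray, M: InteractionMatrix, guild: str, name: str) -> pd.Series:
    labels = M.row_labels if guild == "lower" else M.col_labels
    return pd.Series(values, index=list(labels), name=name)


def degree(M: InteractionMatrix) -> tuple[pd.Series, pd.Series]:
    """DEG: number of realised links per species, (plants, visitors)."""
    return (
        _series(M.row_degrees, M, "lower", "DEG"),
        _series(M.col_degrees, M, "higher", "DEG"),
    )


def species_strength(M: InteractionMatrix) -> tuple[pd.Series, pd.Series]:
    """ST: sum over a species' partners of the partners' dependence on it.

    Strengths are conserved: the visitor strengths sum to R (each plant
    contributes exactly one unit of dependence) and the plant strengths sum
    to C.
    """
    dep = dependencies(M)
    st_plants = dep.d_upper.sum(axis=1)
    st_visitors = dep.d_lower.sum(axis=0)
    return (
        _series(st_plants, M, "lower", "ST"),
        _series(st_visitors, M, "higher", "ST"),
    )


def push_pull(M: InteractionMatrix) -> tuple[pd.Series, pd.Series]:
    """IPP: mean normalised dependence asymmetry over a species' links.

    For each realised link the asymmetry (partner's dependence on the focal
    species minus the focal species' dependence on the partner) is scaled by
    the larger of the two, giving a value in [-1, 1]; a species' IPP is the
    mean over its links.  Positive = "pusher" (affects its partners more
    than it is affected), negative = "being pulled".
    """
    dep = dependencies(M)
    present = M.counts > 0
    bigger = np.maximum(dep.d_lower, dep.d_upper)
    with np.errstate(invalid="ignore", divide="ignore"):
        # asymmetry from the visitor's point of view: how much the plant
        # depends on the visitor minus how much the visitor depends on the plant
        asym_visitor = np.where(present, (dep.d_lower - dep.d_upper) / bigger, 0.0)
    ipp_visitors = asym_visitor.sum(axis=0) / present.sum(axis=0)
    ipp_plants = (-asym_visitor).sum(axis=1) / present.sum(axis=1)
    return (
        _series(ipp_plants, M, "lower", "IPP"),
        _series(ipp_visitors, M, "higher", "IPP"),
    )


def _dprime_one_guild(use: np.ndarray, avail: np.ndarray, totals: np.ndarray, m: int) -> np.ndarray:
    """Standardised Kullback-Leibler specialization for one guild.

    ``use``: partner-use distributions, one species per row, rows sum to 1.
    ``avail``: partner availability (marginal totals / m).  Raw
    d = KL(use || avail); d' = d / ln(m / A_s) with A_s the species' own
    marginal total (d_min = 0, the proportional-use optimum of the
    continuous relaxation), clamped to [0, 1].
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(use > 0, use * np.log(use / avail[None, :]), 0.0)
    d_raw = terms.sum(axis=1)
    d_max = np.log(m / totals.astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        d_std = np.where(d_max > 0, d_raw / d_max, 0.0)
    return np.clip(d_std, 0.0, 1.0)


def dprime(M: InteractionMatrix) -> tuple[pd.Series, pd.Series]:
    """d': discrimination of a species' partner use from partner availability."""
    dep = dependencies(M)
    m = M.m
    row_tot = M.counts.sum(axis=1)
    col_tot = M.counts.sum(axis=0)
    avail_visitors = col_tot / m  # availability seen by plants
    avail_plants = row_tot / m  # availability seen by visitors
    d_plants = _dprime_one_guild(dep.d_lower, avail_visitors, row_tot, m)
    d_visitors = _dprime_one_guild(dep.d_upper.T, avail_plants, col_tot, m)
    return (
        _series(d_plants, M, "lower", "dprime"),
        _series(d_visitors, M, "higher", "dprime"),
    )


def core_periphery(M: InteractionMatrix, guild: str) -> pd.DataFrame:
    """Gc core-periphery classification within one guild.

    Gc = (k - mean k) / sd k with k the within-guild degrees and the sample
    (n-1) standard deviation; species with Gc > 1 are core.  A guild with
    no degree variation has Gc = 0 everywhere and no core species.
    """
    if guild not in GUILDS:
        raise ValueError(f"guild must be one of {GUILDS}")
    k = (M.row_degrees if guild == "lower" else M.col_degrees).astype(float)
    if k.size < 2:
        raise ValueError("guild needs at least two species")
    sd = k.std(ddof=1)
    gc = (k - k.mean()) / sd if sd > 0 else np.zeros_like(k)
    out = pd.DataFrame(
        {"Gc": gc, "core": gc > 1},
        index=list(M.row_labels if guild == "lower" else M.col_labels),
    )
    return out


def species_table(M: InteractionMatrix) -> pd.DataFrame:
    """Per-species metrics table: guild, DEG, ST, IPP, d', Gc, core flag."""
    deg_lo, deg_hi = degree(M)
    st_lo, st_hi = species_strength(M)
    ipp_lo, ipp_hi = push_pull(M)
    dp_lo, dp_hi = dprime(M)
    cp_lo = core_periphery(M, "lower")
    cp_hi = core_periphery(M, "higher")
    rows = []
    for guild, deg, st, ipp, dp, cp in (
        ("lower", deg_lo, st_lo, ipp_lo, dp_lo, cp_lo),
        ("higher", deg_hi, st_hi, ipp_hi, dp_hi, cp_hi),
    ):
        part = pd.DataFrame(
            {
                "guild": guild,
                "species": deg.index,
                "DEG": deg.values,
                "ST": st.values,
                "IPP": ipp.values,
                "dprime": dp.values,
                "Gc": cp["Gc"].values,
                "core": cp["core"].values,
            }
        )
        rows.append(part)
    return pd.concat(rows, ignore_index=True)
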