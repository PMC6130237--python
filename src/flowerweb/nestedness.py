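"""NODF nestedness and Monte-Carlo significance under the Ce null model.

NODF scores, for every pair of rows (and of columns) with strictly
decreasing marginal totals, the percentage of the poorer species' partners
shared with the richer one; ties and empty lines contribute zero.  The Ce
null model fills each cell independently with probability equal to the mean
of its row's and its column's fill proportions, preserving the expected
degree structure of both guilds while randomising identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import InteractionMatrix, binarize

__all__ = ["NestednessResult", "nodf", "null_model_ce", "nestedness_test"]


def _nodf_axis_sum(B: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap scores over all row pairs, plus pair count.

    For rows u, v with marginal totals MT_u > MT_v > 0 the score is
    100 * |shared partners| / MT_v; equal totals or an empty poorer row
    score 0 (the strict decreasing-fill rule).
    """
    mt = B.sum(axis=1)
    overlap = (B @ B.T).astype(float)
    n = B.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mt_u, mt_v = mt[iu], mt[ju]
    lo = np.minimum(mt_u, mt_v)
    valid = (mt_u != mt_v) & (lo > 0)
    scores = np.where(valid, 100.0 * overlap[iu, ju] / np.where(lo > 0, lo, 1), 0.0)
    return float(scores.sum()), n * (n - 1) // 2


def nodf(B: np.ndarray | InteractionMatrix) -> tuple[float, float, float]:
    """(NODF_rows, NODF_cols, NODF_total) of a binary incidence matrix, each
    on the 0-100 scale.  Quantitative webs are binarized first."""
    B = binarize(B)
    if B.shape[0] < 2 or B.shape[1] < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    row_sum, n_row_pairs = _nodf_axis_sum(B)
    col_sum, n_col_pairs = _nodf_axis_sum(B.T)
    return (
        row_sum / n_row_pairs,
        col_sum / n_col_pairs,
        (row_sum + col_sum) / (n_row_pairs + n_col_pairs),
    )


def ce_probabilities(B: np.ndarray | InteractionMatrix) -> np.ndarray:
    """Cell occupancy probabilities of the Ce null model:
    p_ij = (d_i / C + d_j / R) / 2 from the observed row/column degrees."""
    B = binarize(B)
    R, C = B.shape
    d_i = B.sum(axis=1) / C
    d_j = B.sum(axis=0) / R
    return (d_i[:, None] + d_j[None, :]) / 2.0


def null_model_ce(
    M: np.ndarray | InteractionMatrix, rng: np.random.Generator
) -> np.ndarray:
    """One Ce draw: independent Bernoulli cells at ``ce_probabilities``.

    Dimensions are preserved; rows or columns that come out empty are kept
    as generated (their NODF pairs simply score zero), so the null
    distribution is not conditioned on connectivity.
    """
    p = ce_probabilities(M)
    return (rng.random(p.shape) < p).astype(np.int64)


@dataclass(frozen=True)
class NestednessResult:
    habitat: str
    NODF_rows: float
    NODF_cols: float
    NODF_total: float
    null_mean: float
    null_sd: float
    p_value: float
    n_null: int
    seed: int | None

    @property
    def nested(self) -> bool:
        return self.p_value < 0.01


def nestedness_test(
    M: InteractionMatrix | np.ndarray,
    n_null: int = 1000,
    seed: int | None = 0,
) -> NestednessResult:
    """Upper-tail Monte-Carlo test of NODF_total against the Ce null model.

    p = (1 + #{null >= observed}) / (n_null + 1), the add-one convention,
    so p is never exactly zero and is bit-reproducible for a given seed.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    B = binarize(M)
    nrows, ncols, obs = nodf(B)
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_null)
    for k in range(n_null):
        null_vals[k] = nodf(null_model_ce(B, rng))[2]
    exceed = int(np.sum(null_vals >= obs))
    habitat = M.habitat or "" if isinstance(M, InteractionMatrix) else ""
    return NestednessResult(
        habitat=habitat,
        NODF_rows=nrows,
        NODF_cols=ncols,
        NODF_total=obs,
        null_mean=float(null_vals.mean()),
        null_sd=float(null_vals.std(ddof=1)) if n_null > 1 else 0.0,
        p_value=(1 + exceed) / (n_null + 1),
        n_null=n_null,
        seed=seed,
    )
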