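"""Modified leave-one-out nearest-neighbour identification.

Each sequence is queried against the library with self-matches excluded,
plus every candidate within a divergence radius (``exclusion_div``) of the
query — 2%, 5% or 10% depending on the coverage level of the dataset —
so a query can never be identified by its own BIN or divergence cluster.
Candidates lacking a family label or overlapping the query over fewer
than ``min_overlap_frac`` of its non-gap sites are also ineligible.  The
top hit is the eligible candidate with the highest percent similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, distance_matrix, similarity
from .io import ReferenceLibrary


@dataclass(frozen=True)
class LOOConfig:
    """Eligibility rules for the modified leave-one-out search."""

    exclusion_div: float = 0.02
    min_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.exclusion_div < 1.0:
            raise ValueError("exclusion_div must be in [0, 1)")
        if not 0.0 < self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must be in (0, 1]")


@dataclass
class IdentificationResult:
    """Top hit and correctness of one query at order and family rank.

    ``hit_id`` is None (and similarity NaN) when no candidate is eligible;
    such queries are "unassignable" and excluded from calibration
    denominators but reported separately.
    """

    query_id: str
    hit_id: str | None
    similarity: float
    overlap_bp: int
    predicted_order: str | None
    predicted_family: str | None
    true_order: str
    true_family: str
    correct_order: bool | None
    correct_family: bool | None


def _eligible_mask(
    i: int,
    D: DistanceMatrix,
    families: np.ndarray,
    query_len: int,
    config: LOOConfig,
) -> np.ndarray:
    d = D.d[i]
    with np.errstate(invalid="ignore"):
        mask = d > config.exclusion_div  # NaN compares False -> ineligible
    mask &= families != ""
    mask &= D.overlap[i] >= config.min_overlap_frac * query_len
    mask[i] = False
    return mask


def top_hit(
    query_id: str,
    lib: ReferenceLibrary,
    D: DistanceMatrix,
    config: LOOConfig,
) -> IdentificationResult:
    """Identify one query against the library under the exclusion rules."""
    by_id = {r.id: r for r in lib.records}
    query = by_id[query_id]
    i = D.index(query_id)
    families = np.array([by_id[rid].family for rid in D.ids], dtype=object)
    mask = _eligible_mask(i, D, families, query.effective_length, config)
    if not mask.any():
        return IdentificationResult(
            query_id, None, math.nan, 0, None, None,
            query.order, query.family, None, None,
        )
    d_row = np.where(mask, D.d[i], np.inf)
    dmin = d_row.min()
    ties = np.flatnonzero(d_row == dmin)
    j = min(ties, key=lambda k: D.ids[k])  # smallest id wins ties
    hit = by_id[D.ids[j]]
    return IdentificationResult(
        query_id,
        hit.id,
        similarity(float(D.d[i, j])),
        int(D.overlap[i, j]),
        hit.order,
        hit.family,
        query.order,
        query.family,
        hit.order == query.order,
        hit.family == query.family,
    )


def loo_identify(
    lib: ReferenceLibrary,
    config: LOOConfig = LOOConfig(),
    D: DistanceMatrix | None = None,
) -> list[IdentificationResult]:
    """Query every library sequence against the library (modified LOO)."""
    if len(lib) < 2:
        raise ValueError("library must contain at least 2 records")
    if D is None:
        D = distance_matrix(lib)
    elif D.ids != lib.ids:
        raise ValueError("distance matrix does not match library")
    return [top_hit(r.id, lib, D, config) for r in lib.records]


def results_to_frame(results: list[IdentificationResult]) -> pd.DataFrame:
    """One row per query with all identification fields."""
    return pd.DataFrame(
        [
            (
                r.query_id, r.hit_id, r.similarity, r.overlap_bp,
                r.predicted_order, r.predicted_family,
                r.true_order, r.true_family,
                r.correct_order, r.correct_family,
            )
            for r in results
        ],
        columns=[
            "query_id", "hit_id", "similarity", "overlap_bp",
            "predicted_order", "predicted_family",
            "true_order", "true_family",
            "correct_order", "correct_family",
        ],
    )


def summarize_success(results: list[IdentificationResult] | pd.DataFrame,
                      by: str = "all") -> pd.DataFrame:
    """Percent of queries with a hit that were assigned the correct order
    and family, overall (``by='all'``) or per true order (``by='order'``).
    Unassignable queries are counted separately, never in the denominator."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise ValueError("no identification results")

    def _row(group: str, sub: pd.DataFrame) -> dict:
        hits = sub[sub["hit_id"].notna()]
        n = len(hits)
        return {
            "group": group,
            "n_queries": len(sub),
            "n_with_hit": n,
            "n_unassignable": len(sub) - n,
            "pct_correct_order": 100.0 * hits["correct_order"].sum() / n if n else math.nan,
            "pct_correct_family": 100.0 * hits["correct_family"].sum() / n if n else math.nan,
        }

    if by == "all":
        rows = [_row("all", df)]
    elif by == "order":
        rows = [_row(o, sub) for o, sub in df.groupby("true_order", sort=True)]
    else:
        raise ValueError("by must be 'all' or 'order'")
    return pd.DataFrame(rows)
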