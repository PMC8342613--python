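"""Intra-/inter-taxon divergence summaries, barcode-gap evaluation and
divergence-vs-richness regression.

For every taxon at a rank the maximum within-taxon and minimum
between-taxon p-distances are extracted from the distance matrix
(monotypic taxa lack an intra value).  A family shows a *barcode gap*
when its maximum internal divergence is strictly smaller than the
distance to its nearest neighbour.  The relationship between a family's
maximum internal divergence and its BIN count is modelled with linear,
logarithmic and asymptotic regressions; substitution saturation makes
the asymptotic form ``y = A + (y0 - A) * exp(-k * x)`` the expected
winner on real barcode data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .distances import DistanceMatrix
from .io import ReferenceLibrary


def taxon_divergences(
    D: DistanceMatrix, lib: ReferenceLibrary, rank: str
) -> pd.DataFrame:
    """Per-taxon max intra- and min inter-taxon p-distance.

    Columns: taxon, rank, n_members, max_intra (NaN for monotypic taxa),
    min_inter (NaN when the rank has a single taxon).
    """
    if rank not in ("order", "family"):
        raise ValueError("rank must be 'order' or 'family'")
    if D.ids != lib.ids:
        raise ValueError("distance matrix does not match library")
    labels = np.array([getattr(r, rank) for r in lib.records], dtype=object)
    taxa = sorted(set(labels))
    rows = []
    for taxon in taxa:
        inside = labels == taxon
        outside = ~inside
        n = int(inside.sum())
        if n > 1:
            block = D.d[np.ix_(inside, inside)]
            off = ~np.eye(n, dtype=bool)
            vals = block[off]
            max_intra = float(np.nanmax(vals)) if not np.isnan(vals).all() else math.nan
        else:
            max_intra = math.nan
        if outside.any():
            cross = D.d[np.ix_(inside, outside)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                min_inter = float(np.nanmin(cross))
        else:
            min_inter = math.nan
        rows.append((taxon, rank, n, max_intra, min_inter))
    return pd.DataFrame(
        rows, columns=["taxon", "rank", "n_members", "max_intra", "min_inter"]
    )


def barcode_gap_table(divs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Flag ``gap_present = (max_intra < min_inter)`` per family.

    Monotypic families (no max_intra) are excluded from the flag and
    counted separately; equality counts as no gap (strict <).
    Returns the augmented table and summary counts.
    """
    table = divs.copy()
    monotypic = table["max_intra"].isna()
    gap = pd.array([pd.NA] * len(table), dtype="boolean")
    defined = ~monotypic & table["min_inter"].notna()
    gap[defined] = (
        table.loc[defined, "max_intra"] < table.loc[defined, "min_inter"]
    ).to_numpy()
    table["gap_present"] = gap
    summary = {
        "n_gap": int((table["gap_present"] == True).sum()),  # noqa: E712
        "n_no_gap": int((table["gap_present"] == False).sum()),  # noqa: E712
        "n_monotypic": int(monotypic.sum()),
    }
    return table, summary


@dataclass
class RegressionFit:
    """One fitted model of max intra-taxon divergence vs member count."""

    model: str  # linear | logarithmic | asymptotic
    params: dict = field(default_factory=dict)
    aic: float = math.nan
    rse: float = math.nan
    half_asymptote_x: float = math.nan
    converged: bool = True
    n: int = 0


def _gaussian_aic(rss: float, n: int, n_params: int) -> float:
    return n * math.log(rss / n) + 2 * n_params


def _asymptotic(x, a, y0, k):
    return a + (y0 - a) * np.exp(-k * x)


def fit_divergence_vs_richness(divs: pd.DataFrame) -> list[RegressionFit]:
    """Fit linear, logarithmic and asymptotic models of ``max_intra`` on
    ``n_members`` by least squares; sorted by AIC (converged fits first).

    The asymptotic model ``y = A + (y0 - A) exp(-k x)`` is fitted by
    non-linear least squares with a small multi-start over the rate k;
    ``half_asymptote_x`` is the member count at which the fitted curve
    reaches half the asymptote A.
    """
    data = divs.dropna(subset=["max_intra"])
    x = data["n_members"].to_numpy(dtype=float)
    y = data["max_intra"].to_numpy(dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 non-monotypic taxa, got {n}")

    fits: list[RegressionFit] = []

    for name, design in (("linear", x), ("logarithmic", np.log(x))):
        if np.ptp(design) == 0:  # constant regressor: slope unidentifiable
            fits.append(RegressionFit(model=name, converged=False, n=n))
            continue
        X = sm.add_constant(design)
        res = sm.OLS(y, X).fit()
        rss = float(res.ssr)
        fits.append(
            RegressionFit(
                model=name,
                params={"intercept": float(res.params[0]), "slope": float(res.params[1])},
                aic=_gaussian_aic(rss, n, 2),
                rse=math.sqrt(rss / (n - 2)),
                n=n,
            )
        )

    best = None
    for k0 in (0.01, 0.05, 0.1, 0.3, 1.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _asymptotic,
                    x,
                    y,
                    p0=(float(y.max()), float(y[np.argmin(x)]), k0),
                    bounds=([0.0, -1.0, 1e-6], [1.5, 1.5, 50.0]),
                    maxfev=20000,
                )
            rss = float(((y - _asymptotic(x, *popt)) ** 2).sum())
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        fits.append(RegressionFit(model="asymptotic", converged=False, n=n))
    else:
        (a, y0, k), rss = best
        half_x = math.nan
        if a > 0 and a > y0 and k > 0 and a - a / 2 > 0 and a - y0 > 0:
            half_x = math.log((a - y0) / (a / 2)) / k
        fits.append(
            RegressionFit(
                model="asymptotic",
                params={"asymptote": float(a), "y0": float(y0), "rate": float(k)},
                aic=_gaussian_aic(rss, n, 3),
                rse=math.sqrt(rss / (n - 3)),
                half_asymptote_x=half_x,
                n=n,
            )
        )
    return sorted(fits, key=lambda f: (not f.converged, f.aic))


def flag_outliers(values) -> np.ndarray:
    """Boxplot-rule outliers: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (numpy's default, R type 7).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def regression_summary(fits: list[RegressionFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model,
                "converged": f.converged,
                "aic": f.aic,
                "rse": f.rse,
                "half_asymptote_x": f.half_asymptote_x,
                "n": f.n,
                **{f"param_{k}": v for k, v in f.params.items()},
            }
        )
    return pd.DataFrame(rows)
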