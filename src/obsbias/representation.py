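"""Order-level representation relative to species richness.

If observers sampled mammal orders in proportion to how many species each
order contains, an order with share ``S_i / sum(S)`` of global richness
would hold the same share of observations. The functions here compute those
richness-proportional expectations, classify orders as over- or
underrepresented, test the global fit with a chi-square statistic, rank-
correlate richness with observation totals (Spearman), and summarize
per-species observation intensity by group (e.g. marine vs terrestrial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import warnings

from scipy import stats

__all__ = [
    "OrderRepresentation",
    "RankCorrelation",
    "expected_by_richness",
    "gof_chi_square",
    "spearman_rank",
    "group_mean_obs",
]


@dataclass
class OrderRepresentation:
    order_name: str
    richness: int
    observed: int
    expected: float
    ratio: float
    residual: float  # standardized residual (O - E) / sqrt(E)
    status: str  # over | under | proportional


@dataclass
class RankCorrelation:
    rho: float
    s_stat: float
    p_value: float
    n: int


def expected_by_richness(orders: Mapping[str, tuple[int, int]]) -> list[OrderRepresentation]:
    """Richness-proportional expected observation counts per order.

    Parameters
    ----------
    orders
        Mapping order name -> (richness S_i, observed count O_i).

    The expectation is ``E_i = (sum O) * S_i / (sum S)``, so expected totals
    are conserved. Status is a strict inequality on E_i; ``proportional``
    only when O_i equals E_i exactly. Standardized residuals
    ``(O - E)/sqrt(E)`` are reported so callers can impose their own
    significance gate.
    """
    if not orders:
        raise ValueError("expected_by_richness requires at least one order")
    names = list(orders)
    s = np.array([orders[k][0] for k in names], dtype=float)
    o = np.array([orders[k][1] for k in names], dtype=float)
    if s.sum() <= 0:
        raise ValueError("total richness must be positive")
    e = o.sum() * s / s.sum()
    out = []
    for name, s_i, o_i, e_i in zip(names, s, o, e):
        status = "over" if o_i > e_i else ("under" if o_i < e_i else "proportional")
        out.append(
            OrderRepresentation(
                order_name=name,
                richness=int(s_i),
                observed=int(o_i),
                expected=float(e_i),
                ratio=float(o_i / e_i) if e_i > 0 else float("nan"),
                residual=float((o_i - e_i) / np.sqrt(e_i)) if e_i > 0 else float("nan"),
                status=status,
            )
        )
    return out


def gof_chi_square(reps: Iterable[OrderRepresentation]) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of observed vs richness-expected counts."""
    reps = list(reps)
    if not reps:
        raise ValueError("no orders supplied")
    e = np.array([r.expected for r in reps])
    o = np.array([r.observed for r in reps], dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    chi2 = float(np.sum((o - e) ** 2 / e))
    df = len(reps) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def spearman_rank(x, y) -> RankCorrelation:
    """Spearman rank correlation with the t-approximation p-value.

    Ties receive average ranks. ``s_stat`` is the sum of squared rank
    differences (for tie-free data ``rho = 1 - 6 S / (n^3 - n)``); the
    p-value uses ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 df, matching
    the usual large-sample treatment when ties are present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    s_stat = float(np.sum((rx - ry) ** 2))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return RankCorrelation(rho=rho, s_stat=s_stat, p_value=p, n=n)


def group_mean_obs(
    profiles,
    grouping: Callable[[object], str],
) -> dict[str, dict[str, float]]:
    """Mean per-species observation count within groups.

    ``grouping`` assigns each profile to exactly one group label. Returns
    ``{group: {"mean_n_obs": ..., "n_species": ..., "total_obs": ...}}``;
    empty groups are simply absent (a warning is emitted if the grouping
    yields none at all).
    """
    sums: dict[str, list[float]] = {}
    for p in profiles:
        g = grouping(p)
        sums.setdefault(g, []).append(p.n_obs)
    if not sums:
        warnings.warn("grouping produced no groups", stacklevel=2)
    return {
        g: {
            "mean_n_obs": float(np.mean(v)),
            "n_species": len(v),
            "total_obs": float(np.sum(v)),
        }
        for g, v in sums.items()
    }
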