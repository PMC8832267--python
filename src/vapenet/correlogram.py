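"""Pairwise Pearson correlation between items' co-retrieval profiles.

Each item is represented by its row of the shared-video-count adjacency
matrix (diagonal zeroed); r(i, j) is the Pearson correlation between rows i
and j over all n positions, so items whose overlap patterns rise and fall
together correlate positively.  Two-sided p-values come from the exact-null
t transform t = r * sqrt((m - 2) / (1 - r^2)) with m observations; no
multiple-testing correction is applied by default (Benjamini-Hochberg is
available as an option).  A zero-variance row has undefined correlations,
reported as missing (NaN) rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import ItemNetwork
from .util import DegenerateInputError, round_half_up


@dataclass
class CorrelationMatrix:
    items: list[str]
    r: np.ndarray  # symmetric, diagonal 1, NaN where undefined
    p: np.ndarray  # symmetric two-sided p-values, NaN where undefined
    significant: np.ndarray  # boolean, p <= alpha (False where NaN)
    alpha: float = 0.05


def _pair_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    m = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        return np.nan, np.nan
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if m < 3:
        return r, np.nan
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=m - 2)
    return r, float(p)


def correlate_items(
    net: ItemNetwork,
    alpha: float = 0.05,
    exclude_mutual: bool = False,
    correction: str | None = None,
) -> CorrelationMatrix:
    """Correlation matrix over adjacency rows.

    ``exclude_mutual`` drops the two positions i and j from each pair's
    vectors (m = n - 2 observations) as a sensitivity option; the default
    uses all n positions.  ``correction='bh'`` applies Benjamini-Hochberg to
    the upper-triangle p-values before thresholding at alpha.
    """
    n = len(net.items)
    if n < 3:
        raise DegenerateInputError("a correlogram needs at least 3 items")
    A = net.adjacency_matrix()
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if exclude_mutual:
                keep = [k for k in range(n) if k not in (i, j)]
                x, y = A[i, keep], A[j, keep]
            else:
                x, y = A[i], A[j]
            r[i, j], p[i, j] = _pair_r_p(x, y)
            r[j, i], p[j, i] = r[i, j], p[i, j]
    if correction == "bh":
        iu = np.triu_indices(n, k=1)
        raw = p[iu]
        ok = ~np.isnan(raw)
        adjusted = raw.copy()
        adjusted[ok] = stats.false_discovery_control(raw[ok], method="bh")
        p = p.copy()
        p[iu] = adjusted
        p.T[iu] = adjusted
    elif correction is not None:
        raise DegenerateInputError(f"unknown correction {correction!r}")
    with np.errstate(invalid="ignore"):
        significant = (p <= alpha) & ~np.isnan(p)
    np.fill_diagonal(significant, False)
    return CorrelationMatrix(items=list(net.items), r=r, p=p, significant=significant, alpha=alpha)


def render_correlogram_data(cm: CorrelationMatrix) -> pd.DataFrame:
    """Long-format table for heat-map plotting: one row per unordered pair,
    r reported to 2 decimals (round-half-up, e.g. 0.745 -> 0.75)."""
    rows = []
    n = len(cm.items)
    for i in range(n):
        for j in range(i + 1, n):
            r = cm.r[i, j]
            rows.append(
                {
                    "item_i": cm.items[i],
                    "item_j": cm.items[j],
                    "r": round_half_up(float(r), 2) if not np.isnan(r) else np.nan,
                    "p": cm.p[i, j],
                    "significant": bool(cm.significant[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["item_i", "item_j", "r", "p", "significant"])


def write_matrix_csv(cm: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.r, index=cm.items, columns=cm.items).to_csv(path)
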