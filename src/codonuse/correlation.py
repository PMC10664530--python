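"""Spearman rank-correlation matrices over the per-sequence indices.

Codon-usage studies summarize the dependence structure among composition and
usage indices with a Spearman matrix per species group and a significance
star per pair (* p<0.05, ** p<0.01, *** p<0.001). Groups are small (often
4-9 genes), where the t approximation to the Spearman null is poor, so exact
permutation p-values are used up to n = 9 and the t approximation beyond.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

#: Column order of the correlation analysis (the 12 per-sequence quantities).
CORRELATION_VARIABLES = (
    "GC1", "GC2", "GC3", "GCs", "CAI", "CBI", "FOP", "ENC",
    "GRAVY", "AROMO", "L_sym", "L_aa",
)

EXACT_P_MAX_N = 9
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric rho and p matrices with star annotations."""

    group: str
    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int

    def long_format(self) -> pd.DataFrame:
        """One row per unordered variable pair: (var1, var2, rho, p, stars)."""
        rows = []
        cols = list(self.rho.columns)
        for i, v1 in enumerate(cols):
            for v2 in cols[i + 1 :]:
                rows.append(
                    {
                        "group": self.group,
                        "var1": v1,
                        "var2": v2,
                        "rho": self.rho.loc[v1, v2],
                        "p": self.p.loc[v1, v2],
                        "stars": self.stars.loc[v1, v2],
                    }
                )
        return pd.DataFrame(rows)


@lru_cache(maxsize=None)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray) -> float:
    """Two-sided exact permutation p for the Spearman statistic.

    Enumerates all pairings of the (tie-averaged) rank vectors; the
    statistic is the Pearson correlation of ranks, so ties are handled
    exactly rather than through the classical no-ties null table.
    """
    n = len(x_rank)
    perms = _permutation_matrix(n)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    null = (xc[perms] @ yc) / denom
    observed = float(xc @ yc / denom)
    # small epsilon guards against >=' failing on floating-point ties
    return float(np.mean(np.abs(null) >= abs(observed) - 1e-12))


def spearman_pair(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p for one pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_rank = stats.rankdata(x)
    y_rank = stats.rankdata(y)
    rho = float(stats.pearsonr(x_rank, y_rank)[0]) if np.ptp(x_rank) and np.ptp(y_rank) else float("nan")
    if np.isnan(rho):
        return rho, float("nan")
    if len(x) <= EXACT_P_MAX_N:
        p = _exact_spearman_p(x_rank, y_rank)
    else:
        p = float(stats.spearmanr(x, y)[1])
    return rho, p


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


def spearman_matrix(
    table: pd.DataFrame,
    group: str = "all",
    variables: tuple[str, ...] = CORRELATION_VARIABLES,
) -> CorrelationMatrix:
    """Pairwise Spearman matrix over ``variables`` of ``table``.

    Requires at least 4 rows. Constant columns yield NaN rho/p (reported
    blank downstream) rather than an error, since a small group can easily
    tie every value of an integer index.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"missing variables {missing}")
    n = len(table)
    if n < 4:
        raise InsufficientDataError(f"group {group}: {n} rows < 4")
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, pv = spearman_pair(
                table[variables[i]].to_numpy(), table[variables[j]].to_numpy()
            )
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    rho_df = pd.DataFrame(rho, index=list(variables), columns=list(variables))
    p_df = pd.DataFrame(p, index=list(variables), columns=list(variables))
    stars_df = p_df.map(_stars)
    np.fill_diagonal(stars_df.values, "")
    return CorrelationMatrix(group=group, rho=rho_df, p=p_df, stars=stars_df, n=n)


def spearman_by_group(
    table: pd.DataFrame,
    groups: pd.Series,
    variables: tuple[str, ...] = CORRELATION_VARIABLES,
    min_n: int = 4,
) -> dict[str, CorrelationMatrix]:
    """One correlation matrix per species group; undersized groups skipped."""
    out = {}
    for group, idx in groups.groupby(groups).groups.items():
        sub = table.loc[idx]
        if len(sub) >= min_n:
            out[str(group)] = spearman_matrix(sub, group=str(group), variables=variables)
    return out
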