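"""Mutation-pressure vs natural-selection diagnostics.

Three classic graphical tests are provided in numeric form:

* **Neutrality plot** — ordinary least squares of GC12 on GC3 across the
  sequences of a group. A slope near 1 means the first two codon positions
  track the third (directional mutation pressure dominates); a slope near 0
  means GC12 is held in place while GC3 drifts (selection on the protein
  dominates). A Spearman rank test accompanies the fit.
* **PR2 bias** — within-sequence parity of the third position,
  A3/(A3+T3) against G3/(G3+C3); (0.5, 0.5) is the no-bias centre expected
  under strand-symmetric mutation with no selection.
* **ENC-GC3** — observed ENC against Wright's null expectation
  ENC = 2 + s + 29/(s^2 + (1-s)^2) for third-position G+C fraction s;
  points below the curve indicate codon choice beyond GC pressure alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import PositionComposition
from .genetic_code import DegenerateInputError


class InsufficientDataError(ValueError):
    """Too few points for a regression or correlation."""


@dataclass(frozen=True)
class NeutralityResult:
    """Per-group GC12-on-GC3 regression summary."""

    group: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float
    p_value: float
    ols_p_value: float

    def as_dict(self) -> dict[str, float]:
        return {
            "group": self.group,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "spearman_rho": self.spearman_rho,
            "p_value": self.p_value,
            "ols_p_value": self.ols_p_value,
        }


@dataclass(frozen=True)
class PR2Point:
    """Third-position parity coordinates; (0.5, 0.5) is the neutral centre."""

    at_bias: float
    gc_bias: float

    @property
    def quadrant(self) -> str:
        ns = "A>T" if self.at_bias > 0.5 else ("T>A" if self.at_bias < 0.5 else "A=T")
        ew = "G>C" if self.gc_bias > 0.5 else ("C>G" if self.gc_bias < 0.5 else "G=C")
        return f"{ns},{ew}"


def neutrality_regression(
    gc12: np.ndarray | list[float],
    gc3: np.ndarray | list[float],
    group: str = "all",
) -> NeutralityResult:
    """OLS of GC12 (response) on GC3 (predictor) plus Spearman rank test.

    The reported ``p_value`` is the two-sided Spearman p (the convention of
    neutrality-plot analyses); the OLS slope p is also returned.
    """
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    if gc12.shape != gc3.shape or gc12.ndim != 1:
        raise ValueError("gc12 and gc3 must be 1-D arrays of equal length")
    if len(gc12) < 3:
        raise InsufficientDataError(f"group {group}: need >= 3 points")
    if np.ptp(gc3) == 0:
        raise DegenerateInputError(f"group {group}: zero GC3 variance")
    ols = stats.linregress(gc3, gc12)
    rho, sp_p = stats.spearmanr(gc3, gc12)
    return NeutralityResult(
        group=group,
        n=len(gc12),
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        r_squared=float(ols.rvalue**2),
        spearman_rho=float(rho),
        p_value=float(sp_p),
        ols_p_value=float(ols.pvalue),
    )


def neutrality_by_group(
    comp: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Neutrality regression per species group from a composition table."""
    rows = []
    for group, idx in groups.groupby(groups).groups.items():
        sub = comp.loc[idx]
        rows.append(
            neutrality_regression(
                sub["GC12"].to_numpy(), sub["GC3"].to_numpy(), group=str(group)
            ).as_dict()
        )
    return pd.DataFrame(rows).set_index("group").sort_index()


def pr2_coordinates(comp: PositionComposition) -> PR2Point:
    """Parity-rule-2 coordinates from third-position composition."""
    at = comp.A3 + comp.T3
    gc = comp.G3 + comp.C3
    if at == 0 or gc == 0:
        raise DegenerateInputError(
            "PR2 undefined: a third-position base pair is absent"
        )
    return PR2Point(at_bias=comp.A3 / at, gc_bias=comp.G3 / gc)


def enc_expected(gc3: float) -> float:
    """Wright's null ENC at third-position G+C fraction ``gc3`` in [0, 1]."""
    s = float(gc3)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"gc3 fraction {s} outside [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_deviation(observed_enc: float, gc3: float) -> float:
    """Relative shortfall of observed ENC below the null curve.

    Positive values place the gene below the curve (selection signature);
    zero means the gene sits exactly on it.
    """
    expected = enc_expected(gc3)
    return (expected - observed_enc) / expected


def pr2_table(comp: pd.DataFrame) -> pd.DataFrame:
    """Per-sequence PR2 coordinates and quadrant from a composition table."""
    rows = {}
    for sid, row in comp.iterrows():
        point = pr2_coordinates(
            PositionComposition(**{c: row[c] for c in comp.columns})
        )
        rows[sid] = {
            "at_bias": point.at_bias,
            "gc_bias": point.gc_bias,
            "quadrant": point.quadrant,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def enc_gc3_table(
    enc_values: pd.Series, gc3_percent: pd.Series
) -> pd.DataFrame:
    """Observed ENC vs the null curve; ``gc3_percent`` on the 0-100 scale."""
    out = pd.DataFrame({"ENC": enc_values, "GC3": gc3_percent})
    out["expected_ENC"] = [enc_expected(g / 100.0) for g in out["GC3"]]
    out["deviation"] = (out["expected_ENC"] - out["ENC"]) / out["expected_ENC"]
    return out
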