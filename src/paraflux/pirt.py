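"""Chemostat physiology: Pirt's linear partition of substrate uptake.

Pirt's equation, q_s = m_s + mu / Y^max, splits the specific substrate
consumption rate q_s (mmol g-DW^-1 h^-1) into a growth-independent
maintenance term m_s and a growth-proportional term whose slope is the
reciprocal maximal yield.  With Y^max in g-DW mol^-1 and q_s in mmol, the
slope of q_s on mu is 1000 / Y^max.

Fitting is ordinary least squares of q_s on mu — the chemostat literature
reports no per-point error model, so residuals are treated as
equal-variance.  Standard errors come from the residual variance and
require at least three points.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .constants import MMOL_PER_MOL
from .errors import FittingError


@dataclass(frozen=True)
class ChemostatPoint:
    """One steady state: dilution rate mu (h^-1) and the specific substrate
    consumption q_s (mmol g-DW^-1 h^-1) measured at it."""

    mu: float
    q_s: float
    substrate: str = ""

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.q_s <= 0:
            raise ValueError("q_s must be positive")


@dataclass(frozen=True)
class PirtFit:
    """OLS fit of Pirt's equation: intercept m_s, slope 1000 / Y^max."""

    m_s: float
    y_max: float
    slope: float
    se_m_s: float
    se_slope: float
    r_squared: float
    n: int
    substrate: str = ""

    def q_s(self, mu: float) -> float:
        """Predicted uptake at growth rate mu."""
        return self.m_s + MMOL_PER_MOL * mu / self.y_max


def fit_pirt(points: Iterable[ChemostatPoint]) -> PirtFit:
    """Fit Pirt's equation to (mu, q_s) chemostat data by OLS.

    Requires at least two distinct mu values from a single substrate.
    A non-positive slope leaves Y^max undefined and raises
    :class:`FittingError` rather than reporting a negative yield.
    """
    points = list(points)
    if len(points) < 2:
        raise FittingError("at least two chemostat points are required")
    substrates = {p.substrate for p in points}
    if len(substrates) > 1:
        raise FittingError(f"points mix substrates: {sorted(substrates)}")
    mu = np.array([p.mu for p in points])
    q = np.array([p.q_s for p in points])
    if np.unique(mu).size < 2:
        raise FittingError("all mu values are equal; slope is undefined")
    res = stats.linregress(mu, q)
    if res.slope <= 0:
        raise FittingError(
            f"fitted slope {res.slope:.4g} is non-positive; "
            "maximal yield is undefined for these data"
        )
    return PirtFit(
        m_s=float(res.intercept),
        y_max=float(MMOL_PER_MOL / res.slope),
        slope=float(res.slope),
        se_m_s=float(res.intercept_stderr) if len(points) >= 3 else float("nan"),
        se_slope=float(res.stderr) if len(points) >= 3 else float("nan"),
        r_squared=float(res.rvalue**2),
        n=len(points),
        substrate=next(iter(substrates)),
    )


def uptake_ratio(fit_a: PirtFit, fit_b: PirtFit, mu: float) -> float:
    """Predicted uptake-rate ratio q_A(mu) / q_B(mu) at growth rate mu.

    As mu grows the ratio tends to the slope ratio (the asymptotic
    consumption ratio); as mu -> 0 it tends to m_A / m_B.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    denom = fit_b.q_s(mu)
    if denom == 0:
        raise ZeroDivisionError("denominator substrate uptake is zero at this mu")
    return fit_a.q_s(mu) / denom


# --------------------------------------------------------------------------
# delimited-text I/O
# --------------------------------------------------------------------------


def read_chemostat_table(text: str, sep: str = "\t") -> list[ChemostatPoint]:
    """Read (mu, q_s, substrate) triples from delimited text with header."""
    df = pd.read_csv(io.StringIO(text), sep=sep)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        mu_col, q_col = cols["mu"], cols["q_s"]
    except KeyError as exc:
        raise FittingError("table must have 'mu' and 'q_s' columns") from exc
    sub_col = cols.get("substrate")
    return [
        ChemostatPoint(
            mu=float(row[mu_col]),
            q_s=float(row[q_col]),
            substrate=str(row[sub_col]) if sub_col else "",
        )
        for _, row in df.iterrows()
    ]


def format_fit(fit: PirtFit, sep: str = "\t") -> str:
    """Serialize a fit summary as a two-line delimited table."""
    header = sep.join(["substrate", "m_s", "y_max", "slope", "se_m_s",
                       "se_slope", "r_squared", "n"])
    row = sep.join([
        fit.substrate, repr(fit.m_s), repr(fit.y_max), repr(fit.slope),
        repr(fit.se_m_s), repr(fit.se_slope), repr(fit.r_squared), str(fit.n),
    ])
    return header + "\n" + row + "\n"
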