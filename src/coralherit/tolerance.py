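"""Per-genet temperature and pH tolerances and the trade-off test.

Relative temperature tolerance of a genet is the change in its mean
calcification rate between the control and the warming treatment; relative
pH tolerance the analogous change for the acidification treatment. Negative
values mean sensitivity. A trade-off between the two tolerances would show
up as a negative Pearson correlation across genets; a shared general-stress
strategy as a positive one. The combined-future-ocean treatment plays no
role here (it informs the interaction test in the ANOVA module).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CorrelationResult", "genet_tolerances", "tolerance_correlation"]


@dataclass
class CorrelationResult:
    """Pearson correlation between temperature and pH tolerance."""

    r: float
    p: float
    n: int


def genet_tolerances(
    table: pd.DataFrame,
    species: str | None = None,
    relative: bool = False,
) -> pd.DataFrame:
    """Per-genet tolerance table (one row per genet retained).

    A genet is retained only if it has at least one surviving ramet in the
    control and in each stressor treatment; genets dropped for missing
    coverage are counted in the log. With ``relative=True`` tolerances are
    expressed as a fraction of the genet's control mean instead of a raw
    rate difference (robustness check; control mean must be nonzero).
    """
    df = table
    if species is not None:
        df = df[df["species"] == species]
        if df.empty:
            raise ValueError(f"species {species!r} not present in the table")
    if "alive" in df.columns:
        df = df[df["alive"] == 1]
    if "rate" not in df.columns:
        from .calcify import add_rates
        df = add_rates(df)
    present = set(df["treatment"].unique())
    if "control" not in present or not ({"warming", "acidification"} & present):
        raise ValueError("need the control plus at least one stressor treatment")

    means = df.groupby(["genet", "treatment"])["rate"].mean().unstack()
    required = [t for t in ("control", "warming", "acidification")
                if t in present]
    complete = means[required].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropped %d genet(s) lacking a required treatment", dropped)
    means = means[complete]

    out = pd.DataFrame(index=means.index)
    denom = means["control"].abs() if relative else 1.0
    if relative and (means["control"] == 0).any():
        raise ValueError("relative tolerances undefined: zero control mean")
    if "warming" in present:
        out["temp_tolerance"] = (means["warming"] - means["control"]) / denom
    if "acidification" in present:
        out["ph_tolerance"] = (means["acidification"] - means["control"]) / denom
    out.attrs["n_dropped"] = dropped
    return out


def tolerance_correlation(tol: pd.DataFrame) -> CorrelationResult:
    """Pearson r between temperature and pH tolerance with its two-sided
    t-test p-value on n − 2 degrees of freedom."""
    if not {"temp_tolerance", "ph_tolerance"} <= set(tol.columns):
        raise ValueError("tolerance table needs temp_tolerance and ph_tolerance")
    x = tol["temp_tolerance"].to_numpy(float)
    y = tol["ph_tolerance"].to_numpy(float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 genets for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a tolerance axis: r undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)
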