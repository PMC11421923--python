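"""Per-species treatment ANOVA on calcification rates and Tukey HSD post hoc.

The linear model has temperature, pH (and optionally their interaction) and
collection site as crossed factors, with genet nested in site and mesocosm
nested in header tank nested in treatment. Sums of squares are sequential
(Type I) in that fixed term order, each F tested against the residual mean
square. Nesting needs no special coding: each term enters as a full block of
level indicators and its degrees of freedom are the rank increment over the
terms already in the model, which is exactly the nested df.

The post hoc compares the four treatment groups with the studentized-range
(Tukey-Kramer) procedure using the fitted model's residual mean square, and
renders the familiar compact letter display (groups sharing a letter do not
differ at the chosen α).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["TreatmentAnova", "TukeyResult", "fit_anova", "tukey_hsd"]

# nested terms, in the order they may be dropped when df run out
_NESTED_ORDER = ["genet", "header_tank", "mesocosm"]


def _indicators(values) -> np.ndarray:
    codes, levels = pd.factorize(values)
    out = np.zeros((len(codes), len(levels)))
    out[np.arange(len(codes)), codes] = 1.0
    return out


@dataclass
class TukeyResult:
    """All-pairs treatment contrasts with adjusted p and letter display."""

    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    ms_error: float
    df_error: float


class TreatmentAnova(BaseEstimator):
    """Sequential-SS ANOVA for the crossed warming × acidification design.

    Parameters
    ----------
    include_interaction : bool
        Fit the temperature × pH interaction term (tested in the paper-style
        full model; drop for the additive model).
    alpha : float
        Significance level used by the Tukey post hoc and letter display.
    min_residual_df : int
        If the residual degrees of freedom fall at or below this, nested
        terms are dropped from the back of the model (mesocosm first) with
        a warning — the two-stage strategy needed for small samplings.

    Attributes
    ----------
    anova_table_ : DataFrame with df, sum_sq, mean_sq, F, p per term.
    residuals_ : ndarray of model residuals.
    group_stats_ : per-treatment n and mean used by the post hoc.
    dropped_terms_ : list of nested terms removed for lack of df.
    """

    def __init__(self, include_interaction: bool = True, alpha: float = 0.05,
                 min_residual_df: int = 0):
        self.include_interaction = include_interaction
        self.alpha = alpha
        self.min_residual_df = min_residual_df

    def _terms(self, df: pd.DataFrame, dropped: set[str]):
        temp = (df["temp_level"] != "ambient").to_numpy(float)[:, None]
        ph = (df["ph_level"] != "ambient").to_numpy(float)[:, None]
        terms = [("temperature", temp), ("pH", ph)]
        if self.include_interaction:
            terms.append(("temperature:pH", temp * ph))
        if "site" in df.columns and df["site"].nunique() > 1:
            terms.append(("site", _indicators(df["site"])))
        nested_cols = {"genet": "genet", "header_tank": "header_tank",
                       "mesocosm": "mesocosm"}
        for name in _NESTED_ORDER:
            col = nested_cols[name]
            if name not in dropped and col in df.columns:
                terms.append((name, _indicators(df[col])))
        return terms

    def fit(self, data: pd.DataFrame, species: str | None = None):
        df = data
        if species is not None:
            df = df[df["species"] == species]
            if df.empty:
                raise ValueError(f"species {species!r} not present in the table")
        if "alive" in df.columns:
            df = df[df["alive"] == 1]
        if "rate" not in df.columns:
            from .calcify import add_rates
            df = add_rates(df)
        if "treatment" in df.columns:
            sizes = df.groupby("treatment").size()
            if (sizes < 2).any():
                raise ValueError("every treatment needs >= 2 observations")

        y = df["rate"].to_numpy(float)
        n = y.size

        dropped: list[str] = []
        while True:
            terms = self._terms(df, set(dropped))
            df_terms, rank = self._sequential_fit(y, terms, peek=True)
            resid_df = n - rank
            droppable = [t for t in _NESTED_ORDER
                         if t not in dropped and any(nm == t for nm, _ in terms)]
            if resid_df > self.min_residual_df or not droppable:
                break
            victim = droppable[-1]
            dropped.append(victim)
            warnings.warn(
                f"residual df = {resid_df}; dropping nested term "
                f"'{victim}' to free degrees of freedom", UserWarning)
            logger.warning("dropping nested term %s (residual df %d)",
                           victim, resid_df)

        rows, fitted, rank = self._sequential_fit(y, terms, peek=False)
        resid = y - fitted
        df_res = n - rank
        if df_res <= 0:
            raise ValueError("model saturates the data; no residual df left")
        ss_res = float(resid @ resid)
        ms_res = ss_res / df_res

        table = []
        for name, ss, dfr in rows:
            if dfr == 0:
                table.append((name, 0, 0.0, np.nan, np.nan, np.nan))
                continue
            ms = ss / dfr
            F = ms / ms_res
            p = float(stats.f.sf(F, dfr, df_res))
            table.append((name, dfr, ss, ms, F, p))
        table.append(("residual", df_res, ss_res, ms_res, np.nan, np.nan))
        self.anova_table_ = pd.DataFrame(
            table, columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
        ).set_index("term")
        self.residuals_ = resid
        self.df_residual_ = df_res
        self.ms_residual_ = ms_res
        self.dropped_terms_ = dropped
        grp = df.groupby("treatment")["rate"]
        self.group_stats_ = pd.DataFrame({"n": grp.size(), "mean": grp.mean()})
        return self

    @staticmethod
    def _sequential_fit(y, terms, peek=False):
        """Incremental projection: SS of each term = drop in RSS when its
        indicator block joins the model; df = rank increment."""
        n = y.size
        X = np.ones((n, 1))
        coef, rss_prev, rank_prev, _ = np.linalg.lstsq(X, y, rcond=None)
        rss_prev = float(((y - X @ coef) ** 2).sum())
        rows = []
        for name, block in terms:
            X = np.hstack([X, block])
            coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ coef
            rss = float(((y - fitted) ** 2).sum())
            rows.append((name, max(rss_prev - rss, 0.0), int(rank - rank_prev)))
            rss_prev, rank_prev = rss, rank
        if peek:
            return rows, rank_prev
        return rows, fitted, rank_prev

    def tukey(self, alpha: float | None = None) -> TukeyResult:
        """Tukey-Kramer all-pairs contrasts among treatments."""
        if not hasattr(self, "group_stats_"):
            raise RuntimeError("call fit() first")
        alpha = self.alpha if alpha is None else alpha
        stats_df = self.group_stats_
        groups = list(stats_df.index)
        k = len(groups)
        if k < 2:
            raise ValueError("need >= 2 treatment groups")
        if (stats_df["n"] == 0).any():
            raise ValueError("empty treatment group")
        ms, dfe = self.ms_residual_, self.df_residual_
        recs = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = groups[i], groups[j]
                diff = stats_df.loc[b, "mean"] - stats_df.loc[a, "mean"]
                se = np.sqrt(ms / 2.0 * (1.0 / stats_df.loc[a, "n"]
                                         + 1.0 / stats_df.loc[b, "n"]))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, dfe))
                recs.append((a, b, diff, q, p, p < alpha))
        pairwise = pd.DataFrame(
            recs, columns=["group1", "group2", "diff", "q", "p_adj", "reject"])
        letters = _compact_letters(groups, stats_df["mean"], pairwise, alpha)
        return TukeyResult(pairwise=pairwise, letters=letters, alpha=alpha,
                           ms_error=ms, df_error=dfe)


def _compact_letters(groups, means, pairwise, alpha) -> dict[str, str]:
    """Greedy clique cover of the non-significance graph, visiting groups by
    ascending mean (ties broken by label order)."""
    ns = {g: set() for g in groups}  # non-significant neighbours
    for _, row in pairwise.iterrows():
        if row["p_adj"] >= alpha:
            ns[row["group1"]].add(row["group2"])
            ns[row["group2"]].add(row["group1"])
    order = sorted(groups, key=lambda g: (means[g], g))
    cliques: list[set] = []
    for g in order:
        placed = False
        for c in cliques:
            if all(other in ns[g] for other in c):
                c.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # absorb duplicate/subset cliques
    cliques = [c for i, c in enumerate(cliques)
               if not any(c < other for other in cliques if other is not c)
               and c not in cliques[:i]]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, c in zip(alphabet, cliques):
        for g in sorted(c, key=lambda g: (means[g], g)):
            letters[g] += letter
    return letters


def fit_anova(table: pd.DataFrame, species: str | None = None,
              include_interaction: bool = True) -> pd.DataFrame:
    """Sequential-SS ANOVA table for one species (thin functional wrapper)."""
    est = TreatmentAnova(include_interaction=include_interaction)
    return est.fit(table, species=species).anova_table_


def tukey_hsd(table: pd.DataFrame, species: str | None = None,
              alpha: float = 0.05,
              include_interaction: bool = True) -> TukeyResult:
    """Fit the ANOVA then run the Tukey post hoc across treatments."""
    est = TreatmentAnova(include_interaction=include_interaction, alpha=alpha)
    est.fit(table, species=species)
    return est.tukey()
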