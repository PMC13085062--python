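"""Feature engineering and selection: interaction terms, normalization,
redundancy pruning, correlation ranking against 6MWD, and recursive
feature elimination.

All fold-dependent fitting (normalization parameters, RFE) is designed to
run inside cross-validation training folds; :class:`Normalizer` stores its
location/scale so held-out folds are transformed with training-fold
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LinearRegression

__all__ = [
    "SelectionReport",
    "Normalizer",
    "add_interactions",
    "prune_correlated",
    "rank_correlations",
    "rfe",
]

#: columns never treated as features
META_COLUMNS = ("subject_id", "distance")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class SelectionReport:
    """Record of what selection did and why."""

    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    flagged_autocorrelated: list[tuple[str, int, float]] = field(default_factory=list)
    interaction_terms: list[tuple[str, str]] = field(default_factory=list)
    ranked_correlations: pd.DataFrame | None = None
    selected: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_correlated": [list(x) for x in self.dropped_correlated],
            "flagged_autocorrelated": [list(x) for x in self.flagged_autocorrelated],
            "interaction_terms": [list(x) for x in self.interaction_terms],
            "ranked_correlations": (
                self.ranked_correlations.to_dict(orient="records")
                if self.ranked_correlations is not None
                else None
            ),
            "selected": list(self.selected),
        }


def add_interactions(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> tuple[pd.DataFrame, SelectionReport]:
    """Append product columns ``a_x_b`` for each named feature pair."""
    report = SelectionReport()
    out = table.copy()
    for a, b in pairs:
        for col in (a, b):
            if col not in out.columns:
                raise KeyError(f"interaction refers to unknown feature {col!r}")
        out[f"{a}_x_{b}"] = out[a] * out[b]
        report.interaction_terms.append((a, b))
    return out, report


def default_interaction_pairs(
    table: pd.DataFrame, k: int = 3
) -> list[tuple[str, str]]:
    """Pairwise products of the top-k |r|-ranked features (not all pairs)."""
    ranked = rank_correlations(table)
    top = list(ranked["feature"].head(k))
    return [(a, b) for i, a in enumerate(top) for b in top[i + 1 :]]


class Normalizer:
    """Column-wise standardization with stored location/scale.

    Fit on training data only; ``transform`` applies the stored parameters
    (so a held-out fold does not, in general, end up with mean 0) and
    ``inverse_transform`` recovers the original values.  Zero-variance
    columns are dropped with a warning attribute rather than divided by 0.
    """

    def __init__(self) -> None:
        self.loc_: pd.Series | None = None
        self.scale_: pd.Series | None = None
        self.dropped_: list[str] = []
        self.columns_: list[str] = []

    def fit(self, table: pd.DataFrame) -> "Normalizer":
        feats = feature_columns(table)
        loc = table[feats].mean()
        scale = table[feats].std(ddof=0)
        self.dropped_ = [c for c in feats if scale[c] == 0]
        self.columns_ = [c for c in feats if scale[c] > 0]
        self.loc_ = loc[self.columns_]
        self.scale_ = scale[self.columns_]
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.loc_ is None:
            raise RuntimeError("Normalizer is not fitted")
        out = table.copy()
        out = out.drop(columns=[c for c in self.dropped_ if c in out.columns])
        out[self.columns_] = (table[self.columns_] - self.loc_) / self.scale_
        return out

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.loc_ is None:
            raise RuntimeError("Normalizer is not fitted")
        out = table.copy()
        out[self.columns_] = table[self.columns_] * self.scale_ + self.loc_
        return out


def prune_correlated(
    table: pd.DataFrame,
    r_threshold: float = 0.90,
    lag_window: int = 0,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Drop one member of each highly correlated feature pair.

    For every pair with |Pearson r| > ``r_threshold`` the member with the
    weaker |correlation to distance| is dropped (when no distance column is
    present, the later column is dropped).  Pairs are visited in descending
    |r| so the operation is idempotent.  When ``lag_window`` > 0, features
    whose lag-1..lag_window autocorrelation across the table's row ordering
    exceeds the threshold are flagged in the report, not dropped — a
    cross-sectional cohort has no intrinsic temporal ordering.
    """
    report = SelectionReport()
    feats = feature_columns(table)
    if len(feats) < 2:
        return table.copy(), report
    corr = table[feats].corr().abs()
    target_r = (
        table[feats].corrwith(table["distance"]).abs()
        if "distance" in table.columns
        else pd.Series(0.0, index=feats)
    )
    pairs = [
        (corr.iloc[i, j], feats[i], feats[j])
        for i in range(len(feats))
        for j in range(i + 1, len(feats))
        if corr.iloc[i, j] > r_threshold
    ]
    pairs.sort(reverse=True)
    dropped: set[str] = set()
    for r, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        weaker, kept = (a, b) if target_r[a] <= target_r[b] else (b, a)
        dropped.add(weaker)
        report.dropped_correlated.append((weaker, kept, float(r)))

    if lag_window > 0:
        for c in feats:
            if c in dropped:
                continue
            x = table[c].to_numpy(dtype=float)
            x = x - x.mean()
            denom = float(np.dot(x, x))
            if denom == 0:
                continue
            for lag in range(1, lag_window + 1):
                ac = float(np.dot(x[:-lag], x[lag:]) / denom)
                if abs(ac) > r_threshold:
                    report.flagged_autocorrelated.append((c, lag, ac))
                    break

    out = table.drop(columns=sorted(dropped))
    return out, report


def rank_correlations(table: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Pearson/Spearman correlation of every feature vs 6MWD, sorted by |r|.

    Returns a DataFrame with columns ``feature, pearson_r, spearman_rho,
    p_value`` in descending |pearson_r| order; ``top_k`` truncates.
    """
    if "distance" not in table.columns:
        raise KeyError("table has no 'distance' column")
    rows = []
    y = table["distance"].to_numpy(dtype=float)
    for c in feature_columns(table):
        x = table[c].to_numpy(dtype=float)
        pr = stats.pearsonr(x, y)
        rho = stats.spearmanr(x, y)
        rows.append(
            {
                "feature": c,
                "pearson_r": float(pr.statistic),
                "spearman_rho": float(rho.statistic),
                "p_value": float(pr.pvalue),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "pearson_r", key=lambda s: s.abs(), ascending=False, kind="mergesort"
    )
    out = out.reset_index(drop=True)
    return out.head(top_k) if top_k else out


def _make_rfe_estimator(spec: str, seed: int | None):
    if spec == "linear":
        return LinearRegression()
    if spec == "rf":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown RFE estimator spec {spec!r}")


def rfe(
    table: pd.DataFrame,
    k_features: int,
    estimator: str = "linear",
    seed: int | None = 0,
) -> list[str]:
    """Recursive feature elimination down to ``k_features`` columns.

    Iteratively fits the estimator on standardized features and removes
    the least important one until k remain.  Deterministic given the seed.
    """
    feats = feature_columns(table)
    if k_features > len(feats):
        raise ValueError("k_features exceeds the number of available features")
    if k_features == len(feats):
        return list(feats)
    X = table[feats].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    y = table["distance"].to_numpy(dtype=float)
    sel = RFE(
        _make_rfe_estimator(estimator, seed),
        n_features_to_select=k_features,
        step=1,
    ).fit(X, y)
    return [f for f, keep in zip(feats, sel.support_) if keep]
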