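"""miRNA sequence variants: frequency tables, screening, composite score, ROC.

Sequence variants (substitutions relative to the reference mature, shifted
ends, untemplated 3' additions) are tabulated as per-sample relative
frequencies: variant reads over all reads of that miRNA.  Variants are
screened between groups with a two-sided Mann-Whitney U test; the selected
variants feed a per-sample composite score — one point added for each
variant with frequency above its across-sample median, one point subtracted
for each below — whose group discrimination is summarized by the ROC AUC
with a Mann-Whitney p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


def call_variants(
    records: pd.DataFrame,
    mirna_totals: pd.DataFrame,
    min_mirna_reads: int = 20,
) -> pd.DataFrame:
    """Per-(miRNA, variant) relative frequencies per sample.

    Parameters
    ----------
    records : DataFrame
        Read-level variant tallies with columns ``mirna, variant, sample,
        count`` (from the annotation stage).
    mirna_totals : DataFrame
        All reads of each miRNA per sample (miRNA x sample).
    min_mirna_reads : int, default 20
        (miRNA, sample) cells with fewer total reads than this are reported
        missing (NaN), not zero — a frequency estimated from a handful of
        reads is dominated by counting noise.

    Returns
    -------
    DataFrame with a (mirna, variant) MultiIndex and one column per sample;
    values in [0, 1].
    """
    samples = list(mirna_totals.columns)
    if records.empty:
        return pd.DataFrame(
            columns=samples,
            index=pd.MultiIndex.from_tuples([], names=["mirna", "variant"]),
        )
    pivot = records.pivot_table(
        index=["mirna", "variant"], columns="sample", values="count", aggfunc="sum"
    ).reindex(columns=samples)
    totals = mirna_totals.reindex(pivot.index.get_level_values("mirna"))
    totals.index = pivot.index
    freq = pivot.fillna(0.0) / totals.where(totals > 0)
    freq = freq.where(totals >= min_mirna_reads)  # low-depth cells -> missing
    bad = freq.stack()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("variant reads exceed miRNA reads somewhere")
    return freq


def screen_variants(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.1,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney screen of variant frequencies between groups.

    Missing cells are excluded pairwise; variants observed in fewer than
    ``min_per_group`` samples in either group are skipped (logged via a
    warning summary).  Returns the selected variants with their p-value and
    direction (+1 when the case-group median is higher).
    """
    labels = pd.Series(labels).reindex(table.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("screen requires exactly two groups")
    case_cols = labels[labels == levels[1]].index
    ctrl_cols = labels[labels == levels[0]].index
    if min(len(case_cols), len(ctrl_cols)) < 3:
        raise ValueError("need at least 3 samples per group")

    rows, skipped = [], 0
    for key, row in table.iterrows():
        x = row[case_cols].dropna().to_numpy(dtype=float)
        y = row[ctrl_cols].dropna().to_numpy(dtype=float)
        if len(x) < min_per_group or len(y) < min_per_group:
            skipped += 1
            continue
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        rows.append(
            {
                "key": key,
                "p_value": float(p),
                "direction": int(np.sign(np.median(x) - np.median(y))),
            }
        )
    if skipped:
        warnings.warn(
            f"{skipped} variant(s) skipped: fewer than {min_per_group} "
            "observed samples per group",
            stacklevel=2,
        )
    if not rows:
        return pd.DataFrame(columns=["p_value", "direction"])
    out = pd.DataFrame(rows).set_index("key")
    out.index = pd.MultiIndex.from_tuples(out.index, names=table.index.names)
    selected = out[out["p_value"] < alpha].sort_values("p_value")
    return selected


def composite_score(
    table: pd.DataFrame,
    directions: pd.Series | None = None,
) -> pd.Series:
    """Above/below-median composite score per sample.

    For each variant the median frequency across *all* samples in the table
    is the anchor; a sample gains +1 per variant with frequency above the
    median, -1 per variant below, 0 at ties or missing cells.  When
    ``directions`` is given (the direction-aware option) the contribution of
    variants lower in the case group is sign-flipped, so that higher scores
    always point toward the case group.

    Samples missing every variant have no defined score and are dropped with
    a warning.
    """
    if len(table) == 0:
        raise ValueError("composite score needs at least one selected variant")
    medians = table.median(axis=1, skipna=True)
    above = table.gt(medians, axis=0)
    below = table.lt(medians, axis=0)
    contrib = above.astype(int) - below.astype(int)
    if directions is not None:
        sign = pd.Series(directions).reindex(table.index).replace(0, 1)
        contrib = contrib.mul(sign, axis=0)
    observed = table.notna().any(axis=0)
    if (~observed).any():
        warnings.warn(
            f"sample(s) {list(table.columns[~observed])} missing all selected "
            "variants: score undefined, excluded",
            stacklevel=2,
        )
    scores = contrib.sum(axis=0)[observed]
    return scores.astype(int)


def roc_auc(scores, labels):
    """Pair-counting ROC AUC and Mann-Whitney p for a score vs binary labels.

    ``AUC = P(score_case > score_control) + 0.5 * P(tie)`` over all
    case-control pairs.  The p-value is the two-sided Mann-Whitney U normal
    approximation with tie correction and continuity correction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("roc_auc requires both classes present")
    cases = scores[labels == levels[1]]
    ctrls = scores[labels == levels[0]]
    n1, n0 = len(cases), len(ctrls)
    diff = cases[:, None] - ctrls[None, :]
    u = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    auc = u / (n1 * n0)

    n = n1 + n0
    pooled = np.concatenate([cases, ctrls])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all scores identical
        return auc, 1.0
    mean_u = n1 * n0 / 2.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(sigma2)  # continuity-corrected
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return auc, min(float(p), 1.0)


class CompositeVariantScorer(BaseEstimator, TransformerMixin):
    """Screen-then-score variant classifier in the scikit-learn idiom.

    ``fit`` screens variants between the two label groups (two-sided
    Mann-Whitney at ``alpha``), stores the selected variants, their
    across-sample median frequencies and directions; ``transform`` maps a
    frequency matrix to per-sample composite scores using the stored
    medians.  Fitting and transforming the same samples reproduces the
    in-sample (optimistically biased) discovery procedure; transforming
    held-out samples gives the cross-validated variant.

    Parameters
    ----------
    alpha : float, default 0.1
        Screening threshold for the Mann-Whitney p-value.
    direction_aware : bool, default False
        Sign-flip variants whose case-group median is lower, so higher
        scores always indicate the case group.  The default is the literal
        above/below-median rule.
    min_per_group : int, default 3
        Minimum observed samples per group for a variant to be testable.

    Attributes
    ----------
    selected_ : pandas.MultiIndex of retained (miRNA, variant) pairs.
    screen_ : DataFrame with p-values and directions for the retained pairs.
    medians_ : Series of across-sample median frequencies (fit samples).
    auc_, p_value_ : in-sample ROC AUC of the fitted scores and its p.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        direction_aware: bool = False,
        min_per_group: int = 3,
    ):
        self.alpha = alpha
        self.direction_aware = direction_aware
        self.min_per_group = min_per_group

    @staticmethod
    def _as_table(X) -> pd.DataFrame:
        """Accept samples x variants (sklearn orientation) or a VariantTable."""
        if isinstance(X, pd.DataFrame) and isinstance(X.index, pd.MultiIndex):
            return X  # already variants x samples
        X = pd.DataFrame(X)
        return X.T

    def fit(self, X, y):
        table = self._as_table(X)
        y = pd.Series(list(y), index=table.columns)
        screen = screen_variants(
            table, y, alpha=self.alpha, min_per_group=self.min_per_group
        )
        if len(screen) == 0:
            raise ValueError("no variant passed the screen")
        self.screen_ = screen
        self.selected_ = screen.index
        sub = table.loc[self.selected_]
        self.medians_ = sub.median(axis=1, skipna=True)
        self.directions_ = screen["direction"]
        scores = self._score(sub)
        self.fitted_scores_ = scores
        self.auc_, self.p_value_ = roc_auc(scores, y.reindex(scores.index))
        return self

    def _score(self, sub: pd.DataFrame) -> pd.Series:
        contrib = sub.gt(self.medians_, axis=0).astype(int) - sub.lt(
            self.medians_, axis=0
        ).astype(int)
        if self.direction_aware:
            contrib = contrib.mul(self.directions_.replace(0, 1), axis=0)
        observed = sub.notna().any(axis=0)
        return contrib.sum(axis=0)[observed].astype(int)

    def transform(self, X) -> pd.Series:
        table = self._as_table(X)
        sub = table.reindex(self.selected_)
        return self._score(sub)

    def roc(self, X, y):
        """ROC AUC and Mann-Whitney p of the scores on (X, y)."""
        scores = self.transform(X)
        y = pd.Series(list(y), index=self._as_table(X).columns)
        return roc_auc(scores, y.reindex(scores.index))
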