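"""Per-comparison, per-sex statistical screening of the feature table.

For each of the four two-group comparisons (C vs B, C vs NB, B vs NB,
C vs A; A = B + NB) and each sex separately, every feature is tested with an
equal-variance two-group F test (the square of the pooled t test, i.e. the
standard one-way ANOVA follow-up) and features with p < alpha are retained.
No multiple-testing correction is applied by default; Benjamini-Hochberg is
available behind a flag.  A multivariate omnibus (Wilks' lambda) is attempted
when the within-group covariance permits it and reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "Comparison",
    "SelectionResult",
    "screen_features",
    "feature_columns",
]

ID_COLUMNS = ("subject_id", "sex", "vowel", "group")


@dataclass(frozen=True)
class Comparison:
    name: str
    positive: str    # class coded 1 (the "affected" side)
    negative: str
    sex: str = "F"

    def labels(self, groups: pd.Series) -> pd.Series:
        """Map raw group labels onto this comparison's two classes (or None)."""
        def side(g):
            if self.positive == "A":
                pos = g in ("B", "NB")
            else:
                pos = g == self.positive
            return self.positive if pos else (self.negative if g == self.negative else None)
        return groups.map(side)


def make_comparison(name: str, sex: str = "F") -> Comparison:
    neg, _, pos = name.partition("_vs_")
    return Comparison(name=name, positive=pos, negative=neg, sex=sex)


COMPARISONS = ("C_vs_B", "C_vs_NB", "B_vs_NB", "C_vs_A")


@dataclass
class SelectionResult:
    comparison: Comparison
    pvalues: pd.Series                    # index = feature names
    selected: list
    alpha: float
    wilks_lambda: float | None = None
    wilks_p: float | None = None
    n_per_group: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "comparison": self.comparison.name,
            "sex": self.comparison.sex,
            "feature": self.pvalues.index,
            "p_value": self.pvalues.values,
            "selected": [f in self.selected for f in self.pvalues.index],
        })


def feature_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in ID_COLUMNS]


def _split_groups(table: pd.DataFrame, cmp: Comparison) -> tuple[pd.DataFrame, pd.DataFrame]:
    sub = table[table["sex"] == cmp.sex] if "sex" in table.columns else table
    side = cmp.labels(sub["group"])
    pos = sub[side == cmp.positive]
    neg = sub[side == cmp.negative]
    return pos, neg


def _wilks_omnibus(x_pos: np.ndarray, x_neg: np.ndarray):
    """One-way MANOVA Wilks' lambda with the Rao F approximation (2 groups)."""
    from statsmodels.multivariate.manova import MANOVA

    n, p = x_pos.shape[0] + x_neg.shape[0], x_pos.shape[1]
    if n <= p + 2:  # singular within-group covariance
        log.warning(
            "MANOVA omnibus skipped: %d features >= %d observations; "
            "per-feature tests only", p, n)
        return None, None
    x = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(len(x_pos)), np.zeros(len(x_neg))])
    exog = np.column_stack([np.ones(len(y)), y])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MANOVA(x, exog).mv_test(
                hypotheses=[("group", np.array([[0.0, 1.0]]), None)]
            )
        frame = res.results["group"]["stat"]
        lam = float(frame.loc["Wilks' lambda", "Value"])
        p = float(frame.loc["Wilks' lambda", "Pr > F"])
        return lam, p
    except Exception as exc:  # singular within covariance, p >= n, ...
        log.warning("MANOVA omnibus unavailable (%s); per-feature tests only", exc)
        return None, None


def screen_features(
    table: pd.DataFrame,
    cmp: Comparison,
    alpha: float = 0.05,
    *,
    welch: bool = False,
    fdr: bool = False,
    features: list | None = None,
) -> SelectionResult:
    """Screen features for ``cmp``: retain those with p < alpha."""
    feats = features if features is not None else feature_columns(table)
    pos, neg = _split_groups(table, cmp)
    pos = pos[feats].dropna()
    neg = neg[feats].dropna()
    n_dropped = (len(_split_groups(table, cmp)[0]) - len(pos)) + (
        len(_split_groups(table, cmp)[1]) - len(neg))
    if n_dropped:
        warnings.warn(f"{cmp.name}/{cmp.sex}: dropped {n_dropped} incomplete rows")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"{cmp.name}/{cmp.sex}: need >= 2 observations per group, "
            f"got {len(pos)} vs {len(neg)}"
        )

    a = pos.to_numpy(dtype=np.float64)
    b = neg.to_numpy(dtype=np.float64)
    if welch:
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        pvals = np.asarray(res.pvalue)
    else:
        res = stats.f_oneway(a, b, axis=0)
        pvals = np.asarray(res.pvalue)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    if fdr:
        from statsmodels.stats.multitest import multipletests
        pvals_adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals_adj = pvals

    pseries = pd.Series(pvals_adj, index=feats, name="p_value")
    selected = [f for f in feats if pseries[f] < alpha]
    lam, lam_p = _wilks_omnibus(a, b)
    return SelectionResult(
        comparison=cmp, pvalues=pseries, selected=selected, alpha=alpha,
        wilks_lambda=lam, wilks_p=lam_p,
        n_per_group={cmp.positive: len(pos), cmp.negative: len(neg)},
    )
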