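"""Staged differential abundance: group means, log2 fold changes,
two-sided Student t-tests and Benjamini-Hochberg adjustment.

The three canonical adipogenesis contrasts are *early* (immature vs.
preadipocytes), *late* (mature vs. immature) and *complete* (mature vs.
preadipocytes); any named condition pair works.  Fold changes are
differences of group mean log2 intensities; significance defaults to
adjusted p < 0.01 with a strict inequality.

``profile_vs_baseline`` reuses the same machinery for metabolite-style
per-condition comparisons against the initial time point, reported
without multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix
from .preprocess import _condition_samples, condition_means, zscore_profiles


@dataclass(frozen=True)
class Contrast:
    name: str
    numerator: str    # e.g. "mature"
    denominator: str  # e.g. "preadipocyte"

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("contrast numerator must differ from denominator")


def standard_contrasts(design: pd.DataFrame) -> list[Contrast]:
    """Early/late/complete contrasts from the ordinal time codes."""
    conds = (design.drop_duplicates("condition")
             .sort_values("time_code")["condition"].tolist())
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions for contrasts")
    out = [Contrast("complete", conds[-1], conds[0])]
    if len(conds) >= 3:
        out = [Contrast("early", conds[1], conds[0]),
               Contrast("late", conds[-1], conds[1])] + out
    return out


@dataclass
class ContrastResult:
    contrast: Contrast
    alpha: float
    table: pd.DataFrame          # feature x (mean_num, mean_den, log2fc, t, df, p, adj_p, significant)
    untested: list = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_features(self) -> list:
        return list(self.table.index[self.table["significant"]])


def student_t_pvalue(group1, group2, equal_var: bool = True
                     ) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, df, p)``.

    Classic pooled-variance Student test by default (``df = n1 + n2 - 2``),
    Welch with Satterthwaite df when ``equal_var=False``.  Degenerate
    zero-variance inputs follow the conventions: equal means -> t = 0,
    p = 1; unequal means -> infinite t, p = 0.
    """
    x = np.asarray([v for v in np.asarray(group1, dtype=float) if math.isfinite(v)])
    y = np.asarray([v for v in np.asarray(group2, dtype=float) if math.isfinite(v)])
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 finite values")
    n1, n2 = len(x), len(y)
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(pooled * (1 / n1 + 1 / n2))
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        if se > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    if se == 0:
        if m1 == m2:
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, m1 - m2), float(df), 0.0
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_contrast(matrix: IntensityMatrix, design: pd.DataFrame,
                     contrast: Contrast, alpha: float = 0.01,
                     equal_var: bool = True) -> ContrastResult:
    """Per-feature log2FC, Student t and BH-adjusted p for one contrast.

    Features with fewer than 2 observed replicates in either condition
    are reported in ``untested`` and excluded from the BH family.
    """
    groups = _condition_samples(matrix, design)
    for cond in (contrast.numerator, contrast.denominator):
        if cond not in groups:
            raise ValueError(f"condition {cond!r} not present in design")
    num = matrix.values[groups[contrast.numerator]].to_numpy(dtype=float)
    den = matrix.values[groups[contrast.denominator]].to_numpy(dtype=float)
    n1 = np.sum(np.isfinite(num), axis=1)
    n2 = np.sum(np.isfinite(den), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    features = np.asarray(matrix.feature_ids, dtype=object)
    untested = list(features[~testable])

    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(np.isfinite(num), num, np.nan), axis=1)
        m2 = np.nanmean(np.where(np.isfinite(den), den, np.nan), axis=1)
        v1 = np.nanvar(num, axis=1, ddof=1)
        v2 = np.nanvar(den, axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            df = n1 + n2 - 2.0
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, 1.0)
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            df = np.where(np.isfinite(df) & (df > 0), df, n1 + n2 - 2.0)

        diff = m1 - m2
        t = diff / se
        zero_se = se == 0
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
        p = np.where(np.isinf(t), 0.0,
                     np.where(zero_se, 1.0, 2.0 * stats.t.sf(np.abs(t), df)))
        p = np.minimum(p, 1.0)

    table = pd.DataFrame({
        "mean_num": m1[testable], "mean_den": m2[testable],
        "log2fc": diff[testable], "t": t[testable], "df": df[testable],
        "p": p[testable],
    }, index=features[testable])
    table["adj_p"] = adjust_bh(table["p"].to_numpy()) if len(table) else []
    table["significant"] = table["adj_p"] < alpha
    return ContrastResult(contrast=contrast, alpha=alpha, table=table,
                          untested=untested)


def percent_significant(results: dict) -> pd.DataFrame:
    """100 x significant / tested, per layer x contrast.

    ``results`` maps layer name -> {contrast name -> ContrastResult}.
    Layers/contrasts with zero tested features report ``NaN``.
    """
    rows = {}
    for layer, by_contrast in results.items():
        rows[layer] = {
            cname: (100.0 * res.n_significant / res.n_tested
                    if res.n_tested else math.nan)
            for cname, res in by_contrast.items()
        }
    return pd.DataFrame(rows).T


@dataclass
class BaselineProfile:
    baseline: str
    pvalues: pd.DataFrame   # feature x non-baseline condition, unadjusted
    zscores: pd.DataFrame   # feature x condition, z-scored condition means


def profile_vs_baseline(matrix: IntensityMatrix, design: pd.DataFrame,
                        baseline_condition: str, equal_var: bool = True
                        ) -> BaselineProfile:
    """Per-condition Student t-tests against a baseline condition.

    Mirrors targeted-metabolite reporting: two-sided p-values per
    condition vs. the baseline, deliberately unadjusted, attached to the
    z-scored condition-mean profile.
    """
    groups = _condition_samples(matrix, design)
    if baseline_condition not in groups:
        raise ValueError(f"baseline condition {baseline_condition!r} not in design")
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions")
    others = [c for c in groups if c != baseline_condition]
    pvals = {}
    for cond in others:
        res = compute_contrast(matrix, design,
                               Contrast(f"{cond}_vs_{baseline_condition}",
                                        cond, baseline_condition),
                               alpha=0.05, equal_var=equal_var)
        pvals[cond] = res.table["p"]
    z = zscore_profiles(condition_means(matrix, design))
    return BaselineProfile(baseline=baseline_condition,
                           pvalues=pd.DataFrame(pvals), zscores=z)
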