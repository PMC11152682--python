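"""Quantification preprocessing: replicate-presence filtering, median
alignment + generalized-log transform, downshifted-Gaussian noise
imputation, and z-scored condition profiles.

The three stages are scikit-learn style transformers operating on
:class:`~adipoptm.io.IntensityMatrix` objects (features as rows, samples
as columns); module-level functions wrap them for one-shot use.

The workflow mirrors standard label-free proteomics practice: a feature
is quantifiable only if it was observed in every replicate of at least
one condition; raw intensities are aligned on per-sample medians and
variance-stabilized with a generalized log; condition blocks that are
entirely missing (censored at the detection limit) are imputed from a
Gaussian downshifted into each sample's low-intensity tail.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LOG2, RAW, IntensityMatrix, check_design


def _condition_samples(matrix: IntensityMatrix,
                       design: pd.DataFrame) -> dict[str, list[str]]:
    check_design(matrix, design)
    sub = design[design["sample_id"].isin(matrix.sample_ids)]
    groups = {cond: list(g["sample_id"]) for cond, g in sub.groupby("condition", sort=False)}
    empty = [c for c in design["condition"].unique() if c not in groups]
    if empty:
        raise ValueError(f"conditions with no samples in the matrix: {empty}")
    return groups


class PresenceFilter(BaseEstimator, TransformerMixin):
    """Keep features observed in all replicates of >= 1 condition.

    Fitted attributes
    -----------------
    mask_ : DataFrame, features x conditions — observed replicate counts.
    retained_ : list of retained feature IDs.
    """

    def __init__(self, design: pd.DataFrame | None = None):
        self.design = design

    def fit(self, X: IntensityMatrix, y=None) -> "PresenceFilter":
        if self.design is None:
            raise ValueError("PresenceFilter requires a design table")
        groups = _condition_samples(X, self.design)
        counts = {cond: X.values[cols].notna().sum(axis=1)
                  for cond, cols in groups.items()}
        self.mask_ = pd.DataFrame(counts)
        self.n_replicates_ = {cond: len(cols) for cond, cols in groups.items()}
        complete = pd.DataFrame(
            {cond: self.mask_[cond] == self.n_replicates_[cond]
             for cond in groups})
        self.retained_ = list(self.mask_.index[complete.any(axis=1)])
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        keep = [f for f in X.feature_ids if f in set(self.retained_)]
        return IntensityMatrix(X.values.loc[keep], X.scale)


class MedianGlogNormalizer(BaseEstimator, TransformerMixin):
    """Per-sample median alignment followed by a generalized-log transform.

    Raw intensities are scaled multiplicatively so sample medians agree
    (medians computed over features observed in every sample, falling
    back to all observed values when no feature is complete), then
    transformed with ``glog(x) = log2((x + sqrt(x^2 + a^2)) / 2)`` where
    ``a`` is the ``shift_quantile`` quantile of aligned observed
    intensities.  The transform is monotone per sample and approaches
    plain log2 for abundant features while compressing variance near the
    detection limit.
    """

    def __init__(self, shift_quantile: float = 0.01):
        self.shift_quantile = shift_quantile

    def fit(self, X: IntensityMatrix, y=None) -> "MedianGlogNormalizer":
        if X.scale != RAW:
            raise ValueError("normalizer expects a raw-scale matrix")
        values = X.values
        observed = values.notna()
        if (observed.sum(axis=0) < 2).any():
            bad = list(values.columns[observed.sum(axis=0) < 2])
            raise ValueError(f"samples with < 2 observed values: {bad}")
        if (values.min(skipna=True).min() is not None
                and np.nanmin(values.to_numpy()) <= 0):
            raise ValueError("raw intensities must be positive")
        shared = observed.all(axis=1)
        basis = values.loc[shared] if shared.any() else values
        medians = basis.median(axis=0, skipna=True)
        target = float(np.exp(np.log(medians).mean()))  # geometric mean
        self.factors_ = target / medians
        aligned = values * self.factors_
        self.glog_shift_ = float(np.nanquantile(aligned.to_numpy(),
                                                self.shift_quantile))
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        aligned = X.values * self.factors_
        a = self.glog_shift_
        arr = aligned.to_numpy(dtype=float)
        out = np.log2((arr + np.sqrt(arr * arr + a * a)) / 2.0)
        return IntensityMatrix(
            pd.DataFrame(out, index=X.feature_ids, columns=X.sample_ids), LOG2)


class NoiseImputer(BaseEstimator, TransformerMixin):
    """Downshifted-Gaussian imputation of missing log2 intensities.

    For every feature x condition block with no observed replicate, and
    for sporadic gaps (some but not all replicates missing), each missing
    cell is drawn from ``N(mean_s - shift * sd_s, (width * sd_s)^2)``
    where ``mean_s``/``sd_s`` are that sample's observed log2 statistics
    — i.e. values are placed in the sample's low-abundance tail, the
    de-facto convention for missing-not-at-random proteomics data.

    A seed is mandatory: imputation must be reproducible.  ``log_``
    records every imputed cell with its reason (``block``/``sporadic``).
    """

    def __init__(self, design: pd.DataFrame | None = None,
                 seed: int | None = None, shift: float = 1.8,
                 width: float = 0.3):
        self.design = design
        self.seed = seed
        self.shift = shift
        self.width = width

    def fit(self, X: IntensityMatrix, y=None) -> "NoiseImputer":
        if self.seed is None:
            raise ValueError("NoiseImputer requires an explicit seed")
        if X.scale != LOG2:
            raise ValueError("imputation operates on log2-scale matrices")
        if self.design is None:
            raise ValueError("NoiseImputer requires a design table")
        self.sample_mean_ = X.values.mean(axis=0, skipna=True)
        self.sample_sd_ = X.values.std(axis=0, ddof=1, skipna=True)
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        groups = _condition_samples(X, self.design)
        values = X.values.copy()
        rng = np.random.default_rng(self.seed)
        records = []
        for cond, cols in groups.items():
            block = values[cols]
            n_obs = block.notna().sum(axis=1)
            for fid in block.index[n_obs < len(cols)]:
                reason = "block" if n_obs[fid] == 0 else "sporadic"
                for sample in cols:
                    if not math.isnan(values.at[fid, sample]):
                        continue
                    mu = self.sample_mean_[sample] - self.shift * self.sample_sd_[sample]
                    sd = self.width * self.sample_sd_[sample]
                    drawn = float(rng.normal(mu, sd))
                    values.at[fid, sample] = drawn
                    records.append({"feature": fid, "sample": sample,
                                    "condition": cond, "imputed_value": drawn,
                                    "reason": reason})
        self.log_ = pd.DataFrame(
            records, columns=["feature", "sample", "condition",
                              "imputed_value", "reason"])
        return IntensityMatrix(values, LOG2)


def filter_by_presence(matrix: IntensityMatrix, design: pd.DataFrame
                       ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Apply the all-replicates-in-one-condition rule; return (matrix, mask)."""
    f = PresenceFilter(design).fit(matrix)
    return f.transform(matrix), f.mask_


def normalize_and_transform(matrix: IntensityMatrix,
                            shift_quantile: float = 0.01) -> IntensityMatrix:
    """Median-align a raw matrix and report it on the glog/log2 scale."""
    return MedianGlogNormalizer(shift_quantile).fit(matrix).transform(matrix)


def impute_noise(matrix: IntensityMatrix, design: pd.DataFrame, seed: int,
                 shift: float = 1.8, width: float = 0.3
                 ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Impute missing cells; return (completed matrix, imputation log)."""
    imp = NoiseImputer(design, seed=seed, shift=shift, width=width).fit(matrix)
    completed = imp.transform(matrix)
    return completed, imp.log_


def condition_means(matrix: IntensityMatrix,
                    design: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean log2 intensity per condition (time-code order)."""
    groups = _condition_samples(matrix, design)
    order = (design.drop_duplicates("condition")
             .sort_values("time_code")["condition"])
    return pd.DataFrame({cond: matrix.values[groups[cond]].mean(axis=1)
                         for cond in order})


def zscore_profiles(cond_means: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores across conditions (sample SD, n-1 denominator).

    Constant rows map to all-zero by convention.  Requires >= 2 columns.
    """
    if cond_means.shape[1] < 2:
        raise ValueError("z-scored profiles need >= 2 conditions")
    mean = cond_means.mean(axis=1)
    sd = cond_means.std(axis=1, ddof=1)
    z = cond_means.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)
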