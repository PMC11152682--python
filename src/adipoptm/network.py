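"""Weighted co-abundance network analysis over the combined proteome +
corrected-PTM feature space.

The analysis follows the weighted correlation network paradigm:

1. Pearson correlation ``r`` between every feature pair across samples,
2. soft-threshold adjacency — signed ``a = ((1 + r)/2)^beta`` (default,
   beta = 17) or unsigned ``a = |r|^beta``,
3. topological overlap ``TOM_ij = (sum_u a_iu a_uj + a_ij) /
   (min(k_i, k_j) + 1 - a_ij)`` with connectivity ``k_i = sum_{u != i} a_iu``,
4. average-linkage hierarchical clustering of ``1 - TOM``; the tree is
   cut at a static height determined by ``deepsplit`` (0..4 ->
   0.99/0.97/0.95/0.93/0.91); clusters below ``min_module`` go to grey,
   clusters above ``max_module`` are re-cut at decreasing heights,
5. module eigengenes (first right singular vector of the standardized
   module submatrix) and iterative closest-pair merging of modules whose
   eigengene dissimilarity ``1 - r`` falls below ``merge_cut``,
6. module-trait correlation, per-feature module membership (kME) and
   trait significance (GS), and Top-k key-driver extraction scored by
   ``|kME| x |GS|`` with a TOM-derived connectivity edge list.

Everything is deterministic given the inputs; ties are broken by
feature/module identifier order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .io import IntensityMatrix
from .layers import prefix_feature, split_feature
from .ptm import CorrectedSiteMatrix

GREY = "grey"

#: deepsplit -> static cut height on the 1 - TOM dendrogram
DEEPSPLIT_HEIGHTS = {0: 0.99, 1: 0.97, 2: 0.95, 3: 0.93, 4: 0.91}

#: conventional module color names, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


def build_feature_space(proteome: IntensityMatrix,
                        corrected_ack: CorrectedSiteMatrix | IntensityMatrix,
                        corrected_pp: CorrectedSiteMatrix | IntensityMatrix
                        ) -> pd.DataFrame:
    """Row-concatenate the three layers with layer-prefixed feature IDs.

    All matrices must share the same sample set and be complete (the
    network stage admits no missing values).
    """
    from .layers import ACETYLOME, PHOSPHO, PROTEOME

    def values(m):
        return m.matrix.values if isinstance(m, CorrectedSiteMatrix) else m.values

    blocks = []
    samples = list(proteome.values.columns)
    for layer, m in ((PROTEOME, proteome), (ACETYLOME, corrected_ack),
                     (PHOSPHO, corrected_pp)):
        v = values(m)
        if list(v.columns) != samples:
            raise ValueError(f"sample set of layer {layer!r} differs from proteome")
        block = v.copy()
        block.index = [prefix_feature(layer, f) for f in block.index]
        blocks.append(block)
    combined = pd.concat(blocks, axis=0)
    if combined.isna().to_numpy().any():
        n = int(combined.isna().to_numpy().sum())
        raise ValueError(
            f"combined feature space contains {n} missing values; impute or "
            "drop incomplete features before network construction")
    return combined


def adjacency_from_correlation(r, beta: int = 17, signed: bool = True):
    """Map Pearson correlation(s) to soft-threshold adjacency in [0, 1]."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    a = ((1.0 + r_arr) / 2.0) ** beta if signed else np.abs(r_arr) ** beta
    return float(a) if np.isscalar(r) else a


def adjacency_matrix(data: pd.DataFrame, beta: int = 17,
                     signed: bool = True) -> pd.DataFrame:
    """Feature x feature adjacency from per-feature Pearson correlations."""
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant features have zero correlation with everything")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    a = adjacency_from_correlation(corr, beta=beta, signed=signed)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=data.index, columns=data.index)


def topological_overlap(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    index = adj.index if isinstance(adj, pd.DataFrame) else None
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(a - a.T)) > 1e-10:
        raise ValueError("adjacency must be symmetric (tolerance 1e-10)")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return tom


def _cut_oversized(diss: np.ndarray, idx: np.ndarray, height: float,
                   max_module: int, warnings_out: list) -> list[np.ndarray]:
    """Recursively re-cut clusters larger than ``max_module`` at lower heights."""
    if len(idx) <= max_module:
        return [idx]
    h = height
    while h > 0.05:
        sub = squareform(diss[np.ix_(idx, idx)], checks=False)
        labels = fcluster(linkage(sub, method="average"), t=h,
                          criterion="distance")
        if labels.max() > 1:
            parts = []
            for u in np.unique(labels):
                parts.extend(_cut_oversized(diss, idx[labels == u], h - 0.02,
                                            max_module, warnings_out))
            return parts
        h -= 0.02
    warnings_out.append(
        f"cluster of {len(idx)} features indivisible below max_module")
    return [idx]


def detect_modules(tom: pd.DataFrame, min_module: int = 50,
                   max_module: int = 500, deepsplit: int = 2,
                   warnings_out: list | None = None) -> pd.Series:
    """Initial module labels from average-linkage clustering of 1 - TOM.

    Returns a Series feature -> color label (``grey`` = unassigned).
    Clusters below ``min_module`` become grey; clusters above
    ``max_module`` are recursively re-cut at lower heights.
    """
    if deepsplit not in DEEPSPLIT_HEIGHTS:
        raise ValueError(f"deepsplit must be in 0..4, got {deepsplit}")
    warnings_out = warnings_out if warnings_out is not None else []
    features = np.asarray(tom.index, dtype=object)
    n = len(features)
    if n < min_module:
        warnings_out.append(
            f"only {n} features (< min_module={min_module}); all grey")
        return pd.Series(GREY, index=tom.index, name="module")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    height = DEEPSPLIT_HEIGHTS[deepsplit]
    condensed = squareform(diss, checks=False)
    raw = fcluster(linkage(condensed, method="average"), t=height,
                   criterion="distance")
    clusters: list[np.ndarray] = []
    for u in np.unique(raw):
        idx = np.flatnonzero(raw == u)
        if len(idx) < min_module:
            continue
        clusters.extend(_cut_oversized(diss, idx, height - 0.02, max_module,
                                       warnings_out))
    clusters = [c for c in clusters if len(c) >= min_module]
    # deterministic color assignment: by size desc, ties by first feature
    clusters.sort(key=lambda c: (-len(c), int(c.min())))
    labels = pd.Series(GREY, index=tom.index, name="module")
    for i, idx in enumerate(clusters):
        color = (MODULE_COLORS[i] if i < len(MODULE_COLORS)
                 else f"module{i + 1}")
        labels.iloc[idx] = color
    return labels


def module_eigengene(submatrix: pd.DataFrame,
                     warnings_out: list | None = None
                     ) -> tuple[pd.Series, float]:
    """First principal component of the feature-standardized submatrix.

    Returns ``(eigengene, variance_explained)``; the eigengene is the
    unit-norm first right singular vector, sign-oriented so its average
    correlation with the module's features is non-negative.  Constant
    feature rows are excluded with a warning.
    """
    if submatrix.shape[0] < 2:
        raise ValueError("module eigengene needs >= 2 features")
    arr = submatrix.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        msg = f"{int((~keep).sum())} constant feature(s) excluded from eigengene"
        (warnings_out.append(msg) if warnings_out is not None
         else warnings.warn(msg))
        arr, sd = arr[keep], sd[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    # orientation: corr(feature_i, eigengene) has the sign of U[i, 0];
    # summing features' projections gives the majority direction
    proj = z @ eig
    orient = np.sign(proj.sum())
    if orient == 0:
        nz = np.flatnonzero(eig)
        orient = np.sign(eig[nz[0]]) if len(nz) else 1.0
    eig = eig * orient
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return pd.Series(eig, index=submatrix.columns, name="eigengene"), var_explained


def _eigengene_corr(e1: pd.Series, e2: pd.Series) -> float:
    return float(np.corrcoef(e1.to_numpy(), e2.to_numpy())[0, 1])


def merge_modules(data: pd.DataFrame, labels: pd.Series, merge_cut: float = 0.3,
                  warnings_out: list | None = None) -> pd.Series:
    """Iteratively merge the closest module pair while eigengene
    dissimilarity ``1 - r`` stays below ``merge_cut``.

    Closest-pair-first with lexicographic tie-breaks makes the final
    partition independent of input ordering.  Merged labels are re-ranked
    to color names by final module size.
    """
    labels = labels.copy()
    modules = sorted(m for m in labels.unique() if m != GREY)
    eigs = {m: module_eigengene(data.loc[labels.index[labels == m]],
                                warnings_out)[0] for m in modules}
    while len(eigs) > 1:
        best = None
        for i, m1 in enumerate(sorted(eigs)):
            for m2 in sorted(eigs)[i + 1:]:
                diss = 1.0 - _eigengene_corr(eigs[m1], eigs[m2])
                cand = (diss, m1, m2)
                if best is None or cand < best:
                    best = cand
        diss, m1, m2 = best
        if diss >= merge_cut:
            break
        # absorb into the larger module's label (ties: lexicographic)
        n1, n2 = (labels == m1).sum(), (labels == m2).sum()
        keep, drop = (m1, m2) if (n1, m2) >= (n2, m1) else (m2, m1)
        labels[labels == drop] = keep
        del eigs[drop]
        eigs[keep] = module_eigengene(data.loc[labels.index[labels == keep]],
                                      warnings_out)[0]
    return _relabel_by_size(labels)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    mapping = {m: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
               for i, m in enumerate(order)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def prune_by_kme(data: pd.DataFrame, labels: pd.Series, min_kme: float = 0.9,
                 min_module: int = 50, signed: bool = True,
                 warnings_out: list | None = None) -> pd.Series:
    """Return weakly-connected module members to grey.

    Standard membership cleanup: features whose correlation with their
    own module eigengene falls below ``min_kme`` are unassigned; modules
    dropping below ``min_module`` afterwards are dissolved into grey.
    With few samples, chance correlations against a module pattern are
    heavy-tailed, so clusters from the static tree cut accrete
    background features; planted/true members track the eigengene far
    more tightly than chance correlators, which this step removes
    irrespective of module size.  Labels are re-ranked by size at the
    end.
    """
    labels = labels.copy()
    for m in sorted(set(labels) - {GREY}):
        members = labels.index[labels == m]
        eig, _ = module_eigengene(data.loc[members], warnings_out)
        e = eig.to_numpy()
        arr = data.loc[members].to_numpy(dtype=float)
        ac = arr - arr.mean(axis=1, keepdims=True)
        asd = ac.std(axis=1)
        ec = e - e.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac @ ec) / (arr.shape[1] * asd * ec.std())
        # signed networks: membership means tracking the eigengene, not
        # mirroring it
        score = np.nan_to_num(r) if signed else np.abs(np.nan_to_num(r))
        weak = members[~(score >= min_kme)]
        if len(weak) and warnings_out is not None:
            warnings_out.append(
                f"module {m}: {len(weak)} members below kME {min_kme} -> grey")
        labels[weak] = GREY
    for m in sorted(set(labels) - {GREY}):
        if (labels == m).sum() < min_module:
            if warnings_out is not None:
                warnings_out.append(
                    f"module {m} fell below min_module after kME pruning; "
                    "dissolved")
            labels[labels == m] = GREY
    return _relabel_by_size(labels)


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t transform with n - 2 df."""
    if n < 3:
        return float("nan")
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_statistics(eigengenes: pd.DataFrame,
                            trait: np.ndarray) -> pd.DataFrame:
    """Pearson r and two-sided p between each eigengene and the trait."""
    trait = np.asarray(trait, dtype=float)
    if len(trait) < 3:
        raise ValueError("trait needs >= 3 samples")
    if np.std(trait) == 0:
        raise ValueError("trait is constant; correlation undefined")
    rows = {}
    n = len(trait)
    for module, eig in eigengenes.iterrows():
        r = float(np.corrcoef(eig.to_numpy(), trait)[0, 1])
        rows[module] = {"r": r, "p": corr_pvalue(r, n)}
    return pd.DataFrame(rows).T


def kme_gs(data: pd.DataFrame, eigengenes: pd.DataFrame, trait: np.ndarray
           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Module membership (kME) and trait significance (GS) per feature.

    Returns ``(kme, kme_p, gs, gs_p)``.  Constant features get NaN.
    """
    arr = data.to_numpy(dtype=float)
    n = arr.shape[1]
    trait = np.asarray(trait, dtype=float)

    def corr_with(vec: np.ndarray) -> np.ndarray:
        vc = vec - vec.mean()
        vs = vc.std()
        ac = arr - arr.mean(axis=1, keepdims=True)
        asd = ac.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac @ vc) / (arr.shape[1] * asd * vs)
        r[asd == 0] = np.nan
        return np.clip(r, -1.0, 1.0)

    kme = {}
    for module, eig in eigengenes.iterrows():
        kme[module] = corr_with(eig.to_numpy())
    kme = pd.DataFrame(kme, index=data.index)
    kme_p = kme.map(lambda r: corr_pvalue(r, n) if np.isfinite(r) else np.nan)
    gs_vals = corr_with(trait)
    gs = pd.Series(gs_vals, index=data.index, name="GS")
    gs_p = pd.Series([corr_pvalue(r, n) if np.isfinite(r) else np.nan
                      for r in gs_vals], index=data.index, name="GS_p")
    return kme, kme_p, gs, gs_p


@dataclass
class KeyDriverNetwork:
    module: str
    nodes: pd.DataFrame   # feature x (layer, log2fc, kme, gs, score, rank)
    edges: pd.DataFrame   # source, target, weight, emphasized


def select_key_drivers(labels: pd.Series, kme: pd.DataFrame, gs: pd.Series,
                       tom: pd.DataFrame, module: str,
                       log2fc: pd.Series | None = None,
                       n_key_drivers: int = 30,
                       edge_emphasis_threshold: float = 0.5,
                       warnings_out: list | None = None) -> KeyDriverNetwork:
    """Top-k module members by ``|kME| x |GS|`` with a connectivity network.

    Edge weights are the TOM among selected features rescaled by the
    module-wide off-diagonal TOM maximum; edges at or above
    ``edge_emphasis_threshold`` are flagged as emphasized.  Ties in the
    driver score break by feature ID.
    """
    members = list(labels.index[labels == module])
    if not members:
        raise ValueError(f"module {module!r} has no members")
    if len(members) < n_key_drivers and warnings_out is not None:
        warnings_out.append(
            f"module {module} has only {len(members)} members "
            f"(< n_key_drivers={n_key_drivers})")
    score = (kme.loc[members, module].abs() * gs.loc[members].abs()).fillna(0.0)
    ranked = sorted(members, key=lambda f: (-score[f], str(f)))
    top = ranked[:min(n_key_drivers, len(ranked))]

    module_tom = tom.loc[members, members].to_numpy(dtype=float).copy()
    np.fill_diagonal(module_tom, 0.0)
    tom_max = module_tom.max() if module_tom.size else 0.0

    nodes = pd.DataFrame(index=pd.Index(top, name="feature"))
    layers = []
    for f in top:
        try:
            layers.append(split_feature(str(f))[0])
        except ValueError:
            layers.append("unknown")
    nodes["layer"] = layers
    nodes["log2fc"] = (log2fc.reindex(top) if log2fc is not None else np.nan)
    nodes["kme"] = kme.loc[top, module]
    nodes["gs"] = gs.loc[top]
    nodes["score"] = score.loc[top]
    nodes["rank"] = np.arange(1, len(top) + 1)

    rows = []
    sub = tom.loc[top, top].to_numpy(dtype=float)
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            w = sub[i, j] / tom_max if tom_max > 0 else 0.0
            w = min(w, 1.0)
            rows.append({"source": top[i], "target": top[j], "weight": w,
                         "emphasized": w >= edge_emphasis_threshold})
    edges = pd.DataFrame(rows, columns=["source", "target", "weight",
                                        "emphasized"])
    return KeyDriverNetwork(module=module, nodes=nodes, edges=edges)


class WeightedCoabundanceNetwork(BaseEstimator):
    """Signed weighted co-abundance network with module detection.

    Parameters mirror the published analysis: ``soft_power=17``,
    ``min_module=50``, ``max_module=500``, ``deepsplit=2``,
    ``merge_cut=0.3``.

    ``fit(X, trait)`` takes a complete features x samples DataFrame (see
    :func:`build_feature_space`) and the per-sample ordinal trait.

    Fitted attributes
    -----------------
    labels_ : Series feature -> module color (``grey`` = unassigned)
    modules_ : dict module -> list of features
    eigengenes_ : DataFrame module x samples (unit norm rows)
    variance_explained_ : Series per module
    module_trait_ : DataFrame module x (r, p)
    kme_, kme_p_ : DataFrames feature x module
    gs_, gs_p_ : Series per feature
    tom_ : DataFrame feature x feature topological overlap
    warnings_ : list of str
    """

    def __init__(self, soft_power: int = 17, network_sign: str = "signed",
                 min_module: int = 50, max_module: int = 500,
                 deepsplit: int = 2, merge_cut: float = 0.3,
                 min_kme: float = 0.9, n_key_drivers: int = 30,
                 edge_emphasis_threshold: float = 0.5):
        self.soft_power = soft_power
        self.network_sign = network_sign
        self.min_module = min_module
        self.max_module = max_module
        self.deepsplit = deepsplit
        self.merge_cut = merge_cut
        self.min_kme = min_kme
        self.n_key_drivers = n_key_drivers
        self.edge_emphasis_threshold = edge_emphasis_threshold

    def fit(self, X: pd.DataFrame, trait=None) -> "WeightedCoabundanceNetwork":
        if self.network_sign not in ("signed", "unsigned"):
            raise ValueError("network_sign must be 'signed' or 'unsigned'")
        if X.isna().to_numpy().any():
            raise ValueError("network input must be complete (no missing values)")
        self.warnings_: list[str] = []
        signed = self.network_sign == "signed"
        adj = adjacency_matrix(X, beta=self.soft_power, signed=signed)
        self.tom_ = topological_overlap(adj)
        initial = detect_modules(self.tom_, self.min_module, self.max_module,
                                 self.deepsplit, self.warnings_)
        merged = merge_modules(X, initial, self.merge_cut, self.warnings_)
        self.labels_ = prune_by_kme(X, merged, self.min_kme, self.min_module,
                                    signed=signed,
                                    warnings_out=self.warnings_)
        modules = sorted(m for m in self.labels_.unique() if m != GREY)
        oversized = [m for m in modules
                     if (self.labels_ == m).sum() > self.max_module]
        for m in oversized:
            self.warnings_.append(
                f"module {m} exceeds max_module after merging "
                f"({int((self.labels_ == m).sum())} features)")
        self.modules_ = {m: list(self.labels_.index[self.labels_ == m])
                         for m in modules}
        eigs, varex = {}, {}
        for m in modules:
            eigs[m], varex[m] = module_eigengene(X.loc[self.modules_[m]],
                                                 self.warnings_)
        self.eigengenes_ = (pd.DataFrame(eigs).T.reindex(columns=X.columns)
                            if eigs else pd.DataFrame(columns=X.columns))
        self.variance_explained_ = pd.Series(varex, dtype=float)
        if trait is not None:
            trait = np.asarray(trait, dtype=float)
            if len(modules):
                self.module_trait_ = module_trait_statistics(self.eigengenes_,
                                                             trait)
            else:
                self.module_trait_ = pd.DataFrame(columns=["r", "p"])
            self.kme_, self.kme_p_, self.gs_, self.gs_p_ = kme_gs(
                X, self.eigengenes_, trait)
        self.data_ = X
        return self

    def strongest_module(self) -> str:
        """Module with the largest |module-trait correlation|."""
        if self.module_trait_.empty:
            raise ValueError("no modules detected")
        return self.module_trait_["r"].abs().idxmax()

    def key_drivers(self, module: str | None = None,
                    log2fc: pd.Series | None = None) -> KeyDriverNetwork:
        module = module or self.strongest_module()
        return select_key_drivers(
            self.labels_, self.kme_, self.gs_, self.tom_, module,
            log2fc=log2fc, n_key_drivers=self.n_key_drivers,
            edge_emphasis_threshold=self.edge_emphasis_threshold,
            warnings_out=self.warnings_)
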