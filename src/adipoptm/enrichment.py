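"""Over-representation analysis with pathway directionality.

A query list (proteins carrying significantly altered modification
sites) is tested against each gene set with the upper-tail
hypergeometric test over the layer's quantified-protein universe.  Sets
are retained when the overlap is at least ``min_overlap`` members, at
least ``min_fraction`` of the term, and the p-value passes ``alpha``
(raw p by default; BH-adjusted p is always reported alongside).

Directionality assigns each retained set the median log2 fold change of
all significantly changed sites whose parent protein belongs to the set;
two datasets' directions over their shared sets are compared with a
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import ContrastResult, adjust_bh
from .io import GeneSetCollection


def hypergeom_pvalue(overlap: int, query: int, term: int, universe: int) -> float:
    """Upper-tail ``P(X >= overlap)`` for hypergeometric(universe, term, query)."""
    if (not 0 <= overlap <= min(query, term) or term > universe
            or query > universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, query={query}, "
            f"term={term}, universe={universe}")
    return float(stats.hypergeom.sf(overlap - 1, universe, term, query))


@dataclass
class EnrichmentResult:
    table: pd.DataFrame      # retained sets: term_size, overlap, overlap_fraction, p, adj_p
    hits: dict               # set name -> sorted overlapping member IDs
    query_size: int
    universe_size: int
    filtered_out: pd.DataFrame  # sets failing a retention filter, with reason


def enrich(query, collection: GeneSetCollection, universe=None,
           min_overlap: int = 3, min_fraction: float = 0.04,
           alpha: float = 0.05, use_adjusted: bool = False) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``universe`` defaults to the collection's explicit universe and must
    contain the query.  Retention requires overlap >= ``min_overlap``,
    overlap/term size >= ``min_fraction`` and (raw or adjusted, per
    ``use_adjusted``) p < ``alpha``.  BH adjustment spans all nonempty
    terms, before retention filtering.
    """
    if universe is None:
        universe = collection.universe
    if not universe:
        raise ValueError("enrichment requires a non-empty universe")
    uni = set(universe)
    q = set(query) & uni
    stray = set(query) - uni
    if stray:
        raise ValueError(f"query members outside the universe: {sorted(stray)[:5]}")

    rows, hits = [], {}
    for name, members in collection.sets.items():
        term = set(members) & uni
        if not term:
            continue
        overlap = sorted(term & q)
        p = hypergeom_pvalue(len(overlap), len(q), len(term), len(uni))
        rows.append({"set": name, "term_size": len(term),
                     "overlap": len(overlap),
                     "overlap_fraction": len(overlap) / len(term), "p": p})
        hits[name] = overlap
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["term_size", "overlap", "overlap_fraction", "p"])
    if len(table):
        table["adj_p"] = adjust_bh(table["p"].to_numpy())
    else:
        table["adj_p"] = []

    gate = table["adj_p"] if use_adjusted else table["p"]
    reasons = pd.Series("", index=table.index, dtype=object)
    reasons[table["overlap"] < min_overlap] += "overlap<min;"
    reasons[table["overlap_fraction"] < min_fraction] += "fraction<min;"
    reasons[gate >= alpha] += "p>=alpha;"
    keep = reasons == ""
    filtered = table.loc[~keep].copy()
    filtered["reason"] = reasons[~keep]
    return EnrichmentResult(
        table=table.loc[keep].copy(),
        hits={k: v for k, v in hits.items() if keep.get(k, False)},
        query_size=len(q), universe_size=len(uni), filtered_out=filtered)


@dataclass
class PathwayDirection:
    """Median log2FC of significant sites per retained gene set."""

    table: pd.DataFrame   # set x (median_log2fc, n_sites, enrich_p)
    skipped: list         # retained sets with zero contributing sites


def pathway_direction(enrichment: EnrichmentResult,
                      site_contrast: ContrastResult,
                      site_parent: dict,
                      collection: GeneSetCollection) -> PathwayDirection:
    """Directionality of each enriched set: the median log2 fold change
    over *significant* sites whose parent protein is a set member."""
    sig = site_contrast.table[site_contrast.table["significant"]]
    fc_by_parent: dict[str, list[float]] = {}
    for site, fc in sig["log2fc"].items():
        parent = site_parent.get(site)
        if parent is not None:
            fc_by_parent.setdefault(parent, []).append(float(fc))
    rows, skipped = [], []
    for name in enrichment.table.index:
        members = set(collection.sets[name])
        fcs = [fc for prot in members for fc in fc_by_parent.get(prot, [])]
        if not fcs:
            skipped.append(name)
            continue
        rows.append({"set": name, "median_log2fc": float(np.median(fcs)),
                     "n_sites": len(fcs),
                     "enrich_p": float(enrichment.table.at[name, "p"])})
    table = (pd.DataFrame(rows).set_index("set") if rows
             else pd.DataFrame(columns=["median_log2fc", "n_sites", "enrich_p"]))
    return PathwayDirection(table=table, skipped=skipped)


def correlate_pathway_directions(dir_a: PathwayDirection,
                                 dir_b: PathwayDirection,
                                 alpha: float = 0.05
                                 ) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of two datasets' pathway directions.

    Returns ``(r, p, shared)`` where ``shared`` tabulates every gene set
    present in both inputs with both medians, both enrichment p-values
    and a flag for significant enrichment in at least one dataset.
    Requires >= 3 shared sets.
    """
    shared_sets = dir_a.table.index.intersection(dir_b.table.index)
    if len(shared_sets) < 3:
        raise ValueError(
            f"need >= 3 shared gene sets for correlation, got {len(shared_sets)}")
    a = dir_a.table.loc[shared_sets]
    b = dir_b.table.loc[shared_sets]
    x = a["median_log2fc"].to_numpy()
    y = b["median_log2fc"].to_numpy()
    if np.array_equal(x, y):
        r, p = 1.0, 0.0  # identical directions correlate perfectly
    elif np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r, p = (1.0, 0.0) if np.allclose(x - x.mean(), y - y.mean()) else (np.nan, np.nan)
    else:
        res = stats.pearsonr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
    shared = pd.DataFrame({
        "median_fc_a": a["median_log2fc"], "median_fc_b": b["median_log2fc"],
        "p_a": a["enrich_p"], "p_b": b["enrich_p"],
        "flagged": (a["enrich_p"] < alpha) | (b["enrich_p"] < alpha),
    })
    return r, p, shared
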