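"""PTM site identifiers and proteome-corrected site abundances.

Site IDs follow the ``<protein>_<residue><position>`` convention
(``FASN_K673``, ``CD44_S161``).  Lysine (K) sites are acetylation,
serine/threonine/tyrosine (S/T/Y) sites phosphorylation.

Proteome correction subtracts the parent protein's log2 abundance from
the site's log2 abundance per sample, so corrected values track
modification stoichiometry rather than protein amount.  Sites whose
parent protein was not quantified in the global proteome cannot be
corrected and are reported separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LOG2, IntensityMatrix

ACETYL = "acetyl"
PHOSPHO_MOD = "phospho"

_MOD_OF_RESIDUE = {"K": ACETYL, "S": PHOSPHO_MOD, "T": PHOSPHO_MOD,
                   "Y": PHOSPHO_MOD}

_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[KSTY])(?P<position>\d+)$")


@dataclass(frozen=True)
class PTMSite:
    protein_id: str
    residue: str
    position: int
    modification: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        expected = _MOD_OF_RESIDUE.get(self.residue)
        if expected is None:
            raise ValueError(f"residue must be one of K/S/T/Y, got {self.residue!r}")
        if self.modification != expected:
            raise ValueError(
                f"residue {self.residue} implies {expected}, got {self.modification!r}")

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}_{self.residue}{self.position}"


def parse_site_id(text: str) -> PTMSite:
    """Parse ``<protein>_<residue><position>`` into a :class:`PTMSite`.

    >>> parse_site_id("FASN_K673").modification
    'acetyl'
    """
    match = _SITE_RE.match(text)
    if not match:
        raise ValueError(
            f"malformed site ID {text!r}: expected <protein>_<K|S|T|Y><position>")
    protein, residue = match["protein"], match["residue"]
    position = int(match["position"])
    return PTMSite(protein, residue, position, _MOD_OF_RESIDUE[residue])


@dataclass
class CorrectedSiteMatrix:
    """Proteome-corrected site abundances plus the sites that could not
    be matched to a quantified protein."""

    matrix: IntensityMatrix
    site_parent: dict
    unmatched: list


class ProteomeCorrector(BaseEstimator, TransformerMixin):
    """Subtract parent-protein log2 abundance from site log2 abundance.

    The matching key is the protein accession parsed from the site ID
    (``site_parent`` may override the parse).  Correction happens per
    sample before any averaging, which makes corrected fold changes
    exactly the difference of raw-site and protein fold changes.
    """

    def __init__(self, proteome: IntensityMatrix | None = None,
                 site_parent: dict | None = None):
        self.proteome = proteome
        self.site_parent = site_parent

    def fit(self, X: IntensityMatrix, y=None) -> "ProteomeCorrector":
        if self.proteome is None:
            raise ValueError("ProteomeCorrector requires the global proteome")
        if self.proteome.scale != LOG2 or X.scale != LOG2:
            raise ValueError("both matrices must be on the log2 scale")
        if list(X.sample_ids) != list(self.proteome.sample_ids):
            raise ValueError(
                "sample sets differ between site matrix and proteome: "
                f"{X.sample_ids} vs {self.proteome.sample_ids}")
        parents = {}
        for site in X.feature_ids:
            if self.site_parent and site in self.site_parent:
                parents[site] = self.site_parent[site]
            else:
                parents[site] = parse_site_id(site).protein_id
        quantified = set(self.proteome.feature_ids)
        self.parent_of_ = parents
        self.matched_ = [s for s in X.feature_ids if parents[s] in quantified]
        self.unmatched_ = [s for s in X.feature_ids if parents[s] not in quantified]
        return self

    def transform(self, X: IntensityMatrix) -> CorrectedSiteMatrix:
        site_vals = X.values.loc[self.matched_]
        parent_rows = self.proteome.values.loc[
            [self.parent_of_[s] for s in self.matched_]]
        parent_rows.index = self.matched_
        corrected = site_vals - parent_rows  # NaN wherever either is missing
        return CorrectedSiteMatrix(
            matrix=IntensityMatrix(corrected, LOG2),
            site_parent={s: self.parent_of_[s] for s in self.matched_},
            unmatched=list(self.unmatched_),
        )


def correct_sites(site_matrix: IntensityMatrix, proteome: IntensityMatrix,
                  site_parent: dict | None = None) -> CorrectedSiteMatrix:
    """Proteome-correct a site matrix against the global proteome."""
    corr = ProteomeCorrector(proteome, site_parent=site_parent).fit(site_matrix)
    return corr.transform(site_matrix)


def unmatched_report(result: CorrectedSiteMatrix) -> pd.DataFrame:
    return pd.DataFrame({"site_id": result.unmatched,
                         "reason": "parent protein not quantified"})
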