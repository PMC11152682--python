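"""Run configuration: one flat YAML mapping of ``key: value`` pairs.

Defaults reproduce the published analysis parameters: soft power 17,
module size bounds 50/500, deepsplit 2, eigengene merge cut height 0.3,
site-level significance at adjusted p < 0.01, and over-representation
retention filters (overlap >= 3, >= 4 % of the term, p < 0.05).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Validated parameter record for an analysis run."""

    # --- statistics ---
    site_alpha: float = 0.01          # adjusted-p threshold for PTM sites
    protein_alpha: float = 0.01       # adjusted-p threshold for proteins
    equal_variance: bool = True       # classic Student t (False -> Welch)

    # --- over-representation analysis ---
    enrich_min_overlap: int = 3       # minimum cluster size
    enrich_min_fraction: float = 0.04 # overlap / term size
    enrich_alpha: float = 0.05
    enrich_use_adjusted: bool = False # gate retention on raw p by default

    # --- network ---
    soft_power: int = 17
    network_sign: str = "signed"      # "signed" | "unsigned"
    min_module: int = 50
    max_module: int = 500
    deepsplit: int = 2
    merge_cut: float = 0.3
    min_kme: float = 0.9      # membership pruning threshold after merging
    n_key_drivers: int = 30
    edge_emphasis_threshold: float = 0.5

    # --- preprocessing ---
    glog_shift_quantile: float = 0.01
    impute_shift: float = 1.8         # downshift, in sample SDs
    impute_width: float = 0.3         # imputation SD, in sample SDs
    impute_layers: tuple = ("proteome", "acetylome")  # LFQ layers only

    # --- pipeline inputs (paths; unused by library-level calls) ---
    proteome: str | None = None
    acetylome: str | None = None
    phospho: str | None = None
    design: str | None = None
    genesets: str | None = None
    proteome_scale: str = "log2"
    acetylome_scale: str = "log2"
    phospho_scale: str = "log2"

    seed: int = 0
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in ("site_alpha", "protein_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.merge_cut <= 1:
            raise ValueError(f"merge_cut must be in [0, 1], got {self.merge_cut}")
        if self.soft_power < 1 or int(self.soft_power) != self.soft_power:
            raise ValueError(f"soft_power must be an integer >= 1, got {self.soft_power}")
        if self.network_sign not in ("signed", "unsigned"):
            raise ValueError(f"network_sign must be 'signed' or 'unsigned'")
        if not 0 <= self.deepsplit <= 4:
            raise ValueError(f"deepsplit must be in 0..4, got {self.deepsplit}")
        if self.min_module < 1 or self.max_module < self.min_module:
            raise ValueError("require 1 <= min_module <= max_module")
        if self.n_key_drivers < 1:
            raise ValueError("n_key_drivers must be >= 1")
        if not 0 <= self.min_kme <= 1:
            raise ValueError("min_kme must be in [0, 1]")
        if not 0 <= self.edge_emphasis_threshold <= 1:
            raise ValueError("edge_emphasis_threshold must be in [0, 1]")
        if not 0 <= self.enrich_min_fraction <= 1:
            raise ValueError("enrich_min_fraction must be in [0, 1]")
        if self.enrich_min_overlap < 0:
            raise ValueError("enrich_min_overlap must be >= 0")
        if not 0 <= self.glog_shift_quantile < 1:
            raise ValueError("glog_shift_quantile must be in [0, 1)")
        if self.impute_shift < 0 or self.impute_width <= 0:
            raise ValueError("impute_shift >= 0 and impute_width > 0 required")

    def hash(self) -> str:
        """Stable short hash of the full parameter record."""
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig) if f.name != "extra"}


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a flat ``key: value`` YAML configuration file.

    Missing keys take the published defaults; unknown keys raise a
    warning and are kept under ``extra``; values of the wrong type or
    outside their valid range raise ``ValueError``.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: run config must be a flat key: value mapping")
    kwargs: dict = {}
    extra: dict = {}
    for key, value in raw.items():
        if key not in _FIELDS:
            warnings.warn(f"{path}: unknown config key {key!r} ignored", stacklevel=2)
            extra[key] = value
            continue
        kwargs[key] = _coerce(key, value, path)
    return RunConfig(extra=extra, **kwargs)


def _coerce(key: str, value, path):
    expected = _FIELDS[key].type
    if value is None:
        return None
    if expected in ("int",) or key in ("soft_power", "min_module", "max_module",
                                       "deepsplit", "n_key_drivers", "seed",
                                       "enrich_min_overlap"):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValueError(f"{path}: config key {key!r} must be an integer, got {value!r}")
        return value
    if key in ("equal_variance", "enrich_use_adjusted"):
        if not isinstance(value, bool):
            raise ValueError(f"{path}: config key {key!r} must be a boolean, got {value!r}")
        return value
    if key == "impute_layers":
        if isinstance(value, str):
            value = [value]
        if not isinstance(value, (list, tuple)):
            raise ValueError(f"{path}: config key {key!r} must be a list of layer names")
        return tuple(value)
    if isinstance(value, bool):
        raise ValueError(f"{path}: config key {key!r} must not be a boolean")
    if isinstance(value, (int, float)) and key in (
            "site_alpha", "protein_alpha", "enrich_alpha", "merge_cut",
            "edge_emphasis_threshold", "enrich_min_fraction", "min_kme",
            "glog_shift_quantile", "impute_shift", "impute_width"):
        return float(value)
    return value
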