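"""One-command orchestration: filter -> normalize -> correct -> impute ->
contrasts -> enrichment/direction -> network -> key drivers.

Every run writes a complete results bundle into one directory plus a
``manifest.json`` recording the config hash, input hashes, seed, stage
timings, output list and warnings.  The manifest is written even when a
stage fails (recording the failure point); all other outputs are
deterministic given config + seed, so re-runs into fresh directories are
byte-identical except for the timing fields of the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, load_run_config
from .diffabund import compute_contrast, percent_significant, standard_contrasts
from .enrichment import enrich, pathway_direction
from .io import (GeneSetCollection, IntensityMatrix, read_design, read_gmt,
                 read_intensity_table)
from .layers import ACETYLOME, LAYERS, PHOSPHO, PROTEOME
from .network import WeightedCoabundanceNetwork, build_feature_space
from .preprocess import filter_by_presence, impute_noise, normalize_and_transform
from .ptm import CorrectedSiteMatrix, correct_sites, unmatched_report

log = logging.getLogger("adipoptm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    input_hashes: dict = field(default_factory=dict)
    stage_timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        payload = {
            "tool": f"adipoptm {__version__}",
            "config_hash": self.config_hash,
            "seed": self.seed,
            "input_hashes": self.input_hashes,
            "stage_timings": self.stage_timings,
            "outputs": sorted(self.outputs),
            "warnings": self.warnings,
            "failed_stage": self.failed_stage,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _layer_seed(seed: int, layer: str) -> int:
    return (seed * 1000003 + zlib.crc32(layer.encode())) % (2**31)


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the full analysis described by ``config`` into ``out_dir``."""
    if not isinstance(config, RunConfig):
        config = load_run_config(config)
    seed = config.seed if seed is None else seed
    out = Path(out_dir)

    # validate inputs up front: a missing file must not leave partial output
    inputs = {"proteome": config.proteome, "acetylome": config.acetylome,
              "phospho": config.phospho, "design": config.design,
              "genesets": config.genesets}
    missing = [k for k, v in inputs.items() if not v or not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seed=seed,
                           input_hashes={k: _file_hash(v)
                                         for k, v in inputs.items()})
    prov = f"adipoptm {__version__} seed={seed} config={config.hash()}"

    def save(frame: pd.DataFrame, name: str, index_label: str = "feature"):
        path = out / name
        with open(path, "w") as handle:
            handle.write(f"# {prov}\n")
            frame.rename_axis(index_label).to_csv(handle, sep="\t")
        manifest.outputs.append(name)

    stage = "read_inputs"
    try:
        t0 = time.perf_counter()
        design = read_design(config.design)
        matrices = {
            PROTEOME: read_intensity_table(config.proteome, config.proteome_scale),
            ACETYLOME: read_intensity_table(config.acetylome, config.acetylome_scale),
            PHOSPHO: read_intensity_table(config.phospho, config.phospho_scale),
        }
        genesets = read_gmt(config.genesets)
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "normalize"
        t0 = time.perf_counter()
        for layer in LAYERS:
            if matrices[layer].scale == "raw":
                matrices[layer] = normalize_and_transform(
                    matrices[layer], config.glog_shift_quantile)
                log.info("normalized %s (raw -> log2)", layer)
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "presence_filter"
        t0 = time.perf_counter()
        for layer in LAYERS:
            before = len(matrices[layer].feature_ids)
            matrices[layer], _mask = filter_by_presence(matrices[layer], design)
            log.info("%s: %d of %d features pass the replicate-presence "
                     "filter", layer, len(matrices[layer].feature_ids), before)
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "proteome_correction"
        t0 = time.perf_counter()
        corrected: dict[str, CorrectedSiteMatrix] = {}
        for layer in (ACETYLOME, PHOSPHO):
            corrected[layer] = correct_sites(matrices[layer], matrices[PROTEOME])
            log.info("%s: %d sites corrected, %d unmatched", layer,
                     len(corrected[layer].matrix.feature_ids),
                     len(corrected[layer].unmatched))
            save(unmatched_report(corrected[layer]).set_index("site_id"),
                 f"unmatched_{layer}.tsv", index_label="site_id")
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "impute"
        t0 = time.perf_counter()
        analysis: dict[str, IntensityMatrix] = {PROTEOME: matrices[PROTEOME]}
        parents: dict[str, dict] = {}
        for layer in (ACETYLOME, PHOSPHO):
            analysis[layer] = corrected[layer].matrix
            parents[layer] = corrected[layer].site_parent
        block_imputed: dict[str, set] = {layer: set() for layer in LAYERS}
        for layer in LAYERS:
            if layer in config.impute_layers:
                analysis[layer], implog = impute_noise(
                    analysis[layer], design, _layer_seed(seed, layer),
                    shift=config.impute_shift, width=config.impute_width)
                save(implog.set_index("feature"), f"imputation_log_{layer}.tsv")
                block_imputed[layer] = set(
                    implog.loc[implog["reason"] == "block", "feature"])
                log.info("%s: imputed %d cells", layer, len(implog))
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "contrasts"
        t0 = time.perf_counter()
        contrasts = standard_contrasts(design)
        results: dict[str, dict] = {}
        for layer in LAYERS:
            alpha = (config.protein_alpha if layer == PROTEOME
                     else config.site_alpha)
            results[layer] = {}
            for contrast in contrasts:
                res = compute_contrast(analysis[layer], design, contrast,
                                       alpha=alpha,
                                       equal_var=config.equal_variance)
                results[layer][contrast.name] = res
                save(res.table, f"contrast_{layer}_{contrast.name}.tsv")
                log.info("%s %s: %d/%d significant (adj p < %g)", layer,
                         contrast.name, res.n_significant, res.n_tested, alpha)
        pct = percent_significant(results)
        save(pct, "percent_significant.tsv", index_label="layer")
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "enrichment"
        t0 = time.perf_counter()
        directions = {}
        for layer in (ACETYLOME, PHOSPHO):
            universe = sorted(set(parents[layer].values()))
            complete = results[layer]["complete" if "complete" in results[layer]
                                      else next(iter(results[layer]))]
            query = sorted({parents[layer][s]
                            for s in complete.significant_features})
            if not query:
                manifest.warnings.append(
                    f"{layer}: no significant sites; enrichment skipped")
                continue
            enr = enrich(query, genesets, universe,
                         min_overlap=config.enrich_min_overlap,
                         min_fraction=config.enrich_min_fraction,
                         alpha=config.enrich_alpha,
                         use_adjusted=config.enrich_use_adjusted)
            save(enr.table, f"enrichment_{layer}_complete.tsv",
                 index_label="set")
            direction = pathway_direction(enr, complete, parents[layer],
                                          genesets)
            directions[layer] = direction
            save(direction.table, f"pathway_direction_{layer}_complete.tsv",
                 index_label="set")
            log.info("%s: %d sets retained, %d with direction", layer,
                     len(enr.table), len(direction.table))
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "network"
        t0 = time.perf_counter()
        # imputed whole-condition blocks are synthetic values with no real
        # time-course information; their shared downshift at censored
        # stages would seed artifactual trait-correlated modules, so these
        # features stay out of the network (they remain in the contrasts)
        complete_only = {}
        for layer in LAYERS:
            m = analysis[layer]
            keep = m.values.dropna(axis=0)
            keep = keep.loc[[f for f in keep.index
                             if f not in block_imputed[layer]]]
            dropped = len(m.values) - len(keep)
            if dropped:
                manifest.warnings.append(
                    f"{layer}: {dropped} incomplete or block-imputed features "
                    "excluded from the network")
            complete_only[layer] = IntensityMatrix(keep, "log2")
        combined = build_feature_space(complete_only[PROTEOME],
                                       complete_only[ACETYLOME],
                                       complete_only[PHOSPHO])
        trait = (design.set_index("sample_id")
                 .loc[list(combined.columns), "time_code"]
                 .to_numpy(dtype=float))
        net = WeightedCoabundanceNetwork(
            soft_power=config.soft_power, network_sign=config.network_sign,
            min_module=config.min_module, max_module=config.max_module,
            deepsplit=config.deepsplit, merge_cut=config.merge_cut,
            min_kme=config.min_kme, n_key_drivers=config.n_key_drivers,
            edge_emphasis_threshold=config.edge_emphasis_threshold,
        ).fit(combined, trait)
        manifest.warnings.extend(net.warnings_)
        assignment = pd.DataFrame({
            "module": net.labels_,
            "gs": net.gs_, "gs_p": net.gs_p_,
        })
        for m in net.modules_:
            assignment[f"kme_{m}"] = net.kme_[m]
        save(assignment, "module_assignment.tsv")
        save(net.eigengenes_, "module_eigengenes.tsv", index_label="module")
        save(net.module_trait_, "module_trait.tsv", index_label="module")
        log.info("network: %d modules (+grey), sizes %s",
                 len(net.modules_),
                 {m: len(f) for m, f in net.modules_.items()})
        manifest.stage_timings[stage] = time.perf_counter() - t0

        stage = "key_drivers"
        t0 = time.perf_counter()
        # complete-contrast log2FCs on the prefixed feature space
        from .layers import prefix_feature
        fc_parts = []
        for layer in LAYERS:
            t = results[layer]["complete"].table["log2fc"]
            t = t.rename(index=lambda f, L=layer: prefix_feature(L, f))
            fc_parts.append(t)
        complete_fc = pd.concat(fc_parts)
        if not net.module_trait_.empty:
            by_r = net.module_trait_["r"]
            chosen = []
            if (by_r > 0).any():
                chosen.append(by_r.idxmax())
            if (by_r < 0).any():
                chosen.append(by_r.idxmin())
            for module in chosen:
                kd = net.key_drivers(module=module, log2fc=complete_fc)
                save(kd.nodes, f"key_drivers_{module}_nodes.tsv")
                save(kd.edges.set_index("source"),
                     f"key_drivers_{module}_edges.tsv", index_label="source")
                log.info("key drivers of %s: %d features", module,
                         len(kd.nodes))
        manifest.stage_timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.warnings.append(f"stage {stage} failed: {exc}")
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, exc) from exc

    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
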