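"""Synthetic multi-omics time courses with planted ground truth.

The generator emulates the statistical structure of a differentiation
experiment measured at three stages (preadipocyte, immature, mature; 3
replicates each) on three layers: a global proteome, an acetylome and a
phosphoproteome whose site intensities ride on their parent proteins.
Every downstream stage of the pipeline — proteome correction, staged
contrasts, directional enrichment, co-abundance modules and key drivers —
has exact planted truth here.

Construction, per feature and sample, on the log2 scale::

    protein  = baseline + module_pattern + noise
    site     = protein + site_offset + site_pattern + site_noise

* ``baseline`` is Gaussian in log2 (log-normal raw intensities),
* ``module_pattern`` plants co-abundance modules: a trait component
  (sign x amplitude x centered time code) plus a module-specific sample
  pattern orthogonal to the trait, so same-signed modules stay separable
  under the eigengene merge step,
* ``site_pattern`` plants site-specific effects: module membership for a
  subset of sites and, for acetyl sites of gene-set member proteins, a
  per-set direction x amplitude trend that survives proteome correction,
* missingness combines abundance-dependent censoring (whole condition
  blocks of the lowest-intensity features, strongest at the earliest
  stage — detection increases with maturation) with a small sporadic
  rate.

Two "cell lines" share all structural choices (feature universe, module
membership, gene sets) but draw independent noise; gene-set effect
directions agree between the lines for a configurable fraction of sets
(``geneset_concordance``).

All randomness derives from ``SimulationConfig.seed``; sub-streams are
spawned deterministically per purpose and per line, so identical configs
give bit-identical datasets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GeneSetCollection, IntensityMatrix, write_design, write_gmt,
                 write_intensity_table)
from .layers import ACETYLOME, PHOSPHO, PROTEOME, prefix_feature

DEFAULT_CONDITIONS = ("preadipocyte", "immature", "mature")

#: default planted modules: (name, n_features, trait sign, amplitude in log2)
DEFAULT_MODULES = (
    ("turquoise", 150, +1, 1.75),
    ("blue", 120, -1, 1.75),
    ("brown", 90, +1, 1.75),
    ("yellow", 70, -1, 1.75),
)

# share of each planted module drawn from each layer
_MODULE_LAYER_SPLIT = {PROTEOME: 0.7, ACETYLOME: 0.2, PHOSPHO: 0.1}

# default scale of the module-specific, trait-orthogonal pattern
# component, relative to the module amplitude; keeps same-signed module
# eigengenes dissimilar enough to survive the merge step
DEFAULT_ORTH_SCALE = 0.6

CONTRASTS = {"early": (1, 0), "late": (2, 1), "complete": (2, 0)}


@dataclass
class ModuleSpec:
    name: str
    n_features: int
    sign: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, +1):
            raise ValueError(f"module {self.name}: trait sign must be -1 or +1, "
                             f"got {self.sign}")
        if self.n_features < 1:
            raise ValueError(f"module {self.name}: n_features must be >= 1")
        if self.amplitude < 0:
            raise ValueError(f"module {self.name}: amplitude must be >= 0")


@dataclass
class SimulationConfig:
    n_proteins: int = 600
    ptm_sites_per_protein: float = 0.8   # Poisson mean, per PTM layer
    n_conditions: int = 3
    n_replicates: int = 3
    module_spec: tuple = DEFAULT_MODULES
    noise_sd: float = 0.5                # log2 units
    missing_low_quantile: float = 0.10   # condition-wise all-or-none censoring
    sporadic_missing_rate: float = 0.02
    n_genesets: int = 12
    geneset_size_range: tuple = (8, 12)
    geneset_amplitude: float = 2.0       # per-set slope in log2 per time step
    geneset_concordance: float = 1.0
    lines: tuple = ("SGBS", "3T3L1")
    baseline_mean: float = 25.0          # log2
    baseline_sd: float = 2.0
    site_offset_mean: float = -2.0       # sites less abundant than parents
    site_offset_sd: float = 1.0
    module_orth_scale: float = DEFAULT_ORTH_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_conditions, self.n_replicates,
               self.n_genesets) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("missing_low_quantile", "sporadic_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.geneset_concordance <= 1:
            raise ValueError("geneset_concordance must be in [0, 1]")
        if self.ptm_sites_per_protein < 0:
            raise ValueError("ptm_sites_per_protein must be >= 0")
        if self.module_orth_scale < 0:
            raise ValueError("module_orth_scale must be >= 0")
        if len(self.lines) != 2 or len(set(self.lines)) != 2:
            raise ValueError("exactly two distinct line names required")
        lo, hi = self.geneset_size_range
        if lo < 3 or hi < lo:
            raise ValueError("geneset sizes must satisfy 3 <= lo <= hi")
        self.module_spec = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m)
            for m in self.module_spec)
        names = [m.name for m in self.module_spec]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")


@dataclass
class Truth:
    """Planted ground truth for one generated line."""

    module_of: pd.Series                 # prefixed feature -> module ("grey" = none)
    module_sign: dict                    # module -> +1/-1
    log2fc: dict                         # layer -> DataFrame feature x contrast (raw matrix)
    corrected_log2fc: dict               # PTM layer -> DataFrame site x contrast
    geneset_members: dict                # set name -> list of protein IDs
    geneset_direction: pd.DataFrame      # set x line -> +1/-1
    geneset_amplitude: pd.Series         # set -> log2 slope per time step


@dataclass
class SyntheticDataset:
    line: str
    proteome: IntensityMatrix
    acetylome: IntensityMatrix
    phospho: IntensityMatrix
    site_parent: dict                    # site ID -> protein ID (both PTM layers)
    design: pd.DataFrame
    truth: Truth
    config: SimulationConfig = field(repr=False, default=None)

    def layer(self, name: str) -> IntensityMatrix:
        return {PROTEOME: self.proteome, ACETYLOME: self.acetylome,
                PHOSPHO: self.phospho}[name]


def _stream(config: SimulationConfig, *key) -> np.random.Generator:
    """Deterministic named RNG sub-stream."""
    ints = [config.seed & 0x7FFFFFFF]
    for part in key:
        if isinstance(part, str):
            ints.append(zlib.crc32(part.encode()))
        else:
            ints.append(int(part))
    return np.random.default_rng(np.random.SeedSequence(ints))


def _centered_time(n_conditions: int) -> np.ndarray:
    t = np.arange(n_conditions, dtype=float)
    return t - t.mean()


def _condition_names(n: int) -> list[str]:
    if n == len(DEFAULT_CONDITIONS):
        return list(DEFAULT_CONDITIONS)
    return [f"stage{i}" for i in range(n)]


def make_design(config: SimulationConfig, line: str) -> pd.DataFrame:
    conds = _condition_names(config.n_conditions)
    rows = [
        {"sample_id": f"{line}_{cond}_r{rep}", "condition": cond,
         "time_code": t, "replicate": rep}
        for t, cond in enumerate(conds)
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


class _Structure:
    """Line-independent structural choices derived from the seed."""

    def __init__(self, config: SimulationConfig):
        c = config
        rng = _stream(c, "structure")
        self.proteins = [f"P{i:05d}" for i in range(1, c.n_proteins + 1)]
        self.baseline = pd.Series(
            rng.normal(c.baseline_mean, c.baseline_sd, c.n_proteins),
            index=self.proteins)

        # --- PTM sites per layer ---------------------------------------
        self.sites: dict[str, dict[str, str]] = {}  # layer -> site -> parent
        for layer, residues in ((ACETYLOME, "K"), (PHOSPHO, "STY")):
            site_map: dict[str, str] = {}
            counts = rng.poisson(c.ptm_sites_per_protein, c.n_proteins)
            for prot, k in zip(self.proteins, counts):
                positions = rng.choice(np.arange(1, 801), size=max(k, 0),
                                       replace=False) if k else []
                for pos in sorted(int(p) for p in positions):
                    res = residues[rng.integers(len(residues))]
                    site_map[f"{prot}_{res}{pos}"] = prot
            self.sites[layer] = site_map

        # --- protein pools: modules | gene sets | background ------------
        order = list(rng.permutation(self.proteins))
        modules = list(c.module_spec)
        self.module_layer_counts: dict[str, dict[str, int]] = {}
        n_module_prot = 0
        for m in modules:
            n_p = int(round(m.n_features * _MODULE_LAYER_SPLIT[PROTEOME]))
            n_a = int(round(m.n_features * _MODULE_LAYER_SPLIT[ACETYLOME]))
            n_pp = m.n_features - n_p - n_a
            self.module_layer_counts[m.name] = {
                PROTEOME: n_p, ACETYLOME: n_a, PHOSPHO: n_pp}
            n_module_prot += n_p
        sizes = rng.integers(c.geneset_size_range[0],
                             c.geneset_size_range[1] + 1, c.n_genesets)
        n_geneset_prot = int(sizes.sum())
        if n_module_prot + n_geneset_prot > c.n_proteins:
            raise ValueError(
                f"module ({n_module_prot}) + gene-set ({n_geneset_prot}) proteins "
                f"exceed n_proteins ({c.n_proteins})")

        cursor = 0
        self.module_proteins: dict[str, list[str]] = {}
        for m in modules:
            k = self.module_layer_counts[m.name][PROTEOME]
            self.module_proteins[m.name] = order[cursor:cursor + k]
            cursor += k
        self.geneset_members: dict[str, list[str]] = {}
        for i, size in enumerate(sizes, start=1):
            self.geneset_members[f"GS{i:03d}"] = sorted(order[cursor:cursor + size])
            cursor += int(size)
        self.background = order[cursor:]

        # every gene-set member carries at least one acetyl site so the
        # planted set direction is observable on the corrected acetylome
        ack = self.sites[ACETYLOME]
        taken_pos = {p: {int(s.split("_")[-1][1:]) for s, q in ack.items() if q == p}
                     for p in self.proteins}
        for members in self.geneset_members.values():
            for prot in members:
                if not taken_pos[prot]:
                    pos = int(rng.integers(1, 801))
                    ack[f"{prot}_K{pos}"] = prot
                    taken_pos[prot].add(pos)

        # --- module sites: drawn from sites of *background* proteins so the
        # planted pattern survives proteome correction -------------------
        bg = set(self.background)
        self.module_sites: dict[str, dict[str, list[str]]] = {}
        for layer in (ACETYLOME, PHOSPHO):
            pool = sorted(s for s, p in self.sites[layer].items() if p in bg)
            pool = list(rng.permutation(pool))
            for m in modules:
                need = self.module_layer_counts[m.name][layer]
                if len(pool) < need:
                    raise ValueError(
                        f"not enough background {layer} sites to plant module "
                        f"{m.name}: need {need}, have {len(pool)} "
                        "(increase n_proteins or ptm_sites_per_protein)")
                chosen, pool = pool[:need], pool[need:]
                self.module_sites.setdefault(m.name, {})[layer] = chosen

        # --- module sample patterns -------------------------------------
        z_cond = _centered_time(c.n_conditions)
        z = np.repeat(z_cond, c.n_replicates)
        self.trait = z
        # one trait-orthogonal *condition-level* direction per sign group
        # (constant within condition, so it never inflates replicate
        # variance); modules within a sign group alternate +/- so
        # same-signed eigengenes stay dissimilar under the merge step
        orth: dict[int, np.ndarray] = {}
        for sign in (+1, -1):
            g = rng.normal(size=c.n_conditions)
            g -= g.mean()
            if z_cond @ z_cond > 0:
                g -= (g @ z_cond) / (z_cond @ z_cond) * z_cond
            sd = g.std(ddof=0)
            orth[sign] = (g / sd if sd > 1e-9 else np.zeros_like(g))
        self.module_pattern: dict[str, np.ndarray] = {}
        seen_per_sign = {+1: 0, -1: 0}
        for m in modules:
            flip = 1 if seen_per_sign[m.sign] % 2 == 0 else -1
            seen_per_sign[m.sign] += 1
            self.module_pattern[m.name] = (
                m.sign * m.amplitude * z
                + flip * c.module_orth_scale * m.amplitude
                * np.repeat(orth[m.sign], c.n_replicates))

        # --- gene-set directions and amplitudes --------------------------
        base_dir = rng.choice([-1, 1], size=c.n_genesets)
        n_concordant = int(round(c.geneset_concordance * c.n_genesets))
        concordant = np.zeros(c.n_genesets, dtype=bool)
        concordant[list(rng.permutation(c.n_genesets))[:n_concordant]] = True
        names = list(self.geneset_members)
        self.geneset_direction = pd.DataFrame(
            {c.lines[0]: base_dir,
             c.lines[1]: np.where(concordant, base_dir, -base_dir)},
            index=names)
        self.geneset_amplitude = pd.Series(
            c.geneset_amplitude * rng.uniform(0.75, 1.25, c.n_genesets),
            index=names)
        geneset_prots = {p for m in self.geneset_members.values() for p in m}
        effect_sites = [s for s, p in self.sites[ACETYLOME].items()
                        if p in geneset_prots]
        self.geneset_site_wiggle = pd.Series(
            rng.normal(0.0, 0.7 * c.geneset_amplitude, len(effect_sites)),
            index=effect_sites)

        self.site_offsets = {
            layer: pd.Series(
                rng.normal(c.site_offset_mean, c.site_offset_sd,
                           len(self.sites[layer])),
                index=list(self.sites[layer]))
            for layer in (ACETYLOME, PHOSPHO)
        }


def _module_of_frame(structure: _Structure, config: SimulationConfig) -> pd.Series:
    labels: dict[str, str] = {}
    for p in structure.proteins:
        labels[prefix_feature(PROTEOME, p)] = "grey"
    for layer in (ACETYLOME, PHOSPHO):
        for s in structure.sites[layer]:
            labels[prefix_feature(layer, s)] = "grey"
    for m in config.module_spec:
        for p in structure.module_proteins[m.name]:
            labels[prefix_feature(PROTEOME, p)] = m.name
        for layer in (ACETYLOME, PHOSPHO):
            for s in structure.module_sites[m.name][layer]:
                labels[prefix_feature(layer, s)] = m.name
    return pd.Series(labels, name="module")


def generate_dataset(config: SimulationConfig, line: str | None = None) -> SyntheticDataset:
    """Generate one cell line's three-layer dataset with planted truth.

    The structural draw (features, modules, gene sets, patterns) depends
    only on the seed and is shared between lines; noise and missingness
    use line-specific sub-streams.
    """
    c = config
    line = line or c.lines[0]
    if line not in c.lines:
        raise ValueError(f"unknown line {line!r}; config lines are {c.lines}")
    st = _Structure(c)
    design = make_design(c, line)
    samples = list(design["sample_id"])
    n_samples = len(samples)
    t_of_sample = design["time_code"].to_numpy()
    z_cond = _centered_time(c.n_conditions)

    noise_rng = _stream(c, "noise", line)
    sporadic_rng = _stream(c, "sporadic", line)

    # --- proteome signal ------------------------------------------------
    prot_signal = np.tile(st.baseline.to_numpy()[:, None], (1, n_samples))
    prot_pattern = np.zeros((c.n_proteins, n_samples))
    prot_index = {p: i for i, p in enumerate(st.proteins)}
    for m in c.module_spec:
        rows = [prot_index[p] for p in st.module_proteins[m.name]]
        prot_pattern[rows] += st.module_pattern[m.name][None, :]
    prot_values = prot_signal + prot_pattern + noise_rng.normal(
        0, c.noise_sd, prot_pattern.shape)

    # --- PTM layers -----------------------------------------------------
    direction = st.geneset_direction[line]
    layer_values: dict[str, np.ndarray] = {}
    site_patterns: dict[str, np.ndarray] = {}
    site_lists: dict[str, list[str]] = {}
    for layer in (ACETYLOME, PHOSPHO):
        sites = list(st.sites[layer])
        site_lists[layer] = sites
        pattern = np.zeros((len(sites), n_samples))
        site_index = {s: i for i, s in enumerate(sites)}
        for m in c.module_spec:
            rows = [site_index[s] for s in st.module_sites[m.name][layer]]
            pattern[rows] += st.module_pattern[m.name][None, :]
        if layer == ACETYLOME:
            zt = z_cond[t_of_sample]
            # quadratic-in-time contrast: constant within condition,
            # orthogonal to the linear trait, zero net complete-contrast
            # effect — de-correlates gene-set sites from the planted
            # modules without touching replicate variance
            q_cond = z_cond ** 2 - np.mean(z_cond ** 2)
            denom = z_cond @ z_cond
            if denom > 0:
                q_cond = q_cond - (q_cond @ z_cond) / denom * z_cond
            qt = q_cond[t_of_sample]
            for gs, members in st.geneset_members.items():
                slope = direction[gs] * st.geneset_amplitude[gs]
                rows = [site_index[s] for s, p in st.sites[layer].items()
                        if p in set(members)]
                wiggle = st.geneset_site_wiggle.reindex(
                    [sites[i] for i in rows]).to_numpy()
                pattern[rows] += slope * zt[None, :] + wiggle[:, None] * qt[None, :]
        parent_rows = [prot_index[st.sites[layer][s]] for s in sites]
        values = (prot_values[parent_rows]
                  + st.site_offsets[layer].to_numpy()[:, None]
                  + pattern
                  + noise_rng.normal(0, c.noise_sd, pattern.shape))
        layer_values[layer] = values
        site_patterns[layer] = pattern

    # --- missingness ------------------------------------------------------
    def censor(values: np.ndarray, noiseless_mean: np.ndarray) -> np.ndarray:
        out = values.copy()
        t_max = max(c.n_conditions - 1, 1)
        for t in range(c.n_conditions):
            frac = c.missing_low_quantile * (t_max - t) / t_max
            k = int(np.ceil(frac * out.shape[0]))
            if k <= 0:
                continue
            cond_mean = noiseless_mean[:, t]
            lowest = np.argsort(cond_mean, kind="stable")[:k]
            cols = np.flatnonzero(t_of_sample == t)
            out[np.ix_(lowest, cols)] = np.nan
        if c.sporadic_missing_rate > 0:
            mask = sporadic_rng.random(out.shape) < c.sporadic_missing_rate
            out[mask] = np.nan
        return out

    prot_noiseless_cond = np.stack(
        [(prot_signal + prot_pattern)[:, t_of_sample == t].mean(axis=1)
         for t in range(c.n_conditions)], axis=1)
    prot_values = censor(prot_values, prot_noiseless_cond)
    for layer in (ACETYLOME, PHOSPHO):
        sites = site_lists[layer]
        parent_rows = [prot_index[st.sites[layer][s]] for s in sites]
        noiseless = (prot_noiseless_cond[parent_rows]
                     + st.site_offsets[layer].to_numpy()[:, None]
                     + np.stack([site_patterns[layer][:, t_of_sample == t].mean(axis=1)
                                 for t in range(c.n_conditions)], axis=1))
        layer_values[layer] = censor(layer_values[layer], noiseless)

    # --- planted fold-change truth ---------------------------------------
    def pattern_fc(pattern: np.ndarray, index: list[str]) -> pd.DataFrame:
        cond_mean = np.stack([pattern[:, t_of_sample == t].mean(axis=1)
                              for t in range(c.n_conditions)], axis=1)
        cols = {}
        for name, (num, den) in CONTRASTS.items():
            if num < c.n_conditions and den < c.n_conditions:
                cols[name] = cond_mean[:, num] - cond_mean[:, den]
        return pd.DataFrame(cols, index=index)

    log2fc = {PROTEOME: pattern_fc(prot_pattern, st.proteins)}
    corrected_log2fc = {}
    for layer in (ACETYLOME, PHOSPHO):
        sites = site_lists[layer]
        parent_rows = [prot_index[st.sites[layer][s]] for s in sites]
        log2fc[layer] = pattern_fc(
            prot_pattern[parent_rows] + site_patterns[layer], sites)
        corrected_log2fc[layer] = pattern_fc(site_patterns[layer], sites)

    truth = Truth(
        module_of=_module_of_frame(st, c),
        module_sign={m.name: m.sign for m in c.module_spec},
        log2fc=log2fc,
        corrected_log2fc=corrected_log2fc,
        geneset_members=st.geneset_members,
        geneset_direction=st.geneset_direction,
        geneset_amplitude=st.geneset_amplitude,
    )
    site_parent = {**st.sites[ACETYLOME], **st.sites[PHOSPHO]}
    return SyntheticDataset(
        line=line,
        proteome=IntensityMatrix(
            pd.DataFrame(prot_values, index=st.proteins, columns=samples), "log2"),
        acetylome=IntensityMatrix(
            pd.DataFrame(layer_values[ACETYLOME], index=site_lists[ACETYLOME],
                         columns=samples), "log2"),
        phospho=IntensityMatrix(
            pd.DataFrame(layer_values[PHOSPHO], index=site_lists[PHOSPHO],
                         columns=samples), "log2"),
        site_parent=site_parent,
        design=design,
        truth=truth,
        config=c,
    )


def generate_genesets(config: SimulationConfig,
                      dataset: SyntheticDataset) -> GeneSetCollection:
    """Materialize the planted gene sets of a generated dataset.

    Sets are drawn over protein IDs (size >= 3 each); the planted
    per-line directions live in ``dataset.truth.geneset_direction``.
    """
    members = dataset.truth.geneset_members
    for name, prots in members.items():
        if len(prots) < 3:
            raise ValueError(f"gene set {name} smaller than 3 members")
    if config.geneset_size_range[1] > config.n_proteins:
        raise ValueError("requested gene-set size exceeds the protein universe")
    return GeneSetCollection(sets={k: list(v) for k, v in members.items()},
                             universe=dataset.proteome.feature_ids)


def write_fixture_bundle(dataset: SyntheticDataset,
                         genesets: GeneSetCollection,
                         directory: str | Path) -> dict:
    """Write TSV matrices, design, GMT and truth tables; return a manifest."""
    if not dataset.proteome.feature_ids:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prov = f"adipoptm fixture line={dataset.line} seed={dataset.config.seed}"
    paths = {}

    for name, matrix in ((PROTEOME, dataset.proteome),
                         (ACETYLOME, dataset.acetylome),
                         (PHOSPHO, dataset.phospho)):
        p = directory / f"{name}.tsv"
        write_intensity_table(matrix, p, provenance=prov)
        paths[name] = str(p)

    p = directory / "design.tsv"
    write_design(dataset.design, p, provenance=prov)
    paths["design"] = str(p)

    p = directory / "genesets.gmt"
    write_gmt(genesets, p)
    paths["genesets"] = str(p)

    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = dataset.truth
    t.module_of.rename_axis("feature").to_frame().to_csv(
        truth_dir / "modules.tsv", sep="\t")
    for layer, frame in t.log2fc.items():
        frame.rename_axis("feature").to_csv(
            truth_dir / f"log2fc_{layer}.tsv", sep="\t")
    for layer, frame in t.corrected_log2fc.items():
        frame.rename_axis("feature").to_csv(
            truth_dir / f"corrected_log2fc_{layer}.tsv", sep="\t")
    t.geneset_direction.rename_axis("geneset").to_csv(
        truth_dir / "geneset_direction.tsv", sep="\t")
    paths["truth"] = str(truth_dir)

    manifest = {"seed": dataset.config.seed, "line": dataset.line,
                "scale": "log2", "paths": paths}
    return manifest
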