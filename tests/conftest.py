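import numpy as np
import pandas as pd
import pytest

import adipoptm as a
from adipoptm.io import IntensityMatrix
from adipoptm.layers import ACETYLOME, PHOSPHO, PROTEOME


@pytest.fixture(scope="session")
def sim_config():
    return a.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return a.generate_dataset(sim_config)


@pytest.fixture(scope="session")
def processed(dataset):
    """Filtered, corrected, imputed layers plus the combined network input.

    Mirrors the pipeline stage order: presence filter -> proteome
    correction -> noise imputation -> combined feature space (block-
    imputed features excluded from the network input).
    """
    design = dataset.design
    filtered = {}
    for layer in (PROTEOME, ACETYLOME, PHOSPHO):
        m, _ = a.filter_by_presence(dataset.layer(layer), design)
        filtered[layer] = m
    corr_ack = a.correct_sites(filtered[ACETYLOME], filtered[PROTEOME],
                               site_parent=dataset.site_parent)
    corr_pp = a.correct_sites(filtered[PHOSPHO], filtered[PROTEOME],
                              site_parent=dataset.site_parent)
    prot_i, log_p = a.impute_noise(filtered[PROTEOME], design, 101)
    ack_i, log_a = a.impute_noise(corr_ack.matrix, design, 102)
    pp_i, log_pp = a.impute_noise(corr_pp.matrix, design, 103)
    combined = a.build_feature_space(prot_i, ack_i, pp_i)
    block = set()
    for prefix, implog in (("PROT:", log_p), ("ACK:", log_a), ("PP:", log_pp)):
        block.update(prefix + f for f in
                     implog.loc[implog["reason"] == "block", "feature"])
    network_input = combined.loc[[f for f in combined.index if f not in block]]
    trait = (design.set_index("sample_id")
             .loc[list(combined.columns), "time_code"].to_numpy(float))
    return {
        "design": design, "filtered": filtered,
        "corrected": {ACETYLOME: corr_ack, PHOSPHO: corr_pp},
        "imputed": {PROTEOME: prot_i, ACETYLOME: ack_i, PHOSPHO: pp_i},
        "combined": combined, "network_input": network_input, "trait": trait,
    }


@pytest.fixture(scope="session")
def fitted_network(dataset, processed):
    net = a.WeightedCoabundanceNetwork().fit(processed["network_input"],
                                             processed["trait"])
    return net


def small_matrix(values, samples=None, scale="log2", features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    if samples is None:
        # condition-block names (A1..A3, B1..B3, ...) matching
        # two_condition_design when the width is a multiple of 3
        if values.shape[1] % 3 == 0:
            samples = [f"{chr(65 + j // 3)}{j % 3 + 1}"
                       for j in range(values.shape[1])]
        else:
            samples = [f"S{j}" for j in range(values.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(values, index=features, columns=samples), scale)


def two_condition_design(n_rep=3, conditions=("A", "B")):
    rows = [{"sample_id": f"{c}{r}", "condition": c, "time_code": t,
             "replicate": r}
            for t, c in enumerate(conditions) for r in range(1, n_rep + 1)]
    return pd.DataFrame(rows)
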