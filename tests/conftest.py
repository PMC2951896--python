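import numpy as np
import pytest

import xspec_ec as x
from xspec_ec.cli import stage_seed


@pytest.fixture(scope="session")
def default_sim():
    """The standard study condition: k=500 default simulation, seed 7,
    preprocessed, with PCMs, common-tissue subset and CCN machinery."""
    cfg = x.SimulationConfig()
    paired, truth = x.simulate_paired_expression(cfg)
    paired, _ = x.filter_low_expression(paired, floor=200.0)
    paired, _ = x.drop_zero_variance(paired)
    assert paired.k == cfg.k, "default condition should survive filtering intact"
    common_a = paired.matrix_A.condition_labels[: cfg.n_common]
    common_b = paired.matrix_B.condition_labels[: cfg.n_common]
    sub = x.subset_tissues(paired, common_a, common_b)
    pcm_A = x.pairwise_correlation_matrix(paired.matrix_A)
    pcm_B = x.pairwise_correlation_matrix(paired.matrix_B)
    bg_A = x.background_correlations(
        paired.matrix_A, 20000, stage_seed(cfg.seed, "background_A"), "A"
    )
    bg_B = x.background_correlations(
        paired.matrix_B, 20000, stage_seed(cfg.seed, "background_B"), "B"
    )
    nodes = {}
    for q in (0.95, 0.975, 0.99):
        nodes[q] = x.identify_ccn_nodes(
            pcm_A,
            pcm_B,
            x.correlation_threshold(bg_A, q),
            x.correlation_threshold(bg_B, q),
            q,
        )
    return {
        "config": cfg,
        "paired": paired,
        "truth": truth,
        "common": sub,
        "common_a": common_a,
        "common_b": common_b,
        "pcm_A": pcm_A,
        "pcm_B": pcm_B,
        "bg_A": bg_A,
        "bg_B": bg_B,
        "nodes": nodes,
    }


@pytest.fixture(scope="session")
def default_methods(default_sim):
    """Ortholog EC results for all four methods on the default condition."""
    d = default_sim
    node_set = d["nodes"][0.975].node_indices
    icc_result, icc_history = x.icc(d["pcm_A"], d["pcm_B"])
    return {
        "liao_zhang": x.liao_zhang_ec(d["common"]),
        "dutilh": x.dutilh_ec(d["pcm_A"], d["pcm_B"]),
        "icc": icc_result,
        "icc_history": icc_history,
        "essien": x.essien_ec(d["pcm_A"], d["pcm_B"], node_set),
        "node_set": node_set,
    }


@pytest.fixture()
def small_paired():
    """A small, fully generic paired dataset (no degenerate rows)."""
    cfg = x.SimulationConfig(k=30, t_A=8, t_B=7, n_common=5, m=3, seed=123)
    paired, truth = x.simulate_paired_expression(cfg)
    return paired, truth, cfg
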