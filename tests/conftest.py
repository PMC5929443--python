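import numpy as np
import pytest

import emstate as es


@pytest.fixture(scope="session")
def bulk_sim():
    """600-gene clonal E/M simulation with 200+200 planted genes (seed 1)."""
    config = es.BulkSimConfig(
        n_genes=600, n_diff_e=200, n_diff_m=200, effect_size=4.0,
        noise_sd=0.25, n_replicates=3, seed=1,
    )
    return es.simulate_bulk_arrays(config)


@pytest.fixture(scope="session")
def bulk_pipeline(bulk_sim):
    """Normalized matrix, ranked table and k=150 signatures from bulk_sim."""
    matrix, truth = bulk_sim
    norm = es.normalize_arrays(matrix)
    group_e = [s for s in norm.samples if truth.sample_condition[s] == "adh_E"]
    group_m = [s for s in norm.samples if truth.sample_condition[s] == "adh_M"]
    ranked = es.rank_differential(norm, group_e, group_m)
    sig_e, sig_m = es.derive_signatures(ranked, 150)
    return {
        "norm": norm,
        "truth": truth,
        "ranked": ranked,
        "sig_e": sig_e,
        "sig_m": sig_m,
        "group_e": group_e,
        "group_m": group_m,
    }


@pytest.fixture(scope="session")
def sc_sim_58():
    """Planted 58% hybrid population (116 hybrid / 42 + 42 pure), seed 7."""
    config = es.ScSimConfig(
        n_pure_e=42, n_pure_m=42, n_hybrid=116, dropout_prob=0.1, seed=7
    )
    return config, *es.simulate_sc_ct_table(config)


@pytest.fixture(scope="session")
def hp_events():
    """HP-like reference: 72% E, 18% M, 5% + 5% double quadrants, n=10000."""
    config = es.CytoSimConfig(
        clusters=(
            es.ClusterSpec("CD24+/CD44-", 7200),
            es.ClusterSpec("CD24-/CD44+", 1800),
            es.ClusterSpec("CD24+/CD44+", 500),
            es.ClusterSpec("CD24-/CD44-", 500),
        ),
        seed=3,
    )
    return config, *es.simulate_event_table(config)


def classify_sc(cells, refs, panel, **kwargs):
    """Run the full single-cell scoring chain on simulated Ct tables."""
    norm = es.reference_normalize(
        es.ct_to_linear(cells), es.ct_to_linear(refs), refs.ref_groups, panel
    )
    scores = es.cell_scores(norm, panel)
    return es.classify_cells(scores, **kwargs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
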