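import numpy as np
import pandas as pd
import pytest

import dck


def run_pipeline(neurons, edges, tau=0.4, coverage=0.2):
    """Full upstream-input pipeline: USNs -> fractions -> matrix -> calls."""
    catalog = dck.DanTypeCatalog.from_neurons(neurons)
    usns = dck.identify_usns(edges, neurons, catalog)
    fractions = dck.input_fractions(edges, catalog, usns)
    usn_tab = neurons.loc[neurons["neuron_id"].isin(usns)]
    clusters = dck.cluster_by_type(usn_tab)
    matrix = dck.build_matrix(fractions, clusters, catalog)
    edges_t = dck.apply_edge_threshold(matrix, tau)
    calls = dck.classify_type_connectivity(edges_t, catalog, coverage)
    return {
        "catalog": catalog,
        "usns": usns,
        "fractions": fractions,
        "clusters": clusters,
        "matrix": matrix,
        "edges_t": edges_t,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def noise_free_connectome():
    cfg = dck.ConnectomeSimConfig(seed=1, noise_edge_prob=0.0)
    return dck.synth_connectome(cfg)


@pytest.fixture(scope="session")
def noisy_connectome():
    cfg = dck.ConnectomeSimConfig(seed=1)  # documented default noise
    return dck.synth_connectome(cfg)


@pytest.fixture(scope="session")
def noise_free_pipeline(noise_free_connectome):
    neurons, edges, truth = noise_free_connectome
    return run_pipeline(neurons, edges), truth


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_connectome):
    neurons, edges, truth = noisy_connectome
    return run_pipeline(neurons, edges), truth


@pytest.fixture
def toy_neurons():
    return pd.DataFrame(
        {
            "neuron_id": [1, 2, 3, 4, 5],
            "type_label": ["PAM08_a", "KCg-m", "", "SLP001", "MBON09"],
            "category": ["target_dan", "excluded", "candidate_usn", "candidate_usn", "excluded"],
            "hemisphere": ["right"] * 5,
            "sez_associated": [False] * 5,
        }
    )


@pytest.fixture
def toy_edges():
    # KC (2) and MBON09 (5) are excluded; 3 (blank label) and 4 are USNs
    return pd.DataFrame(
        {
            "pre_id": [2, 3, 4, 5],
            "post_id": [1, 1, 1, 1],
            "synapse_count": [5, 30, 10, 7],
            "post_site_class": ["dendritic", "dendritic", "unknown", "dendritic"],
        }
    )
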