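"""Shared fixtures.

Heavy artifacts (the simulated study bundle, the trained classifier, scored
candidate lists) are session-scoped so the end-to-end tests share one
simulation + training + genome-scoring pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import chromloop as cl

# Fixed study conditions for the end-to-end tests: the default simulated
# bundle (3 chromosomes x 2000 bins, 30 planted loops each) with fixed seeds.
SIM_SEED = 7
DATASET_SEED = 11
SPLIT_SEED = 5
TRAIN_SEED = 3
TEST_CHROM = "chr3"

# Desk-scale training schedule: epochs are single-batch at this dataset size,
# so the step budget is raised accordingly; filters are scaled to match.
DESK_FILTERS = (8, 16, 32)
DESK_EPOCHS = 300
DESK_PATIENCE = 60


@pytest.fixture(scope="session")
def sim_params():
    return cl.SimParams(seed=SIM_SEED)


@pytest.fixture(scope="session")
def bundle(sim_params, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return cl.simulate_study(sim_params, str(outdir))


@pytest.fixture(scope="session")
def study(bundle, sim_params):
    """Maps, tracks, truth and per-chromosome window datasets, loaded back
    through the I/O layer from the written bundle."""
    res = sim_params.resolution
    maps, tracks, datasets, manifests = {}, {}, {}, {}
    truth = {c: [t for t in cl.read_interactions(str(bundle.truth_path), res) if t.chrom == c]
             for c in bundle.chroms}
    for c in bundle.chroms:
        maps[c] = cl.read_contact_map(str(bundle.cool_path), c, res)
        tracks[c] = cl.read_accessibility(str(bundle.bedgraph_path), c, res, maps[c].n_bins)
        datasets[c], manifests[c] = cl.build_dataset(
            maps[c], tracks[c], truth[c], seed=DATASET_SEED
        )
    return {"maps": maps, "tracks": tracks, "truth": truth,
            "datasets": datasets, "manifests": manifests, "params": sim_params}


@pytest.fixture(scope="session")
def split(bundle):
    return cl.loco_split(list(bundle.chroms), TEST_CHROM, seed=SPLIT_SEED)


@pytest.fixture(scope="session")
def trained(study, split):
    train_chroms, val_chroms, _ = split
    trw = [w for c in train_chroms for w in study["datasets"][c]]
    vaw = [w for c in val_chroms for w in study["datasets"][c]]
    cfg = cl.ModelConfig(seed=TRAIN_SEED, filters=DESK_FILTERS)
    tc = cl.TrainConfig(seed=TRAIN_SEED, max_epochs=DESK_EPOCHS, patience=DESK_PATIENCE)
    model = cl.train(cl.init_model(cfg), trw, vaw, tc)
    return model


@pytest.fixture(scope="session")
def scored_test_chrom(trained, study):
    """Frequency-filtered candidates on the held-out chromosome."""
    cands = cl.score_chromosome(
        trained, study["maps"][TEST_CHROM], study["tracks"][TEST_CHROM]
    )
    return cands, cl.filter_by_frequency(cands)


@pytest.fixture(scope="session")
def calibrated_threshold(trained, study, split):
    """Operating threshold calibrated on the validation chromosome to yield
    about one call per planted loop."""
    val_chrom = split[1][0]
    ff = cl.filter_by_frequency(
        cl.score_chromosome(trained, study["maps"][val_chrom], study["tracks"][val_chrom])
    )
    return cl.calibrate_threshold(ff, target_count=len(study["truth"][val_chrom]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
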