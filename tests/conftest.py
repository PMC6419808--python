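"""Shared fixtures: one synthetic study, trained once per session.

The default dataset follows the standard study design: 300-bp sequences,
500 regulatory + 500 G+C-matched controls for training, 100+100 balanced
holdout, extra controls for the 1:10 unbalanced holdout, two planted
motifs at 1-3 copies each per regulatory sequence. Embeddings use
dimension 32 and 3 passes — the corpus-size-matched training budget for
these desk-scale corpora.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kgrammar import bagmodel, controls, fixtures, scan, vecmodel
from kgrammar.seqio import GenomicRegion

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATASET_SEED = 11
MOTIF_SEED = 101
MODEL_SEED = 7
TRANSFER_SEED = 21

VEC_DIM = 32
VEC_EPOCHS = 3


@pytest.fixture(scope="session")
def motif_set():
    return fixtures.make_motif_set(n_motifs=2, seed=MOTIF_SEED)


@pytest.fixture(scope="session")
def study(motif_set):
    """Train/holdout partition of the default synthetic study."""
    records = fixtures.simulate_dataset(
        n_per_class=600, n_control=1600, motifs=motif_set, seed=DATASET_SEED
    )
    reg, ctrl = fixtures.split_by_label(records)
    return {
        "train": reg[:500] + ctrl[:500],
        "holdout_reg": reg[500:600],
        "holdout_ctrl": ctrl[500:600],
        "extra_ctrl": ctrl[600:1600],
    }


@pytest.fixture(scope="session")
def bag_model(study):
    return bagmodel.fit_bag_classifier(study["train"], k=8, seed=MODEL_SEED)


@pytest.fixture(scope="session")
def embedding_spaces(study):
    reg = [r for r in study["train"] if r.region.label == "regulatory"]
    ctrl = [r for r in study["train"] if r.region.label == "control"]
    return {
        "regulatory": vecmodel.train_embedding(
            reg, k=8, d=VEC_DIM, epochs=VEC_EPOCHS, seed=MODEL_SEED
        ),
        "random": vecmodel.train_embedding(
            ctrl, k=8, d=VEC_DIM, epochs=VEC_EPOCHS, seed=MODEL_SEED
        ),
    }


@pytest.fixture(scope="session")
def transfer_setup():
    """Genome pair at 2% divergence with models trained on the source."""
    pair = fixtures.simulate_genome_pair(
        divergence=0.02, n_regulatory=100, seed=TRANSFER_SEED
    )
    reg_recs = [pair.source.fetch_region(r) for r in pair.regulatory]
    rng = np.random.default_rng(TRANSFER_SEED + 1)
    ctrl_regions = controls.select_controls(pair.regulatory, pair.source, rng=rng)
    ctrl_recs = [
        pair.source.fetch_region(
            GenomicRegion(r.chrom, r.start, r.end, ".", "control")
        )
        for r in ctrl_regions
    ]
    bag = bagmodel.fit_bag_classifier(
        reg_recs + ctrl_recs,
        labels=[1] * len(reg_recs) + [0] * len(ctrl_recs),
        k=8,
        seed=MODEL_SEED,
    )
    spaces = {
        "regulatory": vecmodel.train_embedding(
            reg_recs, k=8, d=VEC_DIM, epochs=VEC_EPOCHS, seed=MODEL_SEED
        ),
        "random": vecmodel.train_embedding(
            ctrl_recs, k=8, d=VEC_DIM, epochs=VEC_EPOCHS, seed=MODEL_SEED
        ),
    }
    centroid = vecmodel.corpus_centroid(spaces["regulatory"], reg_recs)
    predictions = scan.transfer_score(
        pair.target, pair.hits, bag, spaces, centroid, top_m=3
    )
    return {
        "pair": pair,
        "bag": bag,
        "spaces": spaces,
        "centroid": centroid,
        "predictions": predictions,
    }
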