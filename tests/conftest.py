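import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from loopclust.cluster import kmeans_cluster, select_k, subcluster
from loopclust.core import (
    BasePairAnnotation,
    Loop,
    Nucleotide,
    StackingAnnotation,
    parse_loop_location,
)
from loopclust.gin import ModelConfig, train
from loopclust.graphs import encode_loops
from loopclust.synthetic import generate_dataset


def make_loop(
    location="1U9S_A:136-139_161-162",
    bases="GAGACG",
    pairs=((0, 5, "cWW"), (1, 4, "tHS")),
    stacks=((1, 2, "upward"),),
    coords=None,
    family=None,
):
    """Hand-built internal loop with simple deterministic coordinates."""
    loc = parse_loop_location(location)
    rng = np.random.default_rng(7)
    nts = []
    idx = 0
    for start, end in loc.segments:
        for resnum in range(start, end + 1):
            if coords == "none":
                xyz = {}
            else:
                base_point = np.array([3.0 * idx, 0.5 * idx**2, 1.0 * idx])
                xyz = {
                    "P": base_point + [1, 0, 0],
                    "C4'": base_point - [1, 0, 0],
                }
            nts.append(Nucleotide(resnum, bases[idx], xyz))
            idx += 1
    return Loop(
        loc,
        nts,
        [BasePairAnnotation(*p) for p in pairs],
        [StackingAnnotation(*s) for s in stacks],
        family=family,
    )


@pytest.fixture
def hand_loop():
    return make_loop()


@pytest.fixture(scope="session")
def trained_pipeline():
    """Full run at study scale: 6 internal families x 50 loops, seed 0.

    Shared by the end-to-end tests so the model is trained once.
    """
    ds = generate_dataset(n_per_family=50, seed=0)
    graphs = encode_loops(ds.loops)
    model = train(graphs, (ds.split["train"], ds.split["val"], ds.split["test"]), ModelConfig(seed=0))
    emb = model.embedder.transform(graphs)
    report = select_k(emb, seed=0)
    clusters = kmeans_cluster(emb, report.chosen_k, seed=0)
    subclusters = subcluster(emb, clusters)
    return {
        "dataset": ds,
        "graphs": graphs,
        "model": model,
        "embeddings": emb,
        "k_report": report,
        "clusters": clusters,
        "subclusters": subclusters,
    }
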