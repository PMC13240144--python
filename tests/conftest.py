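import numpy as np
import pytest

import avimast as am
from avimast import dataset, synth


@pytest.fixture
def two_tip_tree():
    return am.parse_newick("(A:1,B:1);")


@pytest.fixture
def five_tip_tree():
    # two clades: (A,B) vs (C,(D,E))
    return am.parse_newick("((A:0.3,B:0.3):0.7,(C:0.5,(D:0.2,E:0.2):0.3):0.5);")


@pytest.fixture(scope="session")
def small_study():
    """A reusable synthetic study: tree sample, records and truth."""
    cfg = synth.SynthConfig(n_species=40, seed=100)
    sample = synth.simulate_tree_sample(cfg, n_trees=6, seed=100)
    records, truth = synth.simulate_records(sample.trees[0], cfg, seed=101)
    return {"config": cfg, "sample": sample, "tree": sample.trees[0],
            "records": records, "truth": truth,
            "frame": dataset.records_to_frame(records)}


def random_tree(rng, n_tips, max_bl=1.0):
    """Random binary tree by sequential joining (independent of treeio)."""
    import avimast
    parts = [f"t{i}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a = parts.pop(j)
        b = parts.pop(i)
        bl_a = rng.uniform(0.05, max_bl)
        bl_b = rng.uniform(0.05, max_bl)
        parts.append(f"({a}:{bl_a:.6f},{b}:{bl_b:.6f})")
    return avimast.parse_newick(parts[0] + ";")
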