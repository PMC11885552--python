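import numpy as np
import pandas as pd
import pytest

import phylomorph as pm
from phylomorph.geometry import estimate_missing_tps, gpa_align
from phylomorph.ordination import select_axes


@pytest.fixture(scope="session")
def fixture_data():
    """The deterministic study-scale dataset (17 taxa, 19 landmarks)."""
    return pm.paper_fixture()


@pytest.fixture(scope="session")
def fixture_shapes(fixture_data):
    landmarks, tree, prior = fixture_data
    return gpa_align(estimate_missing_tps(landmarks))


@pytest.fixture(scope="session")
def fixture_scores(fixture_data, fixture_shapes):
    """Retained (90% variance) Phylo-PC scores of the fixture."""
    _, tree, _ = fixture_data
    flat = pd.DataFrame(fixture_shapes.flat(), index=fixture_shapes.specimen_ids)
    ord_phy = pm.phylo_pca(flat, tree)
    axes = select_axes(ord_phy, 0.90, "variance")
    return ord_phy.scores_frame().iloc[:, axes]


@pytest.fixture
def small_tree():
    return pm.PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return pm.PhyloTree.from_newick(
        "(((A:1.0,B:1.5):1.0,C:0.8):1.2,(D:2.0,E:1.2):0.6);"
    )


def star_tree(n, length=1.0):
    tips = ",".join(f"t{i}:{length}" for i in range(1, n + 1))
    return pm.PhyloTree.from_newick(f"({tips});")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
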