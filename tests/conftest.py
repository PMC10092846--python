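import dendropy
import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from cupnest import bpmm, synthetic

hypothesis_settings.register_profile("default", derandomize=True, deadline=None)
hypothesis_settings.load_profile("default")


def tree_from_newick(nwk: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=nwk, schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture
def five_tip_tree():
    return tree_from_newick("((t1:0.6,(t2:0.35,t3:0.35):0.25):0.4,(t4:0.8,t5:0.8):0.2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def recovery_fit():
    """One fitted recovery-scenario model shared by the sampler checks:
    200 species x 2 records, beta=(1.0,-0.5), variances (0.5, 0.2, 0.3)."""
    sc = synthetic.recovery_scenario(seed=11)
    tree = synthetic.simulate_tree(sc)
    data, truth = synthetic.simulate_traits(tree, sc)
    spec = bpmm.ModelSpec(response="response",
                          fixed_terms={"x1": "continuous", "x2": "continuous"},
                          standardize=False)
    settings = bpmm.MCMCSettings(n_iterations=3000, burn_in=500, thin=1,
                                 n_chains=1, seed=3)
    design = bpmm.build_design(data, spec, tree)
    sample = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=99)
    return {"scenario": sc, "tree": tree, "data": data, "truth": truth,
            "design": design, "sample": sample, "settings": settings}
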