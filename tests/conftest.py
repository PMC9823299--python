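import numpy as np
import pytest

from gierc.codec import GraphContext
from gierc.synth import (
    TemplateSpec,
    default_ensemble_spec,
    key_rotatable_bond,
    make_template,
    sample_ensemble,
)


@pytest.fixture(scope="session")
def small_system():
    """24-atom ring-plus-tail molecule with a bimodal tail torsion."""
    g, ref = make_template(TemplateSpec(kind="ring_plus_tail", n_heavy=10, seed=3))
    assert g.n_atoms == 24
    return g, ref


@pytest.fixture(scope="session")
def small_ctx(small_system):
    g, _ = small_system
    return GraphContext(g)


@pytest.fixture(scope="session")
def small_conformers(small_system):
    g, ref = small_system
    spec = default_ensemble_spec(g, ref, n_conformers=20, seed=11)
    return sample_ensemble(g, ref, spec)


@pytest.fixture(scope="session")
def peptide_system():
    """150-atom glycine-like peptide."""
    g, ref = make_template(TemplateSpec(kind="peptide_like", n_heavy=150, seed=3))
    assert g.n_atoms == 150
    return g, ref


@pytest.fixture(scope="session")
def peptide_ctx(peptide_system):
    g, _ = peptide_system
    return GraphContext(g)


@pytest.fixture(scope="session")
def peptide_conformers(peptide_system):
    g, ref = peptide_system
    spec = default_ensemble_spec(g, ref, n_conformers=12, seed=13)
    return sample_ensemble(g, ref, spec)


@pytest.fixture(scope="session")
def chain_system():
    g, ref = make_template(TemplateSpec(kind="chain", n_heavy=8, seed=3))
    return g, ref


@pytest.fixture(scope="session")
def trained_small_ae(small_system, small_ctx):
    """Graph-AE trained on a 2,000-conformer bimodal ensemble of the
    24-atom system with the torsion transition band excluded — shared by the
    reconstruction-accuracy and interpolation tests."""
    from gierc.graph_ae import TrainConfig, encode_ensemble, train_graph_ae
    from gierc.synth import exclude_transition_region

    g, ref = small_system
    bond = key_rotatable_bond(g)
    spec = default_ensemble_spec(g, ref, n_conformers=2000, seed=21)
    confs = sample_ensemble(g, ref, spec)
    kept, _removed = exclude_transition_region(confs, g, bond, band=60.0)
    x, headers = encode_ensemble(kept, small_ctx)
    cfg = TrainConfig(max_epochs=30, seed=0)
    model, log = train_graph_ae(x, small_ctx, cfg)
    return {
        "model": model, "log": log, "confs": kept, "headers": headers,
        "bond": bond, "band": (90.0, 150.0), "modes": (60.0, 180.0),
    }


@pytest.fixture(scope="session")
def trained_peptide_pair(peptide_system, peptide_ctx):
    """Graph-AE and naive AE trained on the same 150-atom ensemble."""
    from gierc.graph_ae import (
        TrainConfig,
        encode_ensemble,
        train_graph_ae,
        train_naive_ae,
    )

    g, ref = peptide_system
    spec = default_ensemble_spec(g, ref, n_conformers=300, seed=23)
    confs = sample_ensemble(g, ref, spec)
    x, headers = encode_ensemble(confs, peptide_ctx)
    cfg = TrainConfig(max_epochs=60, seed=0)
    gmodel, glog = train_graph_ae(x, peptide_ctx, cfg)
    nmodel, nlog = train_naive_ae(x, peptide_ctx, TrainConfig(max_epochs=60, seed=0))
    return {
        "graph": (gmodel, glog), "naive": (nmodel, nlog),
        "confs": confs, "headers": headers,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
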