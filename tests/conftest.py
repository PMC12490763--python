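import numpy as np
import pytest

from rlalign import encoders, rla_core, synthdata


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def helix_chain():
    from rlalign.structio import Chain

    bb = synthdata.gen_backbone(12, pure="helix")
    return Chain(chain_id="A", sequence="A" * 12, backbone=bb)


@pytest.fixture()
def small_structure():
    """Single-chain synthetic structure, ~30–50 residues."""
    spec = synthdata.GeneratorSpec(num_proteins=1, seed=5)
    s, _ = synthdata.gen_paired_example(spec, 17)
    return s


@pytest.fixture()
def two_chain_structure():
    spec = synthdata.GeneratorSpec(num_proteins=1, num_chains_range=(2, 2), seed=3)
    s, _ = synthdata.gen_paired_example(spec, 11)
    return s


def random_structure(seed: int, length_range=(8, 15), chains=1):
    spec = synthdata.GeneratorSpec(
        num_proteins=1, chain_length_range=length_range,
        num_chains_range=(chains, chains), seed=0,
    )
    s, _ = synthdata.gen_paired_example(spec, seed)
    return s


@pytest.fixture(scope="session")
def trained_model():
    """Desk-scale model trained on the identity-coupled synthetic corpus.

    Shared session-wide because training takes about a minute; the held-out
    proteins come from the same generator but were never trained on.
    """
    spec = synthdata.GeneratorSpec(num_proteins=250, seed=42)
    corpus = synthdata.gen_corpus(spec)
    train_set, held = corpus[:200], corpus[200:250]
    seq_cfg, struct_cfg = encoders.synthetic_profile()
    result = rla_core.train(
        rla_core.TrainingConfig(seed=0), train_set, seq_cfg, struct_cfg
    )
    return result, train_set, held
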