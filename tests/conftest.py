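import numpy as np
import pytest

import storeflow as sf
from storeflow import model as M
from storeflow.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def desk_grid():
    return sf.GridSpec.desk()


@pytest.fixture(scope="session")
def full_grid():
    return sf.GridSpec.full()


@pytest.fixture(scope="session")
def ccfg_k2():
    return sf.CorpusConfig(k=2)


@pytest.fixture(scope="session")
def small_world():
    """A small rule-based crowd on the desk grid (deterministic)."""
    cfg = WorldConfig(n_agents=60, arrival_rate=1.5, seed=11)
    table, labels = generate_world(cfg)
    return cfg, table, labels


@pytest.fixture(scope="session")
def small_corpus(small_world, ccfg_k2):
    """Documents, codec and masked examples derived from the small world."""
    cfg, table, _ = small_world
    docs = sf.documents_from_table(table, ccfg_k2, cfg.grid)
    codec = sf.train_codec(docs, 200, ccfg_k2, grid=cfg.grid)
    examples = [sf.encode_with_mask(d, codec, ccfg_k2) for d in docs]
    return docs, codec, examples


@pytest.fixture(scope="session")
def tiny_ckpt(small_world, small_corpus, ccfg_k2):
    """A briefly trained small model — enough structure for generation tests."""
    cfg, _, _ = small_world
    _, codec, examples = small_corpus
    mc = M.ModelConfig(n_layers=2, n_heads=4, hidden_size=64,
                       context_length=512, vocab_size=len(codec))
    tc = M.TrainConfig(learning_rate=2e-3, batch_size=8, max_epochs=4,
                       patience=4, seed=0)
    return M.train(examples, mc, tc, codec, ccfg_k2, cfg.grid)


@pytest.fixture(scope="session")
def untrained_ckpt(small_world, small_corpus, ccfg_k2):
    """Randomly initialised checkpoint (for validity/constraint tests)."""
    cfg, _, _ = small_world
    _, codec, _ = small_corpus
    mc = M.ModelConfig(n_layers=1, n_heads=2, hidden_size=32,
                       context_length=512, vocab_size=len(codec))
    params = sf.model.init_params(mc, np.random.default_rng(42))
    return M.Checkpoint(params=params, model_config=mc, codec=codec,
                        corpus_config=ccfg_k2, grid=cfg.grid)
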