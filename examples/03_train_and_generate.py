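"""Train a small model with the asymmetric loss and sample next locations.

Trains a small decoder-only model on a synthetic crowd for a few epochs,
then samples the focal agent's next position under the prefix-trie
constraint — every sample is a valid location code or the end word.
"""

import numpy as np

from storeflow import CorpusConfig, GridSpec, documents_from_table, encode_with_mask, train_codec
from storeflow import model as M
from storeflow.synthetic_world import WorldConfig, generate_world

grid = GridSpec.desk()
table, _ = generate_world(WorldConfig(grid=grid, n_agents=60, arrival_rate=1.5,
                                      seed=11))
cfg = CorpusConfig(k=2)
docs = documents_from_table(table, cfg, grid)
codec = train_codec(docs, 200, cfg, grid=grid)
examples = [encode_with_mask(d, codec, cfg) for d in docs]

mc = M.ModelConfig(n_layers=2, n_heads=4, hidden_size=64, context_length=512,
                   vocab_size=len(codec))
tc = M.TrainConfig(learning_rate=2e-3, batch_size=8, max_epochs=4, seed=0)
ckpt = M.train(examples, mc, tc, codec, cfg, grid)
for h in ckpt.history:
    print(f"epoch {h['epoch']}: train {h['train_loss']:.3f}  "
          f"val {h['val_loss']:.3f}")

# condition on the first three frames of a held-out style context
ex = examples[0]
context = list(ex.ids[: ex.frame_starts[3]])
rng = np.random.default_rng(5)
print("sampled next focal positions (constrained decoding):")
for _ in range(5):
    code = M.next_focal_token(ckpt, context, M.SamplerConfig(temperature=0.7,
                                                             top_k=3), rng=rng)
    print("  ", "end-of-trajectory" if code is None else f"cell code {code}")
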