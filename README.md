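# storeflow

Interaction-aware generative simulation of customer trajectories in retail
stores.

Understanding how shoppers move — and how they slow down, reroute, or cut a
visit short when the store gets crowded — matters for layout design,
congestion management and digital-twin planning. Classic agent-based models
hard-code those responses as rules. `storeflow` instead *learns* them from
positioning data: each customer's trajectory becomes a symbolic token
sequence that records, at every 5-second tick, their own grid location
**and** the locations of their nearest neighbours, and a decoder-only
transformer is trained to predict the customer's next position from that
social context. Simulated crowds then emerge from many such agents
generating their moves simultaneously. The package is aimed at researchers
in pedestrian dynamics, computational social science and retail analytics
who want a fully inspectable, CPU-scale implementation of this pipeline.

## The model

* **Spatial tokens.** The floor is a `2^d × 2^d` grid; each cell gets a
  `d`-character hierarchical quadrant code (level 1 letters `a–d`, level 2
  `e–h`, …) in which a shared prefix of length `p` pins two cells into the
  same `2^(d−p)`-cell quadtree square. The full-scale configuration is a
  64×64 grid with 6-character codes (e.g. `bgjoqw`).
* **Multi-agent frames.** At tick *t* the focal customer contributes
  `S<code>`, its nearest neighbour `O<code>`, the second-nearest `T<code>`
  (placeholder bodies such as `Onone` when fewer than *k* others are in
  store). Frames are concatenated over time and closed by an
  end-of-trajectory word.
* **Sub-tokens.** A byte-pair codec with a deliberately small vocabulary
  (200) splits each word into 2–4 reusable pieces, so the model generalises
  across locations sharing quadtree structure.
* **Asymmetric loss.** Training minimises cross-entropy **only at positions
  whose label belongs to a focal (`S`) word or the end word**: neighbours
  condition every prediction, but never supervise. Gradients at masked-out
  positions are exactly zero.
* **Constrained generation.** At simulation time each agent samples its next
  word under a prefix-trie constraint over all valid `S`+code words and the
  end word, so output is well-formed by construction. Arrival rate is the
  crowding control (the stress grid spans 9–720 customers/hour); analyses
  exclude the warm-up phase before the in-store count stabilises.

Because the original indoor-positioning dataset is proprietary, the package
ships a rule-based synthetic world (goal-directed aisle walkers with planted
slowdown / reroute / disengagement rules and per-tick rule labels) that
provides training corpora, seed pools, and known-truth signals for
end-to-end recovery tests.

## Worked example

Encode locations (`examples/01_grid_codes.py`):

```
cell (41, 22)  ->  code 'bgjosv'
prefix 'b'       -> 32x32-cell square (32, 0, 63, 31)
prefix 'bgj'     -> 8x8-cell square (40, 16, 47, 23)
prefix 'bgjos'   -> 2x2-cell square (40, 22, 41, 23)
```

The prefix chain shows the geometry carried by the code: every extra
character narrows the location by a factor of four.

Build a corpus and inspect the loss mask (`examples/02_corpus_and_masking.py`):

```
60 documents; first document starts:
   Safjp Onone Tnone Safln Onone Tnone Safln Onone Tnone ...
codec vocabulary: 200 entries
document 0: 95 sub-tokens, 37 supervised positions (39%)
```

Roughly a third of positions carry loss — exactly the focal-token labels;
neighbour tokens are context only.

Train briefly and generate (`examples/03_train_and_generate.py`):

```
epoch 1: train 5.043  val 4.717
...
epoch 4: train 4.197  val 4.222
sampled next focal positions (constrained decoding):
   cell code afln
   cell code afln
   cell code afjn
```

Validation loss falls from the uniform baseline (ln 200 ≈ 5.3) and every
sample is a well-formed location code.

Measure planted interaction effects (`examples/05_evaluate_metrics.py`):

```
mean speed (m/s) by local density (3x3 block, focal included):
 density  n_obs  mean_speed
       1   5200    0.067058
       2   4000    0.041325
       3   2540    0.042008
big-turn ratio (>=90 deg) by distance to nearest agent:
  0.0-0.5 m: 0.50    0.5-1.0 m: 0.52    1.5-2.0 m: 0.17
stay duration vs arrival rate: 3.04 -> 3.76 -> 4.55 min (0.3 -> 2.4 /min)
```

Speed drops with local density, sharp turns concentrate within 1 m of
another agent, and stays lengthen with crowding — the three fingerprints
the learned model is later tested against.

## Command line

The same pipeline is scriptable:

```bash
storeflow synth --config world.yaml --out traj.csv --labels labels.csv
storeflow build-corpus --traj traj.csv --grid grid.yaml --k 2 --out corpus.txt
storeflow train-bpe --corpus corpus.txt --grid grid.yaml --vocab 200 --out codec.json
storeflow train --corpus corpus.txt --codec codec.json --grid grid.yaml --out ckpt/
storeflow simulate --checkpoint ckpt/ --rate 2.4 --duration 60 --seed 1 \
                   --seed-pool traj.csv --out sim.csv
storeflow evaluate --real traj.csv --sim sim.csv --grid grid.yaml --out report.json
```

Every command appends a JSON-lines provenance log (timestamp, seed, config
hash) next to its output.

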