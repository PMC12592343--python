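# Methods

## The model in brief

`storeflow` treats in-store pedestrian movement as a language-modelling
problem. The store floor is a square grid of cells (side `2^depth`); each
cell is named by a hierarchical quadrant code in which character *d* selects
one of four quadrants at subdivision level *d*, drawn from a level-specific
4-letter alphabet block (level 1: `a–d`, level 2: `e–h`, …). Codes that share
a prefix are spatially close, so sub-word structure carries geometry.

A customer's trajectory, sampled every 5 s, becomes a *document*: at every
tick the focal agent's token (`S` + code) is followed by the tokens of its
`k` nearest neighbours (`O`, `T`, and `U` for rank 3), nearest first, with an
atomic placeholder body (`Onone`, …) when fewer than `k` other customers are
present, and a reserved end word closing the document. A byte-pair-encoding
codec with a deliberately small vocabulary (200 at full scale) splits each
word into a few reusable sub-tokens, so the model can generalise across
locations that share quadtree structure.

A decoder-only transformer is trained on these documents with an
**asymmetric loss**: cross-entropy is computed only at positions whose label
sub-token belongs to a focal (`S`) word or the end word. Neighbour tokens
condition every prediction but never act as targets, so the model learns one
agent's socially situated policy rather than a mixture of everyone's. The
gradient at masked-out positions is exactly zero by construction (asserted
in the tests by autodiff).

Simulation closes the loop: agents enter a store at a controlled arrival
rate, replay the first three positions of a donor trajectory from a seed
pool, and then move by autoregressive sampling, each agent conditioning on
its own history interleaved with the neighbour tokens *it actually saw* at
each past tick (stored, not recomputed). Updates are synchronous within a
tick. Generation is constrained by a prefix trie over the sub-token
spellings of all admissible words, so every sampled word is a valid location
or the end word — no malformed output can occur. An agent leaves when it
emits the end word or reaches a length cap.

## Quadrant-code conventions

The quadrant index at each level is `2·row_bit + col_bit` with bits taken
most-significant first, origin at the min-x/min-y corner, rows increasing
with y (Z-order). Any fixed bijection between quadrants and letters
satisfies every internal property (round trips, locality, prefix regions);
this one is pinned so codes are stable across machines. Cells are half-open
intervals `[k·s, (k+1)·s)` in meters; indices are 0-based. Grids must be
square with a power-of-two side (depth ≤ 6 so the level blocks fit in
`a–z`); non-conforming grids are rejected at construction.

## Sub-token codec

Training is the classic frequency-greedy merge procedure over word types,
with three conventions: merges never cross whitespace; the absent-neighbour
words and the end word are seeded as atomic symbols; ties between equally
frequent pairs break lexicographically, so training is a pure function of
corpus and budget. The full code alphabet of the grid is seeded into the
base vocabulary even when the corpus never visits some cells, so constrained
generation can always spell every location. On a full-scale-configured
corpus (64×64 grid, budget 200) role words decompose into 2.4 sub-tokens on
average; a handful of very frequent words end up fully merged (1 sub-token),
which `decomposition_report` surfaces explicitly rather than hiding.

## Architecture and training

Two presets are defined. The *full* preset mirrors the production-scale
configuration (12 layers, 12 heads, hidden 768, context 6144); it is
expressible but not trained here. The *desk* preset (2 layers, 4 heads,
hidden 128, context 768) is sized for a single CPU. The network is a
standard pre-norm GPT-style decoder (learned positional embeddings, GELU
MLPs, tied input/output embedding) implemented directly in numpy with
analytic gradients; a finite-difference check in the test suite validates
every parameter's gradient. Training uses AdamW (decoupled weight decay on
matrices), linear warmup over the first 10% of steps then linear decay to
10% of the peak rate, batches bucketed by length, a 90/10 train/validation
split *by document*, and early stopping on validation loss with the best
checkpoint kept (ties keep the earlier epoch, so enlarging the patience can
never worsen the selected model). Documents longer than the context window
are head-truncated in whole frames so the most recent context is kept. The
full-scale optimiser preset is lr 3·10⁻⁴ with batch 32; the desk experiments
use lr 2·10⁻³ with batch 16, which reaches the same validation loss in a
third of the epochs at this model size.

Sampling at desk scale uses top-k = 3 with temperature 0.7 by default
(`DESK_SAMPLER`). A briefly trained small model leaves non-trivial
probability on distant cells; sampling those produces off-distribution
contexts whose errors compound. The setting was calibrated once on pilot
runs by matching simulated stay duration, travel distance and speed to the
generator's ground truth, and is recorded here as a desk-scale choice — at
full scale, plain sampling is the natural default. A rejection-resampling
mode exists for fidelity experiments but is not used by default.

## The synthetic world

The real indoor-positioning corpus this line of work builds on is
proprietary, so ground truth comes from a mechanistic generator that is
deliberately *not* a sequence model: goal-directed walkers on the grid with
three planted interaction rules —

* **slowdown**: within `r_slow` = 1.0 m of another agent, a move is skipped
  with probability `1 − slow_factor` (factor 0.5);
* **reroute**: within `r_turn` = 1.0 m, the intended step is replaced by an
  orthogonal detour with probability 0.3;
* **early disengagement**: at 3×3-block density ≥ 4 the remaining goal list
  is dropped with probability 0.05 per tick.

Walkers enter at a door on one edge, visit 1–2 uniformly sampled interior
goals (browsing 1–3 ticks at each), and exit through the door, moving one
4-neighbour step per tick aisle-style: along a single axis until that axis
is exhausted, then turning. Movement pauses occur spontaneously
(`move_prob` 0.9). Every (agent, tick) carries a rule tag
(free/slowed/rerouted/disengaged) used as a planted-signal oracle in tests.
The default world is the 16×16 desk grid with 0.5 m cells and 2,000 agents.

What the generator emulates: 5-s sampling, entry/exit structure,
goal-directed movement with stop-and-go browsing, and crowding responses
(slower movement and sharper turning near others, truncated visits under
high density), so the learned model has a recoverable signal. What it does
not emulate: store layout and shelving (the grid has no obstacles), group
shopping, heterogeneous walking speeds, sensor noise, and the basket-only
sampling of real deployments. Passing the recovery tests therefore shows
the *pipeline* can learn and reproduce planted interaction structure — not
that it matches any particular real store.

## Simulation conventions

Arrivals are fixed-interval by default (one entry every `1/rate` minutes,
starting at half an interval, rounded to ticks — exactly `rate × duration`
entries per run); a Poisson mode with exponential inter-arrivals is
available. The eight stress conditions span 0.15–12 persons/min (9–720 per
hour). Warm-up is excluded by `equilibrium_window`: the earliest tick from
which the trailing 10-minute rolling mean of the active count stays within
±10% of the remaining-run mean, judged over the arrival period only (the
drain-out after arrivals stop is no more stationary than warm-up) and
requiring at least one full rolling window; when the series never settles
(routine at very low rates, where the band is a fraction of one agent) the
fallback is twice the empirical mean stay. Analyses keep agents entering
after the window opens.

## Evaluation metrics

Six metrics compare trajectory tables: occupancy heatmaps; per-agent stay
duration and travel distance (center-to-center step lengths; Table-style
velocity = distance/stay); turning angles (angle between consecutive
displacements, defined only when both are non-zero) binned by
nearest-agent distance with the big-turn threshold at 90°; mean speed
binned by (nearest, second-nearest) distance; mean speed by local density
(agents in the 3×3 block centered on the focal cell, focal included, classes
1–5 with ≥5 pooled); and the RMSE between quadratic least-squares fits of a
crowding–response relationship (stay or distance vs crowding level),
evaluated on the shared crowding levels. Per-tick speed is displacement
over 5 s with stationary ticks counting as zero; empty bins are reported as
undefined, never as zero. An agent's crowding class for the stay summary is
its visit-averaged concurrent in-store count, rounded.

## Desk-scale recovery experiment (problem sizes)

The end-to-end experiment in `storeflow.experiments` uses: a training world
of 800 agents (200 at each arrival rate 0.5/1.2/2.4/4.0 persons/min, 90/10
train/seed-pool split by agent), desk models for k = 2 and k = 0 trained up
to 24 epochs with early stopping, ground-truth hold-out worlds of 120 agents
at rates 0.3/1.2/2.4, and simulations of 40–100 minutes per rate (longer at
low rates so each condition keeps a comparable number of post-warm-up
agents). These sizes are the package's desk-scale study conditions; they
run in minutes on one CPU.

At these sizes the pipeline reliably recovers two of the three planted
effects in the k = 2 simulation: mean speed falls with local density, and
the crowding–stay curve of the interaction-aware model tracks ground truth
more closely than the non-interactive control (RMSE(k=2) < RMSE(k=0)). The
third effect — a higher big-turn ratio within 1 m of another agent than
beyond 2 m — is recovered only marginally and not at every seed: a desk
model trained on ~10⁵ sub-tokens does not fully learn directional
persistence, so its baseline turning stays high everywhere, and the
contrast between near and far bins is small compared to ground truth
(where it is large). This is a known limitation of the desk scale, not of
the method: direction requires decoding relative geometry from quadtree
codes, which is exactly the kind of structure that needs the full-scale
model and corpus.

## Numerical and degenerate-input choices

Everything numeric is float32 except losses (float64 accumulation);
randomness flows through explicit `numpy.random.Generator` objects, so
fixed seeds give bitwise-identical runs on one platform. Distance ties in
neighbour ranking break by ascending agent id; temperature 0 means argmax
with lowest-id tie-break; an all-masked-out batch raises rather than
returning 0; single-tick agents have stay 0 and undefined speed; turning
angles at stationary ticks are skipped, not imputed; empty metric bins are
flagged undefined. The simulator asserts conservation (arrivals − departures
= active count) every run.
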