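"""Agent-based store simulation driven by the trained sequence model.

Each simulated customer is an agent equipped with the generative model:
after entering (its first three positions replay a donor trajectory from a
seed pool), its next location is sampled autoregressively from its own
history interleaved with the stored positions of its nearest neighbours at
each past tick. Updates are synchronous: every agent's move at a tick is
decided from the previous tick's snapshot, so no agent sees another's move
at the same tick. An agent leaves when the model emits the
end-of-trajectory word or when it reaches a maximum trajectory length.

Crowding is controlled by the arrival rate (persons per minute); the eight
stress-test conditions span 0.15 to 12.0 /min (9 to 720 per hour). Analyses
exclude the warm-up period via :func:`equilibrium_window`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import DT_SECONDS, CorpusConfig, nearest_neighbors
from .geometry import GridSpec, code_of, decode_code
from .model import Checkpoint, SamplerConfig, generate_focal
from .transformer import IncrementalDecoder

__all__ = [
    "SimulationConfig",
    "SimState",
    "ARRIVAL_RATE_CONDITIONS",
    "schedule_arrivals",
    "seed_agent",
    "step",
    "run",
    "equilibrium_window",
]

#: The eight arrival-rate conditions, persons per minute (9..720 per hour).
ARRIVAL_RATE_CONDITIONS = (0.15, 0.30, 0.60, 1.20, 2.40, 4.00, 6.00, 12.00)


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings for the agent-based simulation.

    ``seed_pool`` is a trajectory table whose first three positions seed new
    agents (in the original study this pool is the empirical dataset; here it
    is a hold-out split of the synthetic world). ``max_steps`` defaults to
    the longest stay the model can condition on given its context window.
    ``replay_table``: when set, neighbour context is taken from this recorded
    table instead of live agents (the single-focal-agent ablation mode).
    """

    arrival_rate: float  # persons per minute
    duration_min: float
    seed_pool: Optional[pd.DataFrame] = None
    arrival_mode: str = "fixed"  # "fixed" | "poisson"
    max_steps: Optional[int] = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int = 0
    warmup_window_min: float = 10.0
    warmup_tol: float = 0.10
    replay_table: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.arrival_rate <= 0:
            raise ValueError("arrival_rate must be positive")
        if self.arrival_mode not in ("fixed", "poisson"):
            raise ValueError(f"unknown arrival_mode {self.arrival_mode!r}")


def schedule_arrivals(cfg: SimulationConfig) -> List[int]:
    """Entry ticks over ``[0, duration)``.

    Fixed-interval mode places one entry every ``1 / rate`` minutes starting
    at half an interval (so a 60-min run at 0.15 /min yields exactly 9
    entries); Poisson mode draws exponential inter-arrival times at the same
    rate, seeded from ``cfg.seed``.
    """
    if cfg.duration_min <= 0:
        return []
    ticks_per_min = 60.0 / DT_SECONDS
    last_tick = int(np.ceil(cfg.duration_min * ticks_per_min)) - 1
    if cfg.arrival_mode == "fixed":
        interval = 1.0 / cfg.arrival_rate  # minutes
        ticks = []
        i = 0
        while True:
            t_min = (i + 0.5) * interval
            if t_min >= cfg.duration_min:
                break
            ticks.append(min(int(round(t_min * ticks_per_min)), last_tick))
            i += 1
        return ticks
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA221]))
    ticks = []
    t_min = 0.0
    while True:
        t_min += rng.exponential(1.0 / cfg.arrival_rate)
        if t_min >= cfg.duration_min:
            break
        ticks.append(min(int(round(t_min * ticks_per_min)), last_tick))
    return ticks


def seed_agent(pool: pd.DataFrame, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """First three cells of a uniformly sampled donor trajectory (length ≥ 3)."""
    donors = _donor_seeds(pool)
    if not donors:
        raise ValueError("seed pool has no trajectory of length >= 3")
    return list(donors[rng.integers(len(donors))])


def _donor_seeds(pool: pd.DataFrame) -> List[Tuple[Tuple[int, int], ...]]:
    donors = []
    for _, g in pool.groupby("agent_id", sort=True):
        if len(g) < 3:
            continue
        g = g.sort_values("t").head(3)
        donors.append(tuple(zip(g["col"].astype(int), g["row"].astype(int))))
    return donors


class _LiveAgent:
    __slots__ = (
        "aid", "entry_tick", "cells", "seed_cells", "ids", "frame_starts",
        "decoder", "reason",
    )

    def __init__(self, aid: int, entry_tick: int, seed_cells, decoder):
        self.aid = aid
        self.entry_tick = entry_tick
        self.cells: List[Tuple[int, int]] = []
        self.seed_cells = seed_cells
        self.ids: List[int] = []
        self.frame_starts: List[int] = []
        self.decoder: IncrementalDecoder = decoder
        self.reason: Optional[str] = None


@dataclass
class SimState:
    """Live simulation state (5-second tick clock)."""

    tick: int = 0
    agents: Dict[int, _LiveAgent] = field(default_factory=dict)
    completed: List[_LiveAgent] = field(default_factory=list)
    schedule: List[int] = field(default_factory=list)
    cursor: int = 0
    rng: np.random.Generator = None
    active_counts: List[int] = field(default_factory=list)
    arrivals_so_far: int = 0
    departures_so_far: int = 0
    _donors: list = field(default_factory=list)
    _next_aid: int = 0
    _replay_frames: Optional[Dict[int, Dict]] = None


def _word_ids(word: str, ckpt: Checkpoint) -> List[int]:
    codec = ckpt.codec
    return [codec.token_to_id[p] for p in codec.encode_word(word)]


def _default_max_steps(ckpt: Checkpoint) -> int:
    cfg = ckpt.corpus_config
    trie = ckpt.trie()
    # mean sub-tokens per word, over the admissible focal vocabulary
    mean_len = float(np.mean([len(seq) for seq in trie.words]))
    per_frame = (1 + cfg.k) * mean_len
    return max(4, int(ckpt.model_config.context_length / per_frame))


def _ensure_headroom(agent: _LiveAgent, needed: int, context_length: int) -> None:
    """Head-truncate the agent's context in whole frames when near the window."""
    if len(agent.ids) + needed <= context_length:
        return
    keep_from = None
    for i, fs in enumerate(agent.frame_starts):
        if len(agent.ids) - fs + needed <= context_length:
            keep_from = i
            break
    if keep_from is None or keep_from == 0:
        keep_from = max(1, len(agent.frame_starts) // 2)
    offset = agent.frame_starts[keep_from]
    agent.ids = agent.ids[offset:]
    agent.frame_starts = [fs - offset for fs in agent.frame_starts[keep_from:]]
    agent.decoder.reset(np.asarray(agent.ids, np.int64))


def step(state: SimState, ckpt: Checkpoint, cfg: SimulationConfig) -> SimState:
    """Advance the simulation by one 5-second tick (in place).

    Order of events: admit scheduled arrivals; decide every agent's move from
    the previous tick's snapshot (seeded agents replay their three seed
    positions before generating); apply all moves simultaneously; retire
    agents that emitted the end word or hit the length cap; store each
    surviving agent's neighbour context for this tick.
    """
    grid = ckpt.grid
    ccfg = ckpt.corpus_config
    trie = ckpt.trie()
    max_steps = cfg.max_steps or _default_max_steps(ckpt)
    frame_reserve = trie.max_len * (1 + ccfg.k)

    # 1. arrivals
    while state.cursor < len(state.schedule) and state.schedule[state.cursor] <= state.tick:
        aid = state._next_aid
        state._next_aid += 1
        seed_cells = state._donors[state.rng.integers(len(state._donors))]
        agent = _LiveAgent(aid, state.tick, list(seed_cells), ckpt.decoder())
        state.agents[aid] = agent
        state.arrivals_so_far += 1
        state.cursor += 1

    # 2. decide moves from the pre-move snapshot
    staged: Dict[int, Optional[Tuple[int, int]]] = {}
    reasons: Dict[int, str] = {}
    for aid, agent in state.agents.items():
        age = state.tick - agent.entry_tick
        if age < len(agent.seed_cells):
            staged[aid] = agent.seed_cells[age]
            continue
        if len(agent.cells) >= max_steps:
            staged[aid] = None
            reasons[aid] = "max_length"
            continue
        _ensure_headroom(agent, frame_reserve, ckpt.model_config.context_length)
        frame_start = len(agent.ids)
        code, sampled = generate_focal(ckpt, agent.decoder, cfg.sampler, state.rng)
        if code is None:
            # roll the end word back out of the context bookkeeping; the
            # agent departs and its decoder is dropped anyway
            staged[aid] = None
            reasons[aid] = "eos"
        else:
            agent.ids.extend(sampled)
            agent.frame_starts.append(frame_start)
            staged[aid] = decode_code(code, grid)

    # 3. apply moves simultaneously; retire departures
    departed: List[int] = []
    for aid, cell in staged.items():
        agent = state.agents[aid]
        if cell is None:
            agent.reason = reasons[aid]
            departed.append(aid)
        else:
            agent.cells.append(cell)
            if state.tick - agent.entry_tick < len(agent.seed_cells):
                # seeded frame: put the replayed S word into the context
                agent.frame_starts.append(len(agent.ids))
                agent.ids.extend(_word_ids("S" + code_of(cell[0], cell[1], grid), ckpt))
                agent.decoder.append(agent.ids[agent.frame_starts[-1]:])
    for aid in departed:
        state.completed.append(state.agents.pop(aid))
        state.departures_so_far += 1

    # 4. store this tick's neighbour context (post-move snapshot; in replay
    # mode the neighbours come from the recorded table instead)
    if ccfg.k and state.agents:
        frame = {("live", aid): a.cells[-1] for aid, a in state.agents.items()}
        if state._replay_frames is not None:
            for raid, cell in state._replay_frames.get(state.tick, {}).items():
                frame[("replay", raid)] = cell
        for aid, agent in state.agents.items():
            neigh = nearest_neighbors(frame, ("live", aid), ccfg.k, grid)
            ot_ids: List[int] = []
            for prefix, cell in zip(ccfg.neighbor_prefixes, neigh):
                body = ccfg.absent_body if cell is None else code_of(cell[0], cell[1], grid)
                ot_ids.extend(_word_ids(prefix + body, ckpt))
            agent.ids.extend(ot_ids)
            agent.decoder.append(ot_ids)

    state.active_counts.append(len(state.agents))
    state.tick += 1
    return state


def run(
    cfg: SimulationConfig, ckpt: Checkpoint
) -> Tuple[pd.DataFrame, dict]:
    """Run a full simulation; returns (trajectory table, run log).

    The run iterates :func:`step` until the scheduled duration has elapsed
    and every agent has departed, or a hard cap is reached (agents then
    force-retired with reason ``max_length``). The log carries the per-tick
    active-count series, departure reasons and the detected warm-up window.
    """
    if cfg.seed_pool is None or len(cfg.seed_pool) == 0:
        raise ValueError("a non-empty seed_pool is required")
    schedule = schedule_arrivals(cfg)
    replay_frames = None
    if cfg.replay_table is not None:
        replay_frames = {}
        for aid, t, c, r in zip(
            cfg.replay_table["agent_id"], cfg.replay_table["t"],
            cfg.replay_table["col"], cfg.replay_table["row"],
        ):
            replay_frames.setdefault(int(round(t / DT_SECONDS)), {})[aid] = (
                int(c), int(r)
            )
    state = SimState(
        schedule=schedule,
        rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51A7])),
        _donors=_donor_seeds(cfg.seed_pool),
        _replay_frames=replay_frames,
    )
    if not state._donors:
        raise ValueError("seed pool has no trajectory of length >= 3")
    duration_ticks = int(round(cfg.duration_min * 60.0 / DT_SECONDS))
    max_steps = cfg.max_steps or _default_max_steps(ckpt)
    hard_cap = duration_ticks + 3 * max_steps + 16
    forced = False
    while state.tick < duration_ticks or state.agents:
        if state.tick >= hard_cap:
            forced = True
            for agent in state.agents.values():
                agent.reason = "max_length"
                state.completed.append(agent)
                state.departures_so_far += 1
            state.agents.clear()
            break
        step(state, ckpt, cfg)

    rows = []
    reasons: Dict[str, int] = {}
    state.completed.sort(key=lambda a: a.aid)
    for agent in state.completed:
        reasons[agent.reason] = reasons.get(agent.reason, 0) + 1
        for i, (c, r) in enumerate(agent.cells):
            rows.append((agent.aid, (agent.entry_tick + i) * DT_SECONDS, c, r))
    table = pd.DataFrame(rows, columns=["agent_id", "t", "col", "row"])
    if state.active_counts:
        # equilibrium is judged over the arrival period only — after arrivals
        # stop the store drains out, which is no more stationary than warm-up
        series = state.active_counts[:duration_ticks] or state.active_counts
        # fallback when the rolling mean never settles: twice the mean stay
        stay_ticks = [len(a.cells) for a in state.completed if a.cells]
        fallback = int(2 * np.mean(stay_ticks)) if stay_ticks else None
        start, end, stabilized = equilibrium_window(
            series,
            window_min=cfg.warmup_window_min,
            tol=cfg.warmup_tol,
            fallback_start=fallback,
        )
    else:
        start, end, stabilized = 0, 0, True
    log = {
        "arrivals": state.arrivals_so_far,
        "departures": state.departures_so_far,
        "departure_reasons": reasons,
        "active_counts": list(state.active_counts),
        "ticks": state.tick,
        "forced_retirements": forced,
        "warmup": {"start_tick": start, "end_tick": end, "stabilized": stabilized},
    }
    return table, log


def equilibrium_window(
    active_counts: Sequence[int],
    window_min: float = 10.0,
    tol: float = 0.10,
    fallback_start: Optional[int] = None,
) -> Tuple[int, int, bool]:
    """Detect the equilibrium phase of an active-count series.

    Returns ``(start_tick, end_tick, stabilized)``: the smallest start such
    that the trailing ``window_min``-minute rolling mean stays within
    ``±tol`` of the remaining-run mean from there on. When the series never
    stabilises, falls back to ``fallback_start`` (default: half the run) with
    ``stabilized=False``.
    """
    series = np.asarray(active_counts, dtype=float)
    n = len(series)
    if n == 0:
        raise ValueError("empty active-count series")
    w = max(1, int(round(window_min * 60.0 / DT_SECONDS)))
    rolling = pd.Series(series).rolling(w, min_periods=1).mean().to_numpy()
    suffix_mean = np.cumsum(series[::-1])[::-1] / np.arange(n, 0, -1)
    # a start is only accepted if at least one full rolling window remains;
    # otherwise the tail of any series trivially "stabilises"
    for t in range(max(0, n - w + 1)):
        m = suffix_mean[t]
        band = tol * m
        if np.all(np.abs(rolling[t:] - m) <= band):
            return t, n, True
    start = fallback_start if fallback_start is not None else n // 2
    return min(start, n - 1), n, False
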