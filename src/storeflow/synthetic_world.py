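"""Rule-based ground-truth crowd generator.

The real indoor-positioning corpus behind this line of work is proprietary,
so the package ships a mechanistic stand-in: goal-directed grid walkers with
three planted interaction rules — proximity-triggered slowdown, proximity-
triggered rerouting, and density-triggered early disengagement. The
generator is deliberately *not* a sequence model: it is an independent
mechanism, so when the learned model reproduces the planted effects that is
a genuine recovery result rather than self-confirmation.

Every (agent, tick) carries a ground-truth rule tag (free / slowed /
rerouted / disengaged), which downstream tests use as planted-signal
oracles for the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import DT_SECONDS
from .geometry import GridSpec, cell_center

__all__ = ["WorldConfig", "generate_world", "split_corpus"]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic store world.

    Agents enter at an entry cell, visit a few uniformly sampled goal cells,
    browse at each goal for a few ticks, then leave through an exit cell.
    Movement is aisle-style: one 4-neighbour step per tick along a single
    axis at a time (a shopper walking down an aisle turns at corners rather
    than weaving diagonally), which yields long straight legs punctuated by
    corner turns.
    Interactions: when the nearest other agent is within ``r_slow_m`` the
    move is skipped with probability ``1 - slow_factor`` (tag ``slowed``);
    when within ``r_turn_m`` the step is replaced by an orthogonal detour
    with probability ``turn_prob`` (tag ``rerouted``); when the 3×3 local
    density reaches ``disengage_density`` the remaining goals are dropped
    with probability ``disengage_prob`` (tag ``disengaged``).
    """

    grid: GridSpec = field(default_factory=GridSpec.desk)
    entry_cells: Tuple[Tuple[int, int], ...] = ()
    exit_cells: Tuple[Tuple[int, int], ...] = ()
    n_goals_range: Tuple[int, int] = (1, 2)
    goal_dwell_range: Tuple[int, int] = (1, 3)
    move_prob: float = 0.9
    r_slow_m: float = 1.0
    slow_factor: float = 0.5
    r_turn_m: float = 1.0
    turn_prob: float = 0.3
    disengage_density: int = 4
    disengage_prob: float = 0.05
    arrival_rate: float = 2.0  # persons per minute
    n_agents: int = 2000
    max_ticks_per_agent: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_slow_m < 0 or self.r_turn_m < 0:
            raise ValueError("interaction radii must be non-negative")
        for name in ("move_prob", "turn_prob", "disengage_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.slow_factor <= 1:
            raise ValueError("slow_factor must be in (0, 1]")
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be non-negative")
        g = self.grid
        for cell in tuple(self.entry_cells) + tuple(self.exit_cells):
            c, r = cell
            if not (0 <= c < g.n_cols and 0 <= r < g.n_rows):
                raise ValueError(f"entry/exit cell {cell} outside grid")

    def resolved_entries(self) -> Tuple[Tuple[int, int], ...]:
        if self.entry_cells:
            return tuple(self.entry_cells)
        mid = self.grid.n_cols // 2
        return ((mid - 1, 0), (mid, 0))  # a door on the bottom edge

    def resolved_exits(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(self.exit_cells) if self.exit_cells else self.resolved_entries()

    def interaction_free(self) -> "WorldConfig":
        """Copy of this config with all three interaction rules disabled."""
        from dataclasses import replace

        return replace(self, r_slow_m=0.0, r_turn_m=0.0, disengage_prob=0.0)


class _Walker:
    __slots__ = ("aid", "pos", "goals", "dwell", "exit", "age", "trace",
                 "tags", "axis")

    def __init__(self, aid, pos, goals, exit_cell):
        self.aid = aid
        self.pos = pos
        self.goals: List[Tuple[int, int]] = goals
        self.dwell = 0
        self.exit = exit_cell
        self.age = 0
        self.trace: List[Tuple[int, int, int]] = []  # (tick, col, row)
        self.tags: List[str] = []
        self.axis: Optional[int] = None  # 0 = along cols, 1 = along rows


def _aisle_step(w: "_Walker", target, rng) -> Tuple[int, int]:
    """One 4-neighbour step toward the target, walking aisle-style.

    The walker moves along one axis at a time (like a shopper following an
    aisle): it keeps its current axis while that axis still reduces the
    Manhattan distance, and only then switches. At the start of a leg the
    axis is drawn at random among those that make progress.
    """
    pos = w.pos
    dc = target[0] - pos[0]
    dr = target[1] - pos[1]
    useful = [axis for axis, d in ((0, dc), (1, dr)) if d != 0]
    if not useful:
        return pos
    if w.axis not in useful:
        w.axis = useful[rng.integers(len(useful))]
    if w.axis == 0:
        return (pos[0] + int(np.sign(dc)), pos[1])
    return (pos[0], pos[1] + int(np.sign(dr)))


def _orthogonal_step(pos, step, grid, rng) -> Tuple[int, int]:
    """Replace a step with a perpendicular detour (clipped to the grid)."""
    dc, dr = step[0] - pos[0], step[1] - pos[1]
    if dc == 0 and dr == 0:
        return pos
    cands = []
    for sc, sr in ((dr, dc), (-dr, -dc)):  # rotate ±90°
        c, r = pos[0] + sc, pos[1] + sr
        if 0 <= c < grid.n_cols and 0 <= r < grid.n_rows:
            cands.append((int(c), int(r)))
    if not cands:
        return step
    return cands[rng.integers(len(cands))]


def generate_world(cfg: WorldConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the rule-based world; returns (trajectories, rule labels).

    Trajectories use the standard table schema ``agent_id, t, col, row``
    (``t`` in seconds, 5-s ticks); labels carry one tag per (agent, tick).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    s = grid.cell_size_m
    entries = cfg.resolved_entries()
    exits = cfg.resolved_exits()
    interior = [
        (c, r)
        for c in range(1, grid.n_cols - 1)
        for r in range(1, grid.n_rows - 1)
    ]

    # fixed-interval arrivals at cfg.arrival_rate persons/min
    ticks_per_min = 60.0 / DT_SECONDS
    if cfg.arrival_rate > 0:
        interval_ticks = ticks_per_min / cfg.arrival_rate
        entry_ticks = [
            int(round((i + 0.5) * interval_ticks)) for i in range(cfg.n_agents)
        ]
    else:
        entry_ticks = []

    active: List[_Walker] = []
    done: List[_Walker] = []
    next_arrival = 0
    tick = 0
    while next_arrival < len(entry_ticks) or active:
        # admissions
        while next_arrival < len(entry_ticks) and entry_ticks[next_arrival] <= tick:
            aid = next_arrival
            pos = entries[rng.integers(len(entries))]
            n_goals = int(rng.integers(cfg.n_goals_range[0], cfg.n_goals_range[1] + 1))
            goals = [interior[rng.integers(len(interior))] for _ in range(n_goals)]
            exit_cell = exits[rng.integers(len(exits))]
            active.append(_Walker(aid, (int(pos[0]), int(pos[1])), goals, exit_cell))
            next_arrival += 1

        if not active:
            tick += 1
            continue

        # synchronous snapshot of positions at tick start
        centers = np.array(
            [cell_center(w.pos[0], w.pos[1], grid) for w in active]
        )
        cells = np.array([w.pos for w in active])
        if len(active) > 1:
            diff = centers[:, None, :] - centers[None, :, :]
            dists = np.sqrt((diff**2).sum(-1))
            np.fill_diagonal(dists, np.inf)
            d1 = dists.min(1)
        else:
            d1 = np.full(1, np.inf)
        # 3×3 local density (Chebyshev distance ≤ 1 in cells), incl. focal
        cheb = np.maximum(
            np.abs(cells[:, None, 0] - cells[None, :, 0]),
            np.abs(cells[:, None, 1] - cells[None, :, 1]),
        )
        density = (cheb <= 1).sum(1)

        staged: List[Optional[Tuple[int, int]]] = []
        tags: List[str] = []
        leaving: List[bool] = []
        for i, w in enumerate(active):
            tag = "free"
            leave = False
            # early disengagement under local crowding
            if (
                w.goals
                and density[i] >= cfg.disengage_density
                and cfg.disengage_prob > 0
                and rng.random() < cfg.disengage_prob
            ):
                w.goals = []
                w.dwell = 0
                tag = "disengaged"
            target = w.goals[0] if w.goals else w.exit
            new_pos = w.pos
            if w.dwell > 0:
                w.dwell -= 1
            elif w.pos == target:
                if w.goals:
                    w.goals.pop(0)
                    w.dwell = int(
                        rng.integers(cfg.goal_dwell_range[0], cfg.goal_dwell_range[1] + 1)
                    )
                else:
                    leave = True
            elif rng.random() < cfg.move_prob:
                step = _aisle_step(w, target, rng)
                if cfg.r_slow_m > 0 and d1[i] <= cfg.r_slow_m and rng.random() < (
                    1.0 - cfg.slow_factor
                ):
                    if tag == "free":
                        tag = "slowed"
                elif cfg.r_turn_m > 0 and d1[i] <= cfg.r_turn_m and rng.random() < cfg.turn_prob:
                    new_pos = _orthogonal_step(w.pos, step, grid, rng)
                    if tag == "free":
                        tag = "rerouted"
                else:
                    new_pos = step
            if w.age + 1 >= cfg.max_ticks_per_agent:
                leave = True
            staged.append(new_pos)
            tags.append(tag)
            leaving.append(leave)

        # apply all moves simultaneously, record, retire leavers
        still: List[_Walker] = []
        for w, new_pos, tag, leave in zip(active, staged, tags, leaving):
            w.pos = (int(new_pos[0]), int(new_pos[1]))
            w.trace.append((tick, w.pos[0], w.pos[1]))
            w.tags.append(tag)
            w.age += 1
            if leave:
                done.append(w)
            else:
                still.append(w)
        active = still
        tick += 1

    done.sort(key=lambda w: w.aid)
    rows = []
    label_rows = []
    for w in done:
        for (tk, c, r), tag in zip(w.trace, w.tags):
            rows.append((w.aid, tk * DT_SECONDS, c, r))
            label_rows.append((w.aid, tk * DT_SECONDS, tag))
    table = pd.DataFrame(rows, columns=["agent_id", "t", "col", "row"])
    labels = pd.DataFrame(label_rows, columns=["agent_id", "t", "rule_tag"])
    return table, labels


def split_corpus(
    table: pd.DataFrame,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[pd.DataFrame, ...]:
    """Split a trajectory table by agent into disjoint sub-tables.

    Default fractions give (train, validation, seed-pool). The split is a
    seeded permutation of agent ids; fractions must sum to 1.
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    agents = list(dict.fromkeys(table["agent_id"]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(agents))
    bounds = np.floor(np.cumsum(fractions) * len(agents)).astype(int)
    out: List[pd.DataFrame] = []
    start = 0
    for b in bounds:
        chosen = {agents[i] for i in order[start:b]}
        out.append(table[table["agent_id"].isin(chosen)].reset_index(drop=True))
        start = b
    return tuple(out)
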