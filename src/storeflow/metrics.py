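"""Behavioural evaluation metrics for multi-agent trajectory tables.

Six metrics compare two trajectory sets (e.g. ground truth vs. simulation):
cell-occupancy heatmaps, per-agent stay duration, travel distance, turning
angles vs. proximity to the nearest agent, speed vs. proximity to the two
nearest agents, speed vs. local density (agents within the 3×3 cell block
around the focal agent, focal included), and the RMSE between quadratic fits
of a crowding–response relationship (stay duration or travel distance as a
function of crowding level).

Conventions: per-tick speed is the displacement between consecutive 5-s
samples divided by 5 s, with stationary ticks contributing speed 0; the
turning angle at tick t is the angle between the displacements (t−1 → t) and
(t → t+1) and is skipped when either displacement is zero. All functions are
pure: identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import DT_SECONDS
from .geometry import GridSpec

__all__ = [
    "OccupancyMap",
    "FitCurve",
    "occupancy",
    "stay_and_distance",
    "stay_summary",
    "turn_ratio_by_proximity",
    "speed_by_proximity",
    "speed_by_density",
    "fit_quadratic",
    "rmse_between_fits",
    "per_tick_stats",
    "crowding_response",
    "compare_tables",
    "DEFAULT_DISTANCE_BINS",
]

#: Default nearest-agent distance bin edges, meters (0.5 m steps to 5 m).
DEFAULT_DISTANCE_BINS = tuple(np.arange(0.0, 5.5, 0.5))


@dataclass
class OccupancyMap:
    """Per-cell visit counts and normalised frequencies."""

    counts: np.ndarray  # (n_rows, n_cols) int
    freqs: np.ndarray  # (n_rows, n_cols) float, sums to 1 over visited cells

    def __add__(self, other: "OccupancyMap") -> "OccupancyMap":
        counts = self.counts + other.counts
        total = counts.sum()
        return OccupancyMap(counts, counts / total if total else counts.astype(float))


@dataclass(frozen=True)
class FitCurve:
    """Quadratic least-squares fit ``y ≈ c0 + c1·x + c2·x²``."""

    c0: float
    c1: float
    c2: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c0 + self.c1 * x + self.c2 * x * x

    @property
    def coeffs(self) -> Tuple[float, float, float]:
        return (self.c0, self.c1, self.c2)


def occupancy(table: pd.DataFrame, grid: GridSpec) -> OccupancyMap:
    """Count every (agent, tick) observation once per cell."""
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    if len(table):
        np.add.at(
            counts,
            (table["row"].to_numpy(int), table["col"].to_numpy(int)),
            1,
        )
    total = counts.sum()
    freqs = counts / total if total else counts.astype(float)
    return OccupancyMap(counts, freqs)


def stay_and_distance(table: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Per-agent stay (min), travel distance (m) and mean speed (m/s).

    Distance sums Euclidean center-to-center step lengths; stay is
    (last − first tick) in minutes; speed is distance / stay, reported as NaN
    for single-tick agents (stay 0, undefined).
    """
    s = grid.cell_size_m
    rows = []
    for aid, g in table.groupby("agent_id", sort=True):
        g = g.sort_values("t")
        x = g["col"].to_numpy(float) * s
        y = g["row"].to_numpy(float) * s
        dist = float(np.hypot(np.diff(x), np.diff(y)).sum())
        stay_min = float((g["t"].iloc[-1] - g["t"].iloc[0]) / 60.0)
        speed = dist / (stay_min * 60.0) if stay_min > 0 else np.nan
        rows.append((aid, stay_min, dist, speed))
    return pd.DataFrame(
        rows, columns=["agent_id", "stay_min", "distance_m", "speed_m_s"]
    )


def per_tick_stats(table: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Per-(agent, tick) kinematics and social context.

    Columns: ``speed`` (m/s over the step t → t+Δt; NaN on an agent's last
    tick), ``turn_deg`` (angle between adjacent displacements; NaN where
    undefined), ``d1``/``d2`` (meters to nearest / second-nearest agent at
    tick t; NaN when absent) and ``density`` (3×3-block count incl. focal).
    """
    s = grid.cell_size_m
    if len(table) == 0:
        return pd.DataFrame(
            columns=["agent_id", "t", "speed", "turn_deg", "d1", "d2", "density"]
        )
    tab = table.sort_values(["agent_id", "t"], kind="mergesort").reset_index(drop=True)
    aid = tab["agent_id"].to_numpy()
    t = tab["t"].to_numpy(float)
    col = tab["col"].to_numpy(float)
    row = tab["row"].to_numpy(float)
    n = len(tab)
    same_next = np.zeros(n, bool)
    same_next[:-1] = (aid[:-1] == aid[1:]) & (np.abs(t[1:] - t[:-1] - DT_SECONDS) < 1e-6)
    dx = np.full(n, np.nan)
    dy = np.full(n, np.nan)
    dx[same_next] = (col[1:] - col[:-1])[same_next[:-1]] * s
    dy[same_next] = (row[1:] - row[:-1])[same_next[:-1]] * s
    speed = np.hypot(dx, dy) / DT_SECONDS

    # turning angle at t between (t-1 -> t) and (t -> t+1)
    turn = np.full(n, np.nan)
    px = np.full(n, np.nan)
    py = np.full(n, np.nan)
    px[1:] = np.where(same_next[:-1], dx[:-1], np.nan)
    py[1:] = np.where(same_next[:-1], dy[:-1], np.nan)
    ok = (
        ~np.isnan(px) & ~np.isnan(dx)
        & ((px != 0) | (py != 0)) & ((dx != 0) | (dy != 0))
    )
    dot = px * dx + py * dy
    norm = np.hypot(px, py) * np.hypot(dx, dy)
    with np.errstate(invalid="ignore"):
        cosang = np.clip(dot / norm, -1.0, 1.0)
    turn[ok] = np.degrees(np.arccos(cosang[ok]))

    # neighbour distances and local density per tick
    d1 = np.full(n, np.nan)
    d2 = np.full(n, np.nan)
    density = np.ones(n, dtype=np.int64)
    for _, idx in pd.Series(np.arange(n)).groupby(t):
        ix = idx.to_numpy()
        if len(ix) == 0:
            continue
        cx = (col[ix] + 0.5) * s
        cy = (row[ix] + 0.5) * s
        if len(ix) > 1:
            diff_x = cx[:, None] - cx[None, :]
            diff_y = cy[:, None] - cy[None, :]
            dist = np.sqrt(diff_x**2 + diff_y**2)
            np.fill_diagonal(dist, np.inf)
            part = np.sort(dist, axis=1)
            d1[ix] = part[:, 0]
            if len(ix) > 2:
                d2[ix] = part[:, 1]
            cheb = np.maximum(
                np.abs(col[ix][:, None] - col[ix][None, :]),
                np.abs(row[ix][:, None] - row[ix][None, :]),
            )
            density[ix] = (cheb <= 1).sum(1)
    return pd.DataFrame(
        {
            "agent_id": aid,
            "t": t,
            "speed": speed,
            "turn_deg": turn,
            "d1": d1,
            "d2": d2,
            "density": density,
        }
    )


def turn_ratio_by_proximity(
    table: pd.DataFrame,
    grid: GridSpec,
    bins: Sequence[float] = DEFAULT_DISTANCE_BINS,
    threshold_deg: float = 90.0,
    stats: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Big-turn ratio (angle ≥ threshold) per nearest-agent-distance bin.

    Each defined turning angle is assigned to the bin of the focal agent's
    nearest-agent distance at the turn tick; ticks with no other agent
    present are excluded. Empty bins get ratio NaN (undefined, not zero).
    """
    st = per_tick_stats(table, grid) if stats is None else stats
    ok = ~st["turn_deg"].isna() & ~st["d1"].isna()
    d = st.loc[ok, "d1"].to_numpy()
    big = (st.loc[ok, "turn_deg"].to_numpy() >= threshold_deg).astype(float)
    edges = np.asarray(bins, dtype=float)
    which = np.digitize(d, edges) - 1
    n_bins = len(edges) - 1
    out = []
    for b in range(n_bins):
        sel = which == b
        n_turns = int(sel.sum())
        ratio = float(big[sel].mean()) if n_turns else np.nan
        out.append((edges[b], edges[b + 1], n_turns, int(big[sel].sum()), ratio))
    return pd.DataFrame(
        out, columns=["d_lo", "d_hi", "n_turns", "n_big", "big_turn_ratio"]
    )


def speed_by_proximity(
    table: pd.DataFrame,
    grid: GridSpec,
    d1_bins: Sequence[float] = DEFAULT_DISTANCE_BINS,
    d2_bins: Sequence[float] = DEFAULT_DISTANCE_BINS,
    stats: Optional[pd.DataFrame] = None,
) -> Dict[str, np.ndarray]:
    """Mean per-tick speed binned by (nearest, second-nearest) distance.

    Returns a dict with the 2-D ``mean`` / ``count`` arrays (NaN mean for
    empty cells) plus the ``absent`` margin — observations with fewer than
    two other agents present, split by whether a nearest agent existed.
    """
    st = per_tick_stats(table, grid) if stats is None else stats
    ok = ~st["speed"].isna()
    st = st[ok]
    e1 = np.asarray(d1_bins, float)
    e2 = np.asarray(d2_bins, float)
    n1, n2 = len(e1) - 1, len(e2) - 1
    total = np.zeros((n1, n2))
    count = np.zeros((n1, n2), dtype=np.int64)
    both = ~st["d1"].isna() & ~st["d2"].isna()
    b1 = np.digitize(st.loc[both, "d1"], e1) - 1
    b2 = np.digitize(st.loc[both, "d2"], e2) - 1
    sp = st.loc[both, "speed"].to_numpy()
    inside = (b1 >= 0) & (b1 < n1) & (b2 >= 0) & (b2 < n2)
    np.add.at(total, (b1[inside], b2[inside]), sp[inside])
    np.add.at(count, (b1[inside], b2[inside]), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    only_d1 = ~st["d1"].isna() & st["d2"].isna()
    alone = st["d1"].isna()
    return {
        "d1_edges": e1,
        "d2_edges": e2,
        "mean": mean,
        "count": count,
        "absent_second_mean": float(st.loc[only_d1, "speed"].mean())
        if only_d1.any() else np.nan,
        "absent_second_count": int(only_d1.sum()),
        "alone_mean": float(st.loc[alone, "speed"].mean()) if alone.any() else np.nan,
        "alone_count": int(alone.sum()),
    }


def speed_by_density(
    table: pd.DataFrame,
    grid: GridSpec,
    max_class: int = 5,
    stats: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Mean per-tick speed per local-density class 1..max_class (top pooled).

    Local density counts agents (focal included) in the 3×3 cell block
    centered on the focal agent's cell, clipped at the store edge.
    """
    st = per_tick_stats(table, grid) if stats is None else stats
    st = st[~st["speed"].isna()]
    dens = np.minimum(st["density"].to_numpy(int), max_class)
    sp = st["speed"].to_numpy()
    rows = []
    for c in range(1, max_class + 1):
        sel = dens == c
        rows.append(
            (c, int(sel.sum()), float(sp[sel].mean()) if sel.any() else np.nan)
        )
    return pd.DataFrame(rows, columns=["density", "n_obs", "mean_speed"])


def stay_summary(
    table: pd.DataFrame,
    grid: GridSpec,
    crowding_threshold: int = 6,
) -> pd.DataFrame:
    """Stay-duration quartiles grouped by concurrent in-store count class.

    An agent's crowding class is the mean number of agents simultaneously
    in store over its visit, rounded, classed as below / at-or-above the
    threshold (default 6).
    """
    if len(table) == 0:
        return pd.DataFrame(
            columns=["crowding_class", "n_agents", "q1", "median", "q3"]
        )
    counts_per_tick = table.groupby("t")["agent_id"].nunique()
    per_agent = stay_and_distance(table, grid).set_index("agent_id")
    classes = {}
    for aid, g in table.groupby("agent_id", sort=True):
        mean_n = counts_per_tick.loc[g["t"]].mean()
        classes[aid] = int(round(mean_n))
    per_agent["crowding_n"] = pd.Series(classes)
    per_agent["crowding_class"] = np.where(
        per_agent["crowding_n"] < crowding_threshold,
        f"n<{crowding_threshold}",
        f"n>={crowding_threshold}",
    )
    rows = []
    for cls, g in per_agent.groupby("crowding_class"):
        q1, med, q3 = np.percentile(g["stay_min"], [25, 50, 75])
        rows.append((cls, len(g), q1, med, q3))
    return pd.DataFrame(rows, columns=["crowding_class", "n_agents", "q1", "median", "q3"])


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> FitCurve:
    """Ordinary least-squares degree-2 fit (requires ≥ 3 distinct x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 3:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    c = np.polynomial.polynomial.polyfit(x, y, 2)
    return FitCurve(float(c[0]), float(c[1]), float(c[2]))


def rmse_between_fits(
    a: FitCurve, b: FitCurve, grid: Sequence[float]
) -> float:
    """Root mean squared difference of two fitted curves on shared points."""
    xs = np.asarray(grid, float)
    if xs.size == 0:
        raise ValueError("empty evaluation grid")
    return float(np.sqrt(np.mean((a(xs) - b(xs)) ** 2)))


def crowding_response(
    tables: Dict[float, pd.DataFrame], grid: GridSpec
) -> pd.DataFrame:
    """Mean stay / travel distance per crowding condition.

    ``tables`` maps a crowding level (e.g. arrival rate in persons/min) to a
    trajectory table; rows are sorted by level. Feed the columns to
    :func:`fit_quadratic` to build the curves whose RMSE quantifies how
    closely a simulation tracks crowding-dependent behaviour.
    """
    rows = []
    for level in sorted(tables):
        sd = stay_and_distance(tables[level], grid)
        rows.append(
            (
                level,
                len(sd),
                float(sd["stay_min"].mean()),
                float(sd["distance_m"].mean()),
                float(sd["speed_m_s"].mean()),
            )
        )
    return pd.DataFrame(
        rows, columns=["level", "n_agents", "stay_min", "distance_m", "speed_m_s"]
    )


def compare_tables(
    real: pd.DataFrame,
    sim: pd.DataFrame,
    grid: GridSpec,
    bins: Sequence[float] = DEFAULT_DISTANCE_BINS,
) -> dict:
    """Full metric report comparing two trajectory tables (JSON-ready)."""
    report: dict = {}
    for name, tab in (("real", real), ("sim", sim)):
        st = per_tick_stats(tab, grid)
        occ = occupancy(tab, grid)
        sd = stay_and_distance(tab, grid)
        report[name] = {
            "n_agents": int(tab["agent_id"].nunique()) if len(tab) else 0,
            "stay_min_mean": float(sd["stay_min"].mean()) if len(sd) else None,
            "distance_m_mean": float(sd["distance_m"].mean()) if len(sd) else None,
            "speed_m_s_mean": float(sd["speed_m_s"].mean()) if len(sd) else None,
            "occupancy_freqs": occ.freqs.tolist(),
            "turn_ratio": turn_ratio_by_proximity(tab, grid, bins, stats=st)
            .to_dict("list"),
            "speed_by_density": speed_by_density(tab, grid, stats=st).to_dict("list"),
            "stay_summary": stay_summary(tab, grid).to_dict("list"),
        }
    ra = np.asarray(report["real"]["occupancy_freqs"]).ravel()
    sa = np.asarray(report["sim"]["occupancy_freqs"]).ravel()
    if ra.std() > 0 and sa.std() > 0:
        report["occupancy_correlation"] = float(np.corrcoef(ra, sa)[0, 1])
    return report
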