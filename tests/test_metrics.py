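"""Metric suite: closed forms, planted signals, brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from storeflow.geometry import GridSpec
from storeflow.metrics import (
    crowding_response,
    fit_quadratic,
    occupancy,
    per_tick_stats,
    rmse_between_fits,
    speed_by_density,
    speed_by_proximity,
    stay_and_distance,
    stay_summary,
    turn_ratio_by_proximity,
)


def table_from(paths):
    """paths: {agent_id: [(col,row), ...]} starting at t=0, 5-s ticks."""
    rows = []
    for aid, cells in paths.items():
        for i, (c, r) in enumerate(cells):
            rows.append((aid, 5.0 * i, c, r))
    return pd.DataFrame(rows, columns=["agent_id", "t", "col", "row"])


GRID = GridSpec(16, 16, 4, 0.25)


class TestOccupancy:
    def test_parked_agent_single_cell(self):
        t = table_from({"a": [(3, 4)] * 10})
        occ = occupancy(t, GRID)
        assert occ.counts[4, 3] == 10
        assert occ.freqs[4, 3] == 1.0

    def test_additivity(self):
        t1 = table_from({"a": [(0, 0)] * 4})
        t2 = table_from({"b": [(5, 5)] * 6})
        both = occupancy(pd.concat([t1, t2]), GRID)
        summed = occupancy(t1, GRID) + occupancy(t2, GRID)
        np.testing.assert_array_equal(both.counts, summed.counts)
        assert both.freqs.sum() == pytest.approx(1.0)

    def test_random_walk_approaches_uniform_on_torus_free_grid(self):
        # an ergodic symmetric walk on a 2x2 grid visits cells uniformly
        rng = np.random.default_rng(0)
        g = GridSpec(2, 2, 1, 1.0)
        pos = (0, 0)
        cells = []
        for _ in range(20_000):
            c, r = pos
            moves = [(c2, r2) for c2, r2 in
                     [(c + 1, r), (c - 1, r), (c, r + 1), (c, r - 1)]
                     if 0 <= c2 < 2 and 0 <= r2 < 2]
            pos = moves[rng.integers(len(moves))]
            cells.append(pos)
        occ = occupancy(table_from({"a": cells}), g)
        np.testing.assert_allclose(occ.freqs, 0.25, atol=0.02)


class TestStayAndDistance:
    def test_worked_arithmetic_example(self):
        # 1 cell east per tick for 12 ticks (13 observations), 0.25 m cells
        t = table_from({"a": [(c, 0) for c in range(13)]})
        out = stay_and_distance(t, GRID).iloc[0]
        assert out["distance_m"] == pytest.approx(3.0)
        assert out["stay_min"] == pytest.approx(1.0)
        assert out["speed_m_s"] == pytest.approx(0.05)

    def test_stationary_agent_zero_distance(self):
        out = stay_and_distance(table_from({"a": [(2, 2)] * 5}), GRID).iloc[0]
        assert out["distance_m"] == 0.0

    def test_single_tick_agent_undefined_speed(self):
        out = stay_and_distance(table_from({"a": [(2, 2)]}), GRID).iloc[0]
        assert out["stay_min"] == 0.0
        assert np.isnan(out["speed_m_s"])

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(4)
        paths = {
            a: [tuple(rng.integers(16, size=2)) for _ in range(rng.integers(2, 30))]
            for a in range(8)
        }
        got = stay_and_distance(table_from(paths), GRID).set_index("agent_id")
        for a, cells in paths.items():
            dist = 0.0
            for (c0, r0), (c1, r1) in zip(cells, cells[1:]):
                dist += np.hypot(c1 - c0, r1 - r0) * GRID.cell_size_m
            assert got.loc[a, "distance_m"] == pytest.approx(dist)


class TestTurnRatio:
    def test_straight_walker_never_big_turns(self):
        t = table_from({"a": [(c, 0) for c in range(10)],
                        "b": [(c, 2) for c in range(10)]})
        out = turn_ratio_by_proximity(t, GRID)
        ratios = out["big_turn_ratio"].dropna()
        assert (ratios == 0).all()

    def test_back_and_forth_walker_always_big_turns(self):
        # both agents strictly alternate (180° turns), so every defined
        # angle in every bin is a big turn
        t = table_from({"a": [(0, 0), (1, 0)] * 5, "b": [(5, 0), (6, 0)] * 5})
        out = turn_ratio_by_proximity(t, GRID)
        defined = out["big_turn_ratio"].dropna()
        assert len(defined) > 0
        assert (defined == 1.0).all()

    def test_planted_turns_only_near_neighbour(self):
        """Turns planted only when the nearest agent is close show up in the
        near-distance bin and nowhere else."""
        # focal zig-zags (90° turns) with the companion one cell away, then
        # walks straight while the companion sits far away
        zig = []
        for i in range(7):
            zig.append((i, i))
            zig.append((i + 1, i))
        straight = [(i, 9) for i in range(14)]
        comp_near = [(c, r + 1) for c, r in zig]
        comp_far = [(15, 15)] * 14
        t1 = table_from({"f": zig, "c": comp_near})
        t2 = table_from({"f2": straight, "c2": comp_far})
        t2["t"] += 1000 * 5.0  # disjoint time window
        t = pd.concat([t1, t2], ignore_index=True)
        out = turn_ratio_by_proximity(t, GRID, bins=[0.0, 1.0, 2.0, 6.0])
        near_ratio = out.iloc[0]["big_turn_ratio"]
        far_ratio = out.iloc[2]["big_turn_ratio"]
        assert near_ratio == 1.0
        assert far_ratio == 0.0

    def test_empty_bin_is_nan_not_zero(self):
        t = table_from({"a": [(c, 0) for c in range(5)],
                        "b": [(c, 1) for c in range(5)]})
        out = turn_ratio_by_proximity(t, GRID, bins=[0.0, 0.1, 4.0])
        assert np.isnan(out.iloc[0]["big_turn_ratio"])


class TestSpeedByProximity:
    def test_single_agent_all_in_alone_margin(self):
        t = table_from({"a": [(c, 0) for c in range(6)]})
        out = speed_by_proximity(t, GRID)
        assert out["count"].sum() == 0
        assert out["alone_count"] == 5
        assert out["alone_mean"] == pytest.approx(0.25 / 5.0)

    def test_planted_slowdown_rule_recovered(self):
        """Agents built to move at half speed when d1 < 1 m reproduce a
        near/far mean-speed ratio of exactly 0.5."""
        # far pair: walker at 2 cells/tick, buddy parked 9 cells away
        f_far = table_from({"f_far": [(2 * i, 0) for i in range(8)],
                            "b1": [(0, 9)] * 8})
        # near pair: walker at 1 cell/tick, buddy tracking one row away
        near = table_from({"f_near": [(i, 8) for i in range(8)],
                           "b2": [(i, 9) for i in range(8)]})
        near["t"] += 500 * 5.0
        t = pd.concat([f_far, near], ignore_index=True)
        st = per_tick_stats(t, GRID)
        f = st[st["agent_id"].isin(["f_far", "f_near"]) & ~st["speed"].isna()]
        near_mean = f[f["d1"] < 1.0]["speed"].mean()
        far_mean = f[f["d1"] >= 1.0]["speed"].mean()
        assert near_mean / far_mean == pytest.approx(0.5)

    def test_refined_bins_reaggregate_to_coarse(self):
        rng = np.random.default_rng(2)
        paths = {
            a: [tuple(rng.integers(16, size=2)) for _ in range(20)]
            for a in range(6)
        }
        t = table_from(paths)
        coarse = speed_by_proximity(t, GRID, [0, 2, 4], [0, 2, 4])
        fine = speed_by_proximity(t, GRID, [0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        # weighted re-aggregation of the fine table equals the coarse table
        for i in range(2):
            for j in range(2):
                cnt = fine["count"][2 * i: 2 * i + 2, 2 * j: 2 * j + 2]
                tot = np.nansum(
                    fine["mean"][2 * i: 2 * i + 2, 2 * j: 2 * j + 2] * cnt
                )
                if cnt.sum():
                    assert coarse["mean"][i, j] == pytest.approx(tot / cnt.sum())
                    assert coarse["count"][i, j] == cnt.sum()


class TestSpeedByDensity:
    def test_lone_agent_density_one(self):
        t = table_from({"a": [(c, 0) for c in range(8)]})
        out = speed_by_density(t, GRID)
        assert out[out["density"] == 1]["n_obs"].iloc[0] == 7
        assert out[out["density"] > 1]["n_obs"].sum() == 0

    def test_adjacent_pair_density_two(self):
        t = table_from({"a": [(3, 3)] * 5, "b": [(4, 3)] * 5})
        out = speed_by_density(t, GRID)
        assert out[out["density"] == 2]["n_obs"].iloc[0] == 8

    def test_matches_brute_force_block_count(self):
        rng = np.random.default_rng(5)
        paths = {
            a: [tuple(rng.integers(16, size=2)) for _ in range(15)]
            for a in range(10)
        }
        t = table_from(paths)
        st = per_tick_stats(t, GRID)
        # oracle: explicit 3x3 block count per (agent, tick)
        for _, row in st.sample(50, random_state=0).iterrows():
            frame = t[t["t"] == row["t"]]
            me = frame[frame["agent_id"] == row["agent_id"]].iloc[0]
            n = (
                (frame["col"].sub(me["col"]).abs() <= 1)
                & (frame["row"].sub(me["row"]).abs() <= 1)
            ).sum()
            assert row["density"] == n


class TestQuadraticFits:
    def test_exact_interpolation_of_noiseless_quadratic(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2.0 - 1.5 * x + 0.25 * x * x
        fit = fit_quadratic(x, y)
        assert fit.coeffs == pytest.approx((2.0, -1.5, 0.25), abs=1e-9)
        assert np.max(np.abs(fit(x) - y)) < 1e-9

    def test_constant_response(self):
        fit = fit_quadratic([1, 2, 3, 4], [7.0] * 4)
        assert fit.coeffs == pytest.approx((7.0, 0.0, 0.0), abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 100)
        y = 1 + 2 * x - 0.3 * x**2 + rng.normal(0, 0.5, 100)
        fit = fit_quadratic(x, y)
        X = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coeffs == pytest.approx(tuple(beta), rel=1e-8)
        # residual orthogonality (normal-equation check)
        resid = y - fit(x)
        assert np.max(np.abs(X.T @ resid)) < 1e-6

    def test_too_few_distinct_x_raises(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 2.0], [1, 2, 3])

    def test_rmse_identical_curves_zero(self):
        f = fit_quadratic([0, 1, 2], [1.0, 2.0, 5.0])
        assert rmse_between_fits(f, f, [0, 1, 2, 3]) == 0.0

    def test_rmse_constant_offset(self):
        a = fit_quadratic([0, 1, 2], [1.0, 2.0, 5.0])
        b = fit_quadratic([0, 1, 2], [1.0 + 3.5, 2.0 + 3.5, 5.0 + 3.5])
        assert rmse_between_fits(a, b, np.linspace(0, 2, 7)) == pytest.approx(3.5)

    def test_rmse_matches_pointwise_oracle(self):
        a = fit_quadratic([0, 1, 2], [1.0, 0.5, 4.0])
        b = fit_quadratic([0, 1, 2], [2.0, -1.0, 3.0])
        xs = np.linspace(0, 2, 5)
        want = np.sqrt(np.mean([(a(x) - b(x)) ** 2 for x in xs]))
        assert rmse_between_fits(a, b, xs) == pytest.approx(want)

    def test_empty_grid_raises(self):
        f = fit_quadratic([0, 1, 2], [1.0, 2.0, 5.0])
        with pytest.raises(ValueError):
            rmse_between_fits(f, f, [])


class TestStaySummary:
    def test_crowding_classes_split(self):
        # 8 agents overlapping in time -> n>=6 class; 2 lone agents -> n<6
        paths = {}
        for a in range(8):
            paths[f"busy{a}"] = [(a, a)] * 12
        t_busy = table_from(paths)
        lone = []
        for a in range(2):
            for i in range(4):
                lone.append((f"lone{a}", 5.0 * (100 + i + 10 * a), 1, 1))
        t = pd.concat(
            [t_busy, pd.DataFrame(lone, columns=["agent_id", "t", "col", "row"])]
        )
        out = stay_summary(t, GRID)
        classes = dict(zip(out["crowding_class"], out["n_agents"]))
        assert classes == {"n<6": 2, "n>=6": 8}

    def test_purely_pure_function(self, small_world):
        cfg, table, _ = small_world
        a = stay_summary(table, cfg.grid)
        b = stay_summary(table.sample(frac=1.0, random_state=1), cfg.grid)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )


def test_crowding_response_sorted_levels(small_world):
    cfg, table, _ = small_world
    out = crowding_response({2.0: table, 0.5: table}, cfg.grid)
    assert list(out["level"]) == [0.5, 2.0]
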