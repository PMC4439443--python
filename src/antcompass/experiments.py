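"""End-to-end experiment drivers over the synthetic ant world.

Three analyses, each yielding a tidy per-evaluation table plus a summary:

* pitch sweep -- how a systematic pitch difference between a stored reference
  and the current view shifts the rIDF minimum and flattens the rIDF, at 81
  locations along the route and nine pitch levels;
* strategy evaluation -- heading error of five memory-retrieval strategies at
  those 81 locations, under five learning/test pitch-distribution scenarios;
* route experiment -- closed-loop route recapitulation under matched and
  mismatched pitch scenarios, reporting the halt outcome of each run.

A single master seed fans out deterministically to every stage, so a full run
is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .compass import compute_ridf, detectability, heading_error, ridf_minimum
from .eye import Pose, RetinaSpec, render_scan, render_view
from .memory import (MemoryBank, StrategySpec, best_match, build_averaged_bank,
                     build_memory_bank, candidate_indices, pairwise_sq_diffs)
from .recap import recapitulate_route
from .world import (PitchDistribution, Route, World, WorldParams,
                    generate_route, generate_world, sample_pitch_trace,
                    spawn_seeds)

__all__ = ["ExperimentConfig", "Environment", "build_environment",
           "run_pitch_sweep", "run_strategy_evaluation", "run_route_experiment"]

SCENARIOS = (("zero", "zero"), ("small", "small"), ("large", "large"),
             ("small", "large"), ("large", "small"))
PITCH_LEVELS = (-40.0, -20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class ExperimentConfig:
    world_params: WorldParams = WorldParams()
    route_length_m: float = 8.12
    memory_spacing_m: float = 0.01
    test_spacing_m: float = 0.10
    pitch_levels: tuple = PITCH_LEVELS
    scenarios: tuple = SCENARIOS
    strategies: tuple = ("closest", "local", "full", "limited", "averaged")
    ridf_step_deg: float = 2.0
    n_recap_seeds: int = 1
    master_seed: int = 0
    retina: RetinaSpec = field(default_factory=RetinaSpec)

    def __post_init__(self) -> None:
        ratio = self.route_length_m / self.memory_spacing_m
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError("memory spacing must divide the route length")
        for pair in self.scenarios:
            if tuple(pair) not in {(a, b) for a in ("zero", "small", "large")
                                   for b in ("zero", "small", "large")}:
                raise ValueError(f"unknown scenario {pair}")


@dataclass
class Environment:
    """A seeded world + route + test grid shared by the experiments."""

    config: ExperimentConfig
    world: World
    route: Route
    test_point_idx: np.ndarray     # route point indices of the test locations
    seeds: dict

    @property
    def n_tests(self) -> int:
        return len(self.test_point_idx)

    def test_memory_index(self, k: int) -> int:
        """1-based index of the memory co-located with test location k."""
        step = int(round(self.config.test_spacing_m / self.config.memory_spacing_m))
        return k * step


def build_environment(config: ExperimentConfig) -> Environment:
    """Generate the seeded world and route and lay out the test grid.

    Test locations sit on the memory grid every ``test_spacing_m`` starting at
    the route origin (81 locations for the 8.12 m route at 10 cm); the
    co-located memory is excluded at retrieval time, so the nearest usable
    memory is always at least 1 cm away.
    """
    s = spawn_seeds(config.master_seed, 8)
    seeds = {"world": int(s[0]), "route": int(s[1]), "learn": int(s[2]),
             "test": int(s[3]), "recap": int(s[4]), "pool": int(s[5])}
    params = replace(config.world_params, seed=seeds["world"])
    world = generate_world(params)
    route = generate_route(world, config.route_length_m,
                           config.memory_spacing_m, seed=seeds["route"])
    step = int(round(config.test_spacing_m / config.memory_spacing_m))
    n_tests = int(np.floor(route.length_m / config.test_spacing_m + 1e-9))
    test_idx = np.arange(n_tests) * step
    # the last test point must leave a memory 1 cm further along for the
    # closest-memory strategy
    if test_idx[-1] >= route.n_points - 1:
        test_idx = test_idx[:-1]
    return Environment(config, world, route, test_idx, seeds)


def _distribution(kind: str, env: Environment) -> PitchDistribution:
    return PitchDistribution.from_kind(kind, seed=env.seeds["pool"])


def _learning_bank(env: Environment, kind: str,
                   cache: dict | None = None) -> MemoryBank:
    if cache is not None and kind in cache:
        return cache[kind]
    n_mem = len(env.route.storage_indices(env.config.memory_spacing_m))
    trace = sample_pitch_trace(_distribution(kind, env), n_mem,
                               seed=env.seeds["learn"])
    bank = build_memory_bank(env.world, env.route, trace, env.config.retina)
    if cache is not None:
        cache[kind] = bank
    return bank


# ---------------------------------------------------------------------------
# Pitch sweep (systematic effect of pitch on the rIDF)
# ---------------------------------------------------------------------------

def run_pitch_sweep(config: ExperimentConfig,
                    env: Environment | None = None,
                    pitch_levels=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """rIDF heading error and detectability per location x pitch level.

    At each test location a 0-pitch reference is rendered facing the route
    tangent; the view is then re-rendered over a full 360 deg yaw scan at each
    pitch level and differenced against the reference.  Returns (rows,
    summary): one row per evaluation, and per-level medians with IQR.
    """
    env = env or build_environment(config)
    levels = list(config.pitch_levels if pitch_levels is None else pitch_levels)
    rows = []
    for k, i in enumerate(env.test_point_idx):
        x, y = env.route.points[i]
        yaw = env.route.headings_deg[i]
        ref = render_view(env.world, Pose(x, y, yaw_deg=yaw, pitch_deg=0.0),
                          config.retina)
        for pitch in levels:
            ridf = compute_ridf(env.world, (x, y), pitch, ref,
                                config.ridf_step_deg)
            off, vmin = ridf_minimum(ridf)
            rows.append({
                "location": k, "s_cm": round(i * env.route.spacing_m * 100, 6),
                "pitch_deg": pitch,
                "offset_deg": off,
                "heading_error_deg": heading_error(yaw + off, yaw),
                "ridf_min": vmin,
                "detectability": detectability(ridf),
            })
    rows = pd.DataFrame(rows)
    summary = rows.groupby("pitch_deg").agg(
        median_error_deg=("heading_error_deg", "median"),
        iqr_error_deg=("heading_error_deg", _iqr),
        median_detectability=("detectability", "median"),
        n=("heading_error_deg", "size"),
    ).reset_index()
    return rows, summary


def _iqr(x) -> float:
    q1, q3 = np.percentile(np.asarray(x, dtype=float), [25, 75])
    return float(q3 - q1)


# ---------------------------------------------------------------------------
# Strategy evaluation (five strategies x five pitch scenarios)
# ---------------------------------------------------------------------------

def run_strategy_evaluation(config: ExperimentConfig,
                            env: Environment | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heading error of each retrieval strategy at every test location.

    For each scenario the learning bank is built with pitches from the
    learning distribution; at test time one pitch per location is drawn from
    the test distribution.  All strategies share the same 360 deg yaw scan at
    a location, so their errors are directly comparable.  Returns (rows,
    summary); the summary holds per-cell medians/IQR and a two-sample
    rank-sum p-value against the full-route strategy.
    """
    env = env or build_environment(config)
    cache: dict = {}
    yaws = np.arange(0.0, 360.0, config.ridf_step_deg)
    rows = []
    test_seeds = spawn_seeds(env.seeds["test"], len(config.scenarios))
    for sc, (learn_kind, test_kind) in enumerate(config.scenarios):
        bank = _learning_bank(env, learn_kind, cache)
        avg_images = build_averaged_bank(bank).images
        test_pitches = sample_pitch_trace(
            _distribution(test_kind, env), env.n_tests,
            seed=int(test_seeds[sc])).angles_deg
        prev_heading = {s: float(env.route.headings_deg[0])
                        for s in config.strategies}
        for k, i in enumerate(env.test_point_idx):
            x, y = env.route.points[i]
            tangent = env.route.headings_deg[i]
            t_pitch = float(test_pitches[k])
            t_index = env.test_memory_index(k)
            s_test = float(t_index)
            scan = render_scan(env.world, x, y, t_pitch, yaws, config.retina,
                               z=bank.eye_height_m)
            diffs = pairwise_sq_diffs(scan, bank.images)
            diffs_avg = pairwise_sq_diffs(scan, avg_images)
            for strat in config.strategies:
                sspec = StrategySpec(strategy=strat,
                                     scan_step_deg=config.ridf_step_deg)
                gated = (strat == "limited"
                         and abs(t_pitch) > sspec.pitch_limit_deg)
                if gated:
                    heading = prev_heading[strat]
                    m_idx, m_pitch, m_s = None, np.nan, np.nan
                else:
                    cand = candidate_indices(bank, t_index, sspec)
                    d = diffs_avg if strat == "averaged" else diffs
                    sub = d[:, cand - 1]
                    row, col = best_match(sub, cand, bank.s_cm[cand - 1], s_test)
                    heading = float(yaws[row])
                    m_idx = int(cand[col])
                    m_pitch = float(bank.pitch_deg[m_idx - 1])
                    m_s = float(bank.s_cm[m_idx - 1])
                prev_heading[strat] = heading
                rows.append({
                    "scenario": f"{learn_kind}/{test_kind}",
                    "strategy": strat, "location": k, "s_cm": s_test,
                    "test_pitch_deg": t_pitch,
                    "heading_deg": heading,
                    "heading_error_deg": heading_error(heading, tangent),
                    "matched_index": m_idx,
                    "pitch_mismatch_deg": (np.nan if m_idx is None
                                           else abs(m_pitch - t_pitch)),
                    "spatial_mismatch_cm": (np.nan if m_idx is None
                                            else abs(m_s - s_test)),
                })
    rows = pd.DataFrame(rows)
    summary = _strategy_summary(rows)
    return rows, summary


def _strategy_summary(rows: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (scenario, strat), grp in rows.groupby(["scenario", "strategy"]):
        err = grp["heading_error_deg"].to_numpy()
        full = rows[(rows["scenario"] == scenario)
                    & (rows["strategy"] == "full")]["heading_error_deg"]
        if strat != "full" and len(full):
            p_vs_full = float(stats.ranksums(err, full.to_numpy()).pvalue)
        else:
            p_vs_full = np.nan
        out.append({
            "scenario": scenario, "strategy": strat,
            "median_error_deg": float(np.median(err)),
            "iqr_error_deg": _iqr(err),
            "median_pitch_mismatch_deg":
                float(np.nanmedian(grp["pitch_mismatch_deg"])),
            "median_spatial_mismatch_cm":
                float(np.nanmedian(grp["spatial_mismatch_cm"])),
            "ranksum_p_vs_full": p_vs_full,
            "n": len(grp),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Closed-loop route experiment
# ---------------------------------------------------------------------------

def run_route_experiment(config: ExperimentConfig,
                         env: Environment | None = None) -> pd.DataFrame:
    """Recapitulate the route once per scenario per seed; tabulate outcomes."""
    env = env or build_environment(config)
    cache: dict = {}
    recap_seeds = spawn_seeds(env.seeds["recap"], config.n_recap_seeds)
    rows = []
    for learn_kind, test_kind in config.scenarios:
        bank = _learning_bank(env, learn_kind, cache)
        dist = _distribution(test_kind, env)
        for r, seed in enumerate(recap_seeds):
            res = recapitulate_route(env.world, bank, env.route, dist,
                                     seed=int(seed),
                                     step_deg=config.ridf_step_deg)
            rows.append({
                "scenario": f"{learn_kind}/{test_kind}",
                "seed": int(seed), "replicate": r,
                "outcome": res.outcome, "n_steps": res.n_steps,
                "final_distance_to_end_m": res.final_distance_to_end_m,
            })
    return pd.DataFrame(rows)
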