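"""Synthetic cohorts with known ground truth for the full pipeline.

The generator emulates the statistical structure the downstream analysis
assumes rather than any cognitive process: a cohort is a mixture of two
latent-ability clusters ("high" and "low" spatial learners), each
participant carrying a correlated pair of abilities (pointing precision,
shortcutting skill) drawn from a per-cluster bivariate normal.

Pointing trials follow a guessing mixture: with probability ``g(ability)``
(a logistic curve, high for low-ability simulants) the response bearing
is uniform on [0, 360) — producing the chance floor of 90 deg mean
absolute error — otherwise the signed error is von Mises around the true
bearing with concentration ``exp(k0 + k1 * ability - b_j)``, where
``b_j`` is a per-trial difficulty offset.

Shortcut trials have an ability-dependent Bernoulli success; successful
trials get efficiency 1 exactly with ability-dependent probability (the
ceiling mass) or ``1 + excess`` with a right-skewed (gamma) excess whose
scale falls with ability and rises with trial difficulty, censored above
at the learned-route efficiency. Unsuccessful trials carry no traveled
length (they are imputed downstream).

All randomness flows from one root seed through named substreams, so
each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .maze_paths import MazeGraph, Trajectory, build_maze, shortest_path_length

__all__ = [
    "ClusterSpec",
    "SimConfig",
    "LatentCohort",
    "generate_cohort",
    "generate_pointing_trials",
    "generate_shortcut_trials",
    "generate_study",
    "generate_attenuation_study",
    "simulate_walk",
    "fixture_maze",
    "PRESETS",
]

_SUBSTREAMS = ("cohort", "difficulty", "pointing_I", "pointing_II", "shortcut", "walks")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


@dataclass(frozen=True)
class ClusterSpec:
    """Latent-ability distribution of one cluster (unitless z-like scale)."""

    n: int
    pointing_mean: float
    pointing_sd: float
    shortcut_mean: float
    shortcut_sd: float
    rho: float  # within-cluster correlation of the two abilities

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("cluster size must be non-negative")
        if not (self.pointing_sd > 0 and self.shortcut_sd > 0):
            raise ValueError("ability SDs must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification of a synthetic cohort.

    Logistic curves are parameterized as ``expit(intercept + slope * ability)``
    (difficulty offsets enter with a minus sign where noted).
    """

    clusters: dict[str, ClusterSpec]
    n_pointing_trials: int = 27
    n_shortcut_trials: int = 20
    # pointing response model
    guess_intercept: float = -0.92   # g(a) = expit(guess_intercept - guess_slope * a)
    guess_slope: float = 1.68
    kappa_intercept: float = -1.43   # log kappa = kappa_intercept + kappa_gain * a - b_j
    kappa_gain: float = 1.5
    pointing_difficulty_sd: float = 0.4   # SD of pointing b_j offsets
    # shortcutting model
    success_intercept: float = 2.76  # P(success) = expit(. + success_slope * a - b_j)
    success_slope: float = 0.94
    perfect_intercept: float = -2.80  # P(efficiency == 1 | success)
    perfect_slope: float = 1.82
    excess_log_scale: float = 0.23   # log gamma scale = . - excess_slope * a + b_j
    excess_slope: float = 0.59
    excess_shape: float = 1.0        # gamma shape of the efficiency excess
    shortcut_difficulty_sd: float = 0.4
    learned_route_eff: float = 2.54  # ceiling / imputation constant
    seed: int = 0

    def __post_init__(self):
        if not self.clusters or sum(c.n for c in self.clusters.values()) <= 0:
            raise ValueError("config must define at least one non-empty cluster")
        if self.n_pointing_trials < 1 or self.n_shortcut_trials < 1:
            raise ValueError("trial counts must be positive")
        if not self.learned_route_eff > 1:
            raise ValueError("learned_route_eff (the ceiling) must exceed 1")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SimConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = json.loads(text)
        raw["clusters"] = {k: ClusterSpec(**v) for k, v in raw["clusters"].items()}
        return cls(**raw)


@dataclass(frozen=True)
class LatentCohort:
    """Per-participant latent abilities with cluster labels."""

    table: pd.DataFrame  # participant_id, cluster, pointing_ability, shortcut_ability

    @property
    def participant_ids(self) -> pd.Index:
        return pd.Index(self.table["participant_id"])


def generate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> LatentCohort:
    """Draw per-cluster bivariate-normal ability pairs."""
    if rng is None:
        rng = _rngs(config.seed)["cohort"]
    rows = []
    counter = 1
    for name, spec in config.clusters.items():
        cov = np.array(
            [
                [spec.pointing_sd**2, spec.rho * spec.pointing_sd * spec.shortcut_sd],
                [spec.rho * spec.pointing_sd * spec.shortcut_sd, spec.shortcut_sd**2],
            ]
        )
        # eigh tolerates the singular covariance at |rho| = 1
        draws = rng.multivariate_normal(
            [spec.pointing_mean, spec.shortcut_mean], cov, size=spec.n, method="eigh"
        )
        for point_a, short_a in draws:
            rows.append(
                {
                    "participant_id": f"p{counter:03d}",
                    "cluster": name,
                    "pointing_ability": float(point_a),
                    "shortcut_ability": float(short_a),
                }
            )
            counter += 1
    return LatentCohort(table=pd.DataFrame(rows))


def _pointing_difficulties(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, config.pointing_difficulty_sd, size=config.n_pointing_trials)


def _shortcut_difficulties(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, config.shortcut_difficulty_sd, size=config.n_shortcut_trials)


def _trial_pairs(rng: np.random.Generator, landmarks: list[str], n: int) -> list[tuple[str, str]]:
    pairs = []
    for _ in range(n):
        s, t = rng.choice(len(landmarks), size=2, replace=False)
        pairs.append((landmarks[s], landmarks[t]))
    return pairs


def generate_pointing_trials(
    cohort: LatentCohort,
    config: SimConfig,
    phase: str,
    rng: np.random.Generator | None = None,
    difficulties: np.ndarray | None = None,
    landmarks: list[str] | None = None,
) -> pd.DataFrame:
    """Pointing trials under the guessing + von Mises mixture.

    One shared set of trials (landmark pair, true bearing, difficulty)
    is drawn per phase; every participant answers each trial.
    """
    if phase not in ("I", "II"):
        raise ValueError("phase must be 'I' or 'II'")
    if rng is None:
        rng = _rngs(config.seed)[f"pointing_{phase}"]
    if difficulties is None:
        difficulties = _pointing_difficulties(config, rng)
    if landmarks is None:
        landmarks = [f"L{i:02d}" for i in range(1, 13)]

    n_trials = config.n_pointing_trials
    pairs = _trial_pairs(rng, landmarks, n_trials)
    true_bearings = rng.uniform(0.0, 360.0, size=n_trials)

    abilities = cohort.table["pointing_ability"].to_numpy()
    n_p = len(abilities)
    g = expit(config.guess_intercept - config.guess_slope * abilities)  # per participant
    log_kappa = (
        config.kappa_intercept
        + config.kappa_gain * abilities[:, None]
        - difficulties[None, :]
    )
    kappa = np.exp(log_kappa)

    guess = rng.random((n_p, n_trials)) < g[:, None]
    vm_err = rng.vonmises(0.0, kappa)  # radians in (-pi, pi]
    uniform_resp = rng.uniform(0.0, 360.0, size=(n_p, n_trials))
    responses = np.where(
        guess,
        uniform_resp,
        (true_bearings[None, :] + np.degrees(vm_err)) % 360.0,
    )

    pid = cohort.table["participant_id"].to_numpy()
    idx_p, idx_t = np.meshgrid(np.arange(n_p), np.arange(n_trials), indexing="ij")
    return pd.DataFrame(
        {
            "participant_id": pid[idx_p.ravel()],
            "phase": phase,
            "trial_id": [f"{phase}-{j + 1:02d}" for j in idx_t.ravel()],
            "start_landmark": [pairs[j][0] for j in idx_t.ravel()],
            "target_landmark": [pairs[j][1] for j in idx_t.ravel()],
            "response_bearing_deg": responses.ravel(),
            "true_bearing_deg": np.broadcast_to(true_bearings, (n_p, n_trials)).ravel(),
        }
    )


def generate_shortcut_trials(
    cohort: LatentCohort,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    maze: MazeGraph | None = None,
    difficulties: np.ndarray | None = None,
) -> pd.DataFrame:
    """Shortcut trials: Bernoulli success, ceiling mass at 1, censored excess."""
    if rng is None:
        rng = _rngs(config.seed)["shortcut"]
    if maze is None:
        maze = fixture_maze()
    if difficulties is None:
        difficulties = _shortcut_difficulties(config, rng)

    landmarks = list(maze.landmarks)
    n_trials = config.n_shortcut_trials
    pairs = []
    shortest = []
    while len(pairs) < n_trials:
        s, t = rng.choice(len(landmarks), size=2, replace=False)
        sl = shortest_path_length(maze, maze.landmarks[landmarks[s]], maze.landmarks[landmarks[t]])
        if sl > 0:
            pairs.append((landmarks[s], landmarks[t]))
            shortest.append(sl)
    shortest = np.array(shortest)

    abilities = cohort.table["shortcut_ability"].to_numpy()
    n_p = len(abilities)
    p_success = expit(
        config.success_intercept + config.success_slope * abilities[:, None] - difficulties[None, :]
    )
    p_perfect = expit(config.perfect_intercept + config.perfect_slope * abilities)
    scale = np.exp(
        config.excess_log_scale - config.excess_slope * abilities[:, None] + difficulties[None, :]
    )

    success = rng.random((n_p, n_trials)) < p_success
    perfect = rng.random((n_p, n_trials)) < p_perfect[:, None]
    excess = rng.gamma(config.excess_shape, scale)
    ceiling = config.learned_route_eff
    efficiency = np.where(perfect, 1.0, np.minimum(1.0 + excess, ceiling))
    traveled = efficiency * shortest[None, :]
    traveled = np.where(success, traveled, np.nan)

    pid = cohort.table["participant_id"].to_numpy()
    idx_p, idx_t = np.meshgrid(np.arange(n_p), np.arange(n_trials), indexing="ij")
    return pd.DataFrame(
        {
            "participant_id": pid[idx_p.ravel()],
            "trial_id": [f"S-{j + 1:02d}" for j in idx_t.ravel()],
            "start_landmark": [pairs[j][0] for j in idx_t.ravel()],
            "target_landmark": [pairs[j][1] for j in idx_t.ravel()],
            "success": success.ravel(),
            "traveled_length_m": traveled.ravel(),
            "shortest_length_m": shortest[idx_t.ravel()],
        }
    )


def simulate_walk(
    maze: MazeGraph, start: str, goal: str, fidelity: float, max_steps: int = 200,
    seed: int | None = None, rng: np.random.Generator | None = None,
) -> tuple[Trajectory, bool]:
    """Noisy greedy walk: shortest-path-reducing step w.p. ``fidelity``.

    At each node the walker moves to the neighbor minimizing the
    remaining shortest-path distance with probability ``fidelity``,
    otherwise to a uniformly random neighbor; stops at the goal or after
    ``max_steps`` (failure). Returns ``(trajectory, reached_goal)``.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    g = maze.graph()
    dist_to_goal = {
        n: float(d)
        for n, d in nx.single_source_dijkstra_path_length(g, goal, weight="length").items()
    }
    path = [start]
    node = start
    steps = 0
    total = 0.0
    while node != goal and steps < max_steps:
        nbrs = list(g.neighbors(node))
        if rng.random() < fidelity:
            nxt = min(nbrs, key=lambda v: dist_to_goal[v] + maze.edge_length(node, v))
        else:
            nxt = nbrs[int(rng.integers(len(nbrs)))]
        total += maze.edge_length(node, nxt)
        path.append(nxt)
        node = nxt
        steps += 1
    return Trajectory(nodes=tuple(path), total_length=total), node == goal


def fixture_maze(side: int = 4, spacing: float = 2.75) -> MazeGraph:
    """Synthetic stand-in maze: a square grid with 12 landmark nodes and a
    closed learned route around the boundary.

    The real experimental mazes are not machine-readable; this fixture
    only reproduces the structural features the pipeline consumes (a
    connected metric graph, landmarks, a guided-tour loop).
    """
    nodes = {}
    for i in range(side):
        for j in range(side):
            nodes[f"n{i}{j}"] = [i * spacing, j * spacing]
    edges = []
    for i in range(side):
        for j in range(side):
            if i + 1 < side:
                edges.append([f"n{i}{j}", f"n{i + 1}{j}"])
            if j + 1 < side:
                edges.append([f"n{i}{j}", f"n{i}{j + 1}"])
    # boundary loop, clockwise
    top = [f"n{i}{side - 1}" for i in range(side)]
    right = [f"n{side - 1}{j}" for j in range(side - 2, -1, -1)]
    bottom = [f"n{i}0" for i in range(side - 2, -1, -1)]
    left = [f"n0{j}" for j in range(1, side - 1)]
    loop = top + right + bottom + left + [top[0]]
    boundary = loop[:-1]
    lm_nodes = [boundary[round(k * len(boundary) / 12) % len(boundary)] for k in range(12)]
    landmarks = {f"L{k + 1:02d}": nid for k, nid in enumerate(dict.fromkeys(lm_nodes))}
    # pad if rounding collapsed any (needs side >= 4 for 12 distinct boundary nodes)
    extras = [n for n in boundary if n not in set(landmarks.values())]
    k = len(landmarks)
    while k < 12 and extras:
        landmarks[f"L{k + 1:02d}"] = extras.pop(0)
        k += 1
    return build_maze({"nodes": nodes, "edges": edges, "landmarks": landmarks, "learned_route": loop})


def generate_study(
    config: SimConfig, out_dir: str | Path | None = None
) -> dict[str, object]:
    """Generate a full dataset bundle: pointing I/II, shortcutting, maze.

    Returns a dict with keys ``pointing`` (both phases, one frame),
    ``shortcut``, ``maze``, ``cohort`` and ``config``. With ``out_dir``
    the CSV/JSON artifacts consumed by the pipeline are also written
    (pointing_phase_I.csv, pointing_phase_II.csv, shortcut.csv,
    maze.json, sim_config.json).
    """
    rngs = _rngs(config.seed)
    cohort = generate_cohort(config, rngs["cohort"])
    maze = fixture_maze()
    landmarks = list(maze.landmarks)
    p1 = generate_pointing_trials(cohort, config, "I", rngs["pointing_I"], landmarks=landmarks)
    p2 = generate_pointing_trials(cohort, config, "II", rngs["pointing_II"], landmarks=landmarks)
    sc = generate_shortcut_trials(cohort, config, rngs["shortcut"], maze=maze)
    pointing = pd.concat([p1, p2], ignore_index=True)
    bundle = {"pointing": pointing, "shortcut": sc, "maze": maze, "cohort": cohort, "config": config}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        p1.to_csv(out / "pointing_phase_I.csv", index=False, float_format=fmt)
        p2.to_csv(out / "pointing_phase_II.csv", index=False, float_format=fmt)
        sc.to_csv(out / "shortcut.csv", index=False, float_format=fmt)
        maze.to_json(out / "maze.json")
        config.to_json(out / "sim_config.json")
    return bundle


def generate_attenuation_study(
    n: int, rho: float, reliability_x: float, reliability_y: float,
    n_trials_x: int = 27, n_trials_y: int = 20, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two Gaussian trial matrices with engineered mean-score reliabilities.

    Per-trial score = latent ability + N(0, sigma_e) noise, with
    ``sigma_e^2 = J * (1 - R) / R`` (unit ability variance) so the
    J-trial mean has reliability exactly R. The two abilities are
    bivariate normal with correlation ``rho``, so the population
    correlation of the observed means is ``rho * sqrt(Rx * Ry)`` — the
    attenuation law the disattenuation correction inverts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for r in (reliability_x, reliability_y):
        if not 0 < r <= 1:
            raise ValueError("engineered reliabilities must lie in (0, 1]")
    ab = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n, method="eigh")
    sx = np.sqrt(n_trials_x * (1 - reliability_x) / reliability_x)
    sy = np.sqrt(n_trials_y * (1 - reliability_y) / reliability_y)
    X = ab[:, :1] + rng.normal(0, sx, size=(n, n_trials_x))
    Y = ab[:, 1:] + rng.normal(0, sy, size=(n, n_trials_y))
    ids = [f"p{i + 1:03d}" for i in range(n)]
    return (
        pd.DataFrame(X, index=pd.Index(ids, name="participant_id")),
        pd.DataFrame(Y, index=pd.Index(ids, name="participant_id")),
    )


def _desktop_like() -> SimConfig:
    """57 analyzed participants, 27 pointing / 20 shortcut trials,
    learned-route efficiency 2.54 — the harder, lower-visibility setting."""
    return SimConfig(
        clusters={
            "high": ClusterSpec(n=20, pointing_mean=1.2, pointing_sd=0.4,
                                shortcut_mean=1.2, shortcut_sd=0.4, rho=0.95),
            "low": ClusterSpec(n=37, pointing_mean=-0.6, pointing_sd=0.45,
                               shortcut_mean=-0.6, shortcut_sd=0.2, rho=0.95),
        },
        n_pointing_trials=27,
        n_shortcut_trials=20,
        learned_route_eff=2.54,
        seed=0,
    )


def _immersive_like() -> SimConfig:
    """48 analyzed participants, 24 + 24 trials, learned-route efficiency
    2.19 — easier environment: less guessing, stronger ceiling at 1."""
    return SimConfig(
        clusters={
            "high": ClusterSpec(n=24, pointing_mean=1.0, pointing_sd=0.4,
                                shortcut_mean=1.0, shortcut_sd=0.4, rho=0.95),
            "low": ClusterSpec(n=24, pointing_mean=-0.3, pointing_sd=0.45,
                               shortcut_mean=-0.3, shortcut_sd=0.25, rho=0.95),
        },
        n_pointing_trials=24,
        n_shortcut_trials=24,
        guess_intercept=-1.3,
        kappa_intercept=-0.94,
        success_intercept=3.22,
        success_slope=2.08,
        perfect_intercept=-2.3,
        perfect_slope=2.1,
        excess_log_scale=0.645,
        excess_slope=1.4,
        learned_route_eff=2.19,
        seed=0,
    )


PRESETS = {"desktop-like": _desktop_like, "immersive-like": _immersive_like}


def preset(name: str, seed: int | None = None) -> SimConfig:
    """A named study preset, optionally reseeded."""
    try:
        cfg = PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        cfg = SimConfig(**{**asdict(cfg), "clusters": cfg.clusters, "seed": seed})
    return cfg
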