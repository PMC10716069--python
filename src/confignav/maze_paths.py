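"""Metric maze graphs and path-length oracles for the shortcutting measure.

A maze is a connected, undirected metric graph: nodes carry planar
coordinates (meters), edges carry strictly positive lengths, named
landmarks sit on nodes, and a *learned route* — the guided tour walked
during the learning phase — is an ordered node sequence. The module
supplies the two quantities the travel-efficiency score consumes: the
shortest traversable path length between any two nodes (the denominator
of each trial's efficiency ratio) and the along-learned-route distance
between landmark pairs, whose trial-averaged ratio to the shortest path
is the *learned-route efficiency* used to impute failed trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "MazeGraph",
    "Trajectory",
    "MazeValidationError",
    "build_maze",
    "shortest_path_length",
    "route_length",
    "learned_route_efficiency",
]

Coord = tuple[float, float]


class MazeValidationError(ValueError):
    """Raised when a maze specification violates a structural invariant."""


@dataclass(frozen=True)
class MazeGraph:
    """Validated metric maze.

    Attributes
    ----------
    nodes : mapping node-id -> (x, y) in meters.
    edges : mapping of frozenset({a, b}) -> length in meters (> 0).
    landmarks : mapping landmark-name -> node-id.
    learned_route : ordered node-id sequence; consecutive pairs are edges.
    """

    nodes: dict[str, Coord]
    edges: dict[frozenset, float]
    landmarks: dict[str, str]
    learned_route: tuple[str, ...]
    _graph: nx.Graph = field(repr=False, compare=False, default=None)

    def graph(self) -> nx.Graph:
        """The underlying networkx graph (edge attribute ``length``)."""
        return self._graph

    def edge_length(self, a: str, b: str) -> float:
        try:
            return self.edges[frozenset((a, b))]
        except KeyError:
            raise MazeValidationError(f"({a}, {b}) is not an edge") from None

    @property
    def is_loop(self) -> bool:
        """True when the learned route returns to its starting node."""
        return len(self.learned_route) > 1 and self.learned_route[0] == self.learned_route[-1]

    def to_spec(self) -> dict:
        """Serialize to the JSON maze-specification schema."""
        return {
            "nodes": {n: list(xy) for n, xy in self.nodes.items()},
            "edges": [[*sorted(e), length] for e, length in sorted(self.edges.items(), key=lambda kv: sorted(kv[0]))],
            "landmarks": dict(self.landmarks),
            "learned_route": list(self.learned_route),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_spec(), indent=1))


@dataclass(frozen=True)
class Trajectory:
    """An ordered node sequence on a maze with its traversed length."""

    nodes: tuple[str, ...]
    total_length: float

    @property
    def n_steps(self) -> int:
        return len(self.nodes) - 1


def _euclidean(p: Coord, q: Coord) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def build_maze(spec: Mapping | str | Path) -> MazeGraph:
    """Build and validate a :class:`MazeGraph` from a specification.

    ``spec`` is a mapping with keys ``nodes`` (id -> [x, y]), ``edges``
    ([a, b] or [a, b, length]), ``landmarks`` (name -> id) and
    ``learned_route`` ([id, ...]), or a path to a JSON file holding one.
    Edge lengths default to the Euclidean distance between endpoint
    coordinates when omitted.

    Raises
    ------
    MazeValidationError
        On an unknown node-id, non-positive edge length, non-adjacent
        learned-route step, or a disconnected graph.
    """
    if isinstance(spec, (str, Path)):
        spec = json.loads(Path(spec).read_text())

    nodes = {str(n): (float(xy[0]), float(xy[1])) for n, xy in spec["nodes"].items()}
    if not nodes:
        raise MazeValidationError("maze has no nodes")

    edges: dict[frozenset, float] = {}
    for entry in spec["edges"]:
        a, b = str(entry[0]), str(entry[1])
        for v in (a, b):
            if v not in nodes:
                raise MazeValidationError(f"edge ({a}, {b}) references unknown node {v!r}")
        if a == b:
            raise MazeValidationError(f"self-loop edge at node {a!r}")
        length = float(entry[2]) if len(entry) > 2 else _euclidean(nodes[a], nodes[b])
        if not length > 0:
            raise MazeValidationError(f"edge ({a}, {b}) has non-positive length {length}")
        edges[frozenset((a, b))] = length

    landmarks = {str(name): str(nid) for name, nid in spec.get("landmarks", {}).items()}
    for name, nid in landmarks.items():
        if nid not in nodes:
            raise MazeValidationError(f"landmark {name!r} references unknown node {nid!r}")

    route = tuple(str(n) for n in spec.get("learned_route", []))
    for n in route:
        if n not in nodes:
            raise MazeValidationError(f"learned route references unknown node {n!r}")
    for a, b in zip(route, route[1:]):
        if frozenset((a, b)) not in edges:
            raise MazeValidationError(f"learned route step ({a}, {b}) is not an edge")

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e, length in edges.items():
        a, b = tuple(e)
        g.add_edge(a, b, length=length)
    if len(nodes) > 1 and not nx.is_connected(g):
        raise MazeValidationError("maze graph is disconnected")

    return MazeGraph(nodes=nodes, edges=edges, landmarks=landmarks, learned_route=route, _graph=g)


def shortest_path_length(maze: MazeGraph, a: str, b: str) -> float:
    """Length (meters) of the minimal-total-length path from ``a`` to ``b``."""
    for v in (a, b):
        if v not in maze.nodes:
            raise MazeValidationError(f"unknown node {v!r}")
    if a == b:
        return 0.0
    return float(nx.dijkstra_path_length(maze.graph(), a, b, weight="length"))


def route_length(maze: MazeGraph, route: Sequence[str]) -> float:
    """Total traversed length of a node sequence; revisits counted every time."""
    total = 0.0
    for a, b in zip(route, route[1:]):
        e = frozenset((a, b))
        if e not in maze.edges:
            raise MazeValidationError(f"consecutive route pair ({a}, {b}) is not an edge")
        total += maze.edges[e]
    return total


def trajectory(maze: MazeGraph, route: Sequence[str]) -> Trajectory:
    """Wrap a node sequence as a validated :class:`Trajectory`."""
    return Trajectory(nodes=tuple(route), total_length=route_length(maze, route))


def _along_route_distance(maze: MazeGraph, start_node: str, target_node: str) -> float:
    """Distance walked along the learned route from start to target.

    Walks forward from the first occurrence of ``start_node``, wrapping
    past the end when the route is a closed loop, until the first
    occurrence of ``target_node``.
    """
    route = list(maze.learned_route)
    if maze.is_loop:
        route = route[:-1]  # drop duplicated closing node
    try:
        i = route.index(start_node)
    except ValueError:
        raise MazeValidationError(f"node {start_node!r} is not on the learned route") from None
    if target_node not in route:
        raise MazeValidationError(f"node {target_node!r} is not on the learned route")

    dist = 0.0
    n = len(route)
    for step in range(1, n + 1):
        j = i + step
        if maze.is_loop:
            a, b = route[(j - 1) % n], route[j % n]
        else:
            if j >= n:
                raise MazeValidationError(
                    f"target {target_node!r} is not ahead of {start_node!r} on the open learned route"
                )
            a, b = route[j - 1], route[j]
        dist += maze.edge_length(a, b)
        node = route[j % n] if maze.is_loop else route[j]
        if node == target_node:
            return dist
    raise MazeValidationError(f"target {target_node!r} unreachable along the learned route")


def learned_route_efficiency(
    maze: MazeGraph, trial_pairs: Iterable[tuple[str, str]]
) -> float:
    """Mean efficiency of always following the learned route.

    For each (start landmark, target landmark) pair, the along-route
    travel distance divided by the shortest-path distance; the mean over
    trials is the imputation constant for unsuccessful shortcut trials.
    """
    ratios = []
    for start_lm, target_lm in trial_pairs:
        for lm in (start_lm, target_lm):
            if lm not in maze.landmarks:
                raise MazeValidationError(f"unknown landmark {lm!r}")
        s, t = maze.landmarks[start_lm], maze.landmarks[target_lm]
        along = _along_route_distance(maze, s, t)
        shortest = shortest_path_length(maze, s, t)
        ratios.append(along / shortest)
    if not ratios:
        raise MazeValidationError("no trial pairs supplied")
    return sum(ratios) / len(ratios)
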