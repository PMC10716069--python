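import numpy as np
import pytest

from confignav.maze_paths import build_maze


@pytest.fixture
def rng():
    return np.random.default_rng(20230317)


@pytest.fixture
def unit_grid_maze():
    """2x2 unit grid: 4 nodes, 4 edges of length 1."""
    return build_maze(
        {
            "nodes": {"a": [0, 0], "b": [1, 0], "c": [0, 1], "d": [1, 1]},
            "edges": [["a", "b"], ["a", "c"], ["b", "d"], ["c", "d"]],
            "landmarks": {"start": "a", "goal": "d"},
            "learned_route": ["a", "b", "d"],
        }
    )


@pytest.fixture
def loop_maze():
    """Square loop with a shortcut chord; learned route is the closed loop.

    Perimeter nodes A-B-C-D (unit edges), plus chord A-C of length 1.2.
    """
    return build_maze(
        {
            "nodes": {"A": [0, 0], "B": [1, 0], "C": [1, 1], "D": [0, 1]},
            "edges": [["A", "B"], ["B", "C"], ["C", "D"], ["D", "A"], ["A", "C", 1.2]],
            "landmarks": {"well": "A", "chair": "B", "plant": "C", "bench": "D"},
            "learned_route": ["A", "B", "C", "D", "A"],
        }
    )


def random_connected_graph_spec(rng, n_nodes: int, p_extra: float = 0.35) -> dict:
    """Random connected graph spec: a random spanning tree plus extra edges,
    with random positive lengths. Small enough for exhaustive path oracles."""
    names = [f"v{i}" for i in range(n_nodes)]
    nodes = {name: [float(rng.uniform(0, 10)), float(rng.uniform(0, 10))] for name in names}
    edges = []
    seen = set()
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append([names[i], names[j], float(rng.uniform(0.1, 5.0))])
        seen.add(frozenset((names[i], names[j])))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            key = frozenset((names[i], names[j]))
            if key not in seen and rng.random() < p_extra:
                edges.append([names[i], names[j], float(rng.uniform(0.1, 5.0))])
                seen.add(key)
    return {"nodes": nodes, "edges": edges, "landmarks": {}, "learned_route": []}


def exhaustive_shortest_path(spec: dict, a: str, b: str) -> float:
    """Independent oracle: minimum total length over all simple paths,
    by depth-first enumeration on the raw spec (no graph library)."""
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in spec["nodes"]}
    for entry in spec["edges"]:
        u, v, w = entry[0], entry[1], float(entry[2])
        adj[u].append((v, w))
        adj[v].append((u, w))
    best = [float("inf")]

    def dfs(node, visited, total):
        if total >= best[0]:
            return
        if node == b:
            best[0] = total
            return
        for nxt, w in adj[node]:
            if nxt not in visited:
                dfs(nxt, visited | {nxt}, total + w)

    dfs(a, {a}, 0.0)
    return best[0]
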