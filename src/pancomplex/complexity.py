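"""Random-walk genome complexity.

Complexity measures local gene-order variability along a reference genome.
For every node of the reference chain, random walks over the directed
gene-neighborhood graph discover *deviating paths* — simple paths that leave
the chain and return to it.  Each unique deviating path whose endpoints lie
within ``window`` chain positions of each other adds ``1/window`` to the
complexity of every reference node strictly between its endpoints.  In a set
of identical genomes no path bypasses any node and the profile is zero
everywhere; insertions, deletions and translocations add bypassing paths and
raise the profile locally.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .graph import GeneGraph, ReferenceChain

__all__ = [
    "ComplexityParams",
    "ComplexityProfile",
    "HotspotRegion",
    "HotspotResult",
    "find_paths",
    "enumerate_paths_exhaustive",
    "compute_complexity",
    "detect_hotspots",
]

Path = tuple[str, ...]


@dataclass(frozen=True)
class ComplexityParams:
    """Tunables of the complexity computation.

    window
        Half-width, in chain nodes, of the neighborhood a deviating path may
        span (default 20).
    iterations
        Number of random walks launched from each reference node (default
        500).
    rng_seed
        Seed for the walk RNG; fixed seed ⇒ bit-identical profiles.
    """

    window: int = 20
    iterations: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class ComplexityProfile:
    """Per-reference-node complexity values plus their genomic coordinates."""

    chain: ReferenceChain
    values: np.ndarray
    params: ComplexityParams

    def __len__(self) -> int:
        return len(self.values)

    def to_pairs(self) -> list[tuple[int, float]]:
        """(start_bp, complexity) pairs, the track-file payload."""
        return [
            (int(self.chain.coords[i]), float(self.values[i]))
            for i in range(len(self.values))
        ]


# ---------------------------------------------------------------------------
# path discovery
# ---------------------------------------------------------------------------


def _walk(
    succ: dict[str, tuple[str, ...]],
    start: str,
    terminate_on: set[str] | dict[str, int],
    rng: random.Random,
) -> Path | None:
    """One random walk from ``start``; returns the path or None if abandoned.

    At each step a uniformly random out-neighbor is drawn.  Landing on a
    reference node terminates the walk (the node is appended); drawing a node
    already on the path triggers a redraw among unvisited neighbors; if every
    out-neighbor is already on the path the walk is abandoned.
    """
    path = [start]
    seen = {start}
    current = start
    rand = rng.random
    while True:
        nbrs = succ.get(current)
        if not nbrs:
            return None
        nxt = nbrs[int(rand() * len(nbrs))] if len(nbrs) > 1 else nbrs[0]
        if nxt in terminate_on:
            path.append(nxt)
            return tuple(path)
        if nxt in seen:
            fresh = [n for n in nbrs if n not in seen]
            if not fresh:
                return None
            nxt = fresh[int(rand() * len(fresh))]
            if nxt in terminate_on:
                path.append(nxt)
                return tuple(path)
        path.append(nxt)
        seen.add(nxt)
        current = nxt


def find_paths(
    graph: GeneGraph,
    start_node: str,
    ref_chain: ReferenceChain,
    iterations: int = 500,
    rng: random.Random | None = None,
    *,
    _succ: dict[str, tuple[str, ...]] | None = None,
    _terminate_on: set[str] | None = None,
) -> set[Path]:
    """Sample deviating paths from ``start_node`` by repeated random walks.

    Each of ``iterations`` walks starts at ``start_node`` and ends the first
    time it reaches a reference-chain node.  Returned paths are unique node
    sequences of length ≥ 2 (direct chain steps are included; they carry no
    complexity because no node lies strictly between their endpoints).
    Neighbor choice is uniform over out-edges, ignoring edge weight.
    """
    if start_node not in graph:
        raise KeyError(f"start node {start_node!r} not in graph")
    rng = rng if rng is not None else random.Random(0)
    succ = _succ if _succ is not None else graph.successor_map()
    terminate = _terminate_on if _terminate_on is not None else set(ref_chain.position)
    paths: set[Path] = set()
    for _ in range(iterations):
        path = _walk(succ, start_node, terminate, rng)
        if path is not None and len(path) > 1:
            paths.add(path)
    return paths


def enumerate_paths_exhaustive(
    graph: GeneGraph,
    start_node: str,
    ref_chain: ReferenceChain,
    max_interior: int = 10,
    *,
    _succ: dict[str, tuple[str, ...]] | None = None,
    _terminate_on: set[str] | None = None,
) -> set[Path]:
    """Enumerate every deviating path the random walk could find.

    Depth-first enumeration of all simple paths from ``start_node`` whose
    interior stays off the reference chain and which terminate at the first
    reference node reached, visiting at most ``max_interior`` interior nodes.
    On the same graph this is a superset of (and the sampling limit of) any
    :func:`find_paths` result, which makes it the test oracle for the walker.
    Only tractable on small graphs.
    """
    if start_node not in graph:
        raise KeyError(f"start node {start_node!r} not in graph")
    succ = _succ if _succ is not None else graph.successor_map()
    terminate = _terminate_on if _terminate_on is not None else set(ref_chain.position)
    results: set[Path] = set()
    stack: list[tuple[str, tuple[str, ...], frozenset[str]]] = [
        (start_node, (start_node,), frozenset((start_node,)))
    ]
    while stack:
        current, path, seen = stack.pop()
        for nxt in succ.get(current, ()):
            if nxt in terminate:
                results.add(path + (nxt,))
            elif nxt not in seen and len(path) - 1 < max_interior:
                stack.append((nxt, path + (nxt,), seen | {nxt}))
    return results


# ---------------------------------------------------------------------------
# complexity accumulation
# ---------------------------------------------------------------------------


def compute_complexity(
    graph: GeneGraph,
    ref_chain: ReferenceChain,
    params: ComplexityParams | None = None,
    method: str = "sampled",
    max_interior: int = 25,
    terminate_on: set[str] | None = None,
) -> ComplexityProfile:
    """Accumulate per-node complexity from deviating paths.

    For every reference node, deviating paths are gathered (``method``
    'sampled' uses the random walker, 'exhaustive' the enumeration oracle)
    and deduplicated globally by node sequence, so a path reachable from two
    start nodes counts once.  A unique path whose endpoints lie ≤ ``window``
    chain positions apart adds ``1/window`` to every node strictly between
    them; the endpoints themselves (which the path does not bypass) receive
    nothing.  Paths terminating on a node outside ``ref_chain``'s contig
    (passed via ``terminate_on`` for multi-contig references) are discarded,
    their chain distance being undefined.
    """
    params = params or ComplexityParams()
    if method not in ("sampled", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    n = len(ref_chain)
    if params.window >= n:
        raise ValueError(
            f"window {params.window} >= chain length {n}: profile would be uninformative"
        )
    for node in ref_chain.nodes:
        if node not in graph:
            raise ValueError(f"reference node {node!r} missing from graph")
    succ = graph.successor_map()
    terminate = terminate_on if terminate_on is not None else set(ref_chain.position)
    pos = ref_chain.position
    window = params.window
    increment = 1.0 / window
    values = np.zeros(n, dtype=np.float64)
    rng = random.Random(params.rng_seed)
    seen_paths: set[Path] = set()
    for start in ref_chain.nodes:
        if method == "sampled":
            paths = find_paths(
                graph,
                start,
                ref_chain,
                iterations=params.iterations,
                rng=rng,
                _succ=succ,
                _terminate_on=terminate,
            )
        else:
            paths = enumerate_paths_exhaustive(
                graph,
                start,
                ref_chain,
                max_interior=max_interior,
                _succ=succ,
                _terminate_on=terminate,
            )
        for path in paths:
            if path in seen_paths:
                continue
            seen_paths.add(path)
            a = pos.get(path[0])
            b = pos.get(path[-1])
            if a is None or b is None:
                continue  # endpoint on another contig: distance undefined
            distance = abs(a - b)
            if distance > window:
                continue
            lo, hi = (a, b) if a < b else (b, a)
            if hi - lo > 1:
                values[lo + 1 : hi] += increment
    return ComplexityProfile(chain=ref_chain, values=values, params=params)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HotspotRegion:
    """A maximal run of reference genes whose complexity exceeds the
    Tukey-fence threshold."""

    contig_id: str
    start_bp: int
    end_bp: int
    n_genes: int
    max_complexity: float
    start_index: int
    end_index: int  # inclusive


@dataclass
class HotspotResult:
    threshold: float
    regions: list[HotspotRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def detect_hotspots(profile: ComplexityProfile, k: float = 1.5) -> HotspotResult:
    """Tukey-fence hotspot detection on a complexity profile.

    The threshold is Q3 + k·IQR over all profile values (quartiles by linear
    interpolation); genes with complexity strictly above it are hotspot
    genes, and maximal consecutive runs of them form regions whose base-pair
    bounds span from the first gene's start to the last gene's end.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    values = profile.values
    if len(values) == 0:
        raise ValueError("empty complexity profile")
    q1, q3 = np.percentile(values, [25, 75])
    threshold = float(q3 + k * (q3 - q1))
    above = values > threshold
    chain = profile.chain
    regions: list[HotspotRegion] = []
    i = 0
    n = len(values)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        regions.append(
            HotspotRegion(
                contig_id=chain.contig_id,
                start_bp=int(chain.coords[i]),
                end_bp=int(chain.ends[j]),
                n_genes=j - i + 1,
                max_complexity=float(values[i : j + 1].max()),
                start_index=i,
                end_index=j,
            )
        )
        i = j + 1
    return HotspotResult(threshold=threshold, regions=regions)
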