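"""Greedy dense-module growth and the restricted whole-network search.

A module grows from a seed by repeatedly adding the neighbour (within
shortest-path distance ``d`` of the current members) that maximises the
module score ``Zm = sum(z_i) / sqrt(k)``; a step is accepted only while the
proportional score increase exceeds ``r``. The restricted search seeds
modules in descending node-weight order and removes every recorded module's
members from the background, so recorded modules are pairwise disjoint.

All tie-breaks are lexicographic on gene id; the search is fully
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the greedy growth and restricted search.

    ``denominator='sqrt'`` is the Stouffer combination sum(z)/sqrt(k); the
    ``'k'`` mode (plain mean) is exposed for comparison only. With
    ``anchor='module'`` candidate distance is measured to the nearest
    current member; ``'seed'`` restricts it to the seed node.
    """

    d: int = 2
    r: float = 0.1
    min_size: int = 5
    denominator: str = "sqrt"
    anchor: str = "module"

    def __post_init__(self):
        if self.d < 1:
            raise ValidationError("d must be >= 1")
        if self.r <= 0:
            raise ValidationError("r must be > 0")
        if self.min_size < 1:
            raise ValidationError("min_size must be >= 1")
        if self.denominator not in ("sqrt", "k"):
            raise ValidationError("denominator must be 'sqrt' or 'k'")
        if self.anchor not in ("module", "seed"):
            raise ValidationError("anchor must be 'module' or 'seed'")


@dataclass
class Module:
    """A grown module: seed, member set, score, and the accepted-step trail."""

    seed: str
    members: frozenset
    zm: float
    history: list = field(default_factory=list)  # [(gene added, Zm after)]

    @property
    def k(self) -> int:
        return len(self.members)


def score_module(weights: Sequence[float], denominator: str = "sqrt") -> float:
    """Stouffer module score: sum(z) / sqrt(k) (or /k in comparison mode)."""
    weights = list(weights)
    if not weights:
        raise ValidationError("score_module requires a non-empty weight list")
    if not all(math.isfinite(w) for w in weights):
        raise ValidationError("module weights must be finite")
    k = len(weights)
    denom = math.sqrt(k) if denominator == "sqrt" else float(k)
    return sum(weights) / denom


def candidate_neighbors(net: nx.Graph, members: Iterable, d: int) -> set:
    """Non-member nodes within shortest-path distance d of any member."""
    members = set(members)
    if not members:
        raise ValidationError("members must be non-empty")
    visited = set(members)
    frontier = members
    found = set()
    for _ in range(d):
        nxt = set()
        for node in frontier:
            for nb in net.neighbors(node):
                if nb not in visited:
                    visited.add(nb)
                    nxt.add(nb)
        found |= nxt
        frontier = nxt
        if not frontier:
            break
    return found


def _accepts(zm_new: float, zm: float, r: float) -> bool:
    # Zm_new > Zm + |Zm|*r: equals Zm*(1+r) for Zm > 0 and stays a real
    # hurdle when Zm <= 0 (where a bare ratio test degenerates).
    return zm_new > zm + abs(zm) * r


def grow_module(net: nx.Graph, seed: str, params: SearchParams) -> Module:
    """Grow a single module greedily from ``seed`` under ``params``.

    At each step every candidate neighbour is evaluated; the one maximising
    the score of ``members + {candidate}`` is added (ties -> smallest gene
    id) provided the proportional increase exceeds ``params.r``; otherwise
    growth stops.
    """
    if seed not in net:
        raise ValidationError(f"seed {seed!r} not in network")
    z = {n: net.nodes[n]["z"] for n in net.nodes}
    members = {seed}
    total = z[seed]
    k = 1
    sqrt_mode = params.denominator == "sqrt"
    zm = total / (math.sqrt(k) if sqrt_mode else k)
    history = [(seed, zm)]
    while True:
        if params.anchor == "seed":
            cands = candidate_neighbors(net, {seed}, params.d) - members
        else:
            cands = candidate_neighbors(net, members, params.d)
        if not cands:
            break
        denom = math.sqrt(k + 1) if sqrt_mode else (k + 1)
        best = min(cands, key=lambda c: (-(total + z[c]) / denom, c))
        zm_new = (total + z[best]) / denom
        if not _accepts(zm_new, zm, params.r):
            break
        members.add(best)
        total += z[best]
        k += 1
        zm = zm_new
        history.append((best, zm))
    return Module(seed=seed, members=frozenset(members), zm=zm, history=history)


def restricted_search(net: nx.Graph, params: SearchParams) -> list:
    """Restricted dense-module search over the whole background network.

    Repeatedly seeds at the highest-weight remaining node (ties -> smallest
    id). A grown module of at least ``params.min_size`` nodes is recorded
    and its members removed from the background; a smaller one is discarded
    and only its seed disqualified from future seeding (it stays available
    as a member). The loop ends when no seed-eligible node remains.
    """
    work = net.copy()
    disqualified: set = set()
    modules: list = []
    while True:
        eligible = [n for n in work.nodes if n not in disqualified]
        if not eligible:
            break
        seed = min(eligible, key=lambda n: (-work.nodes[n]["z"], n))
        module = grow_module(work, seed, params)
        if module.k >= params.min_size:
            modules.append(module)
            work.remove_nodes_from(module.members)
        else:
            disqualified.add(seed)
    return modules
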