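"""Streaming evolutionary community discovery over an edge birth/death stream.

The engine maintains overlapping communities with two levels of involvement:

* a **core** member participates in at least one triangle whose three
  vertices are all core members of the same community;
* a **peripheral** member is a one-hop neighbor of a core member that is not
  itself core in that community.

Only core members propagate community membership. When a new edge (u, v)
closes a triangle with a common neighbor z, two cases apply per triangle:
if two of {u, v, z} are already core members of a common community the third
is promoted to core there; if no community holds any two of them as core, a
brand-new community with core {u, v, z} is created. Promotions cascade to a
fixpoint. An edge with no common neighbor only extends peripheries. Edge
deaths demote cores that lose their last all-core triangle, split a
community whose core-induced subgraph disconnects, and dissolve communities
whose core shrinks below three members.

Live communities are recorded at observation-window boundaries; the recorded
member sets, deduplicated, become the candidate binary features fed to
feature selection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .dynamics import InteractionStream

__all__ = [
    "Community",
    "CommunityState",
    "CommunityCatalog",
    "StreamingCommunityEngine",
    "run_stream",
    "collect_candidate_features",
    "build_membership_matrix",
    "write_catalog",
    "write_candidates",
    "read_candidates",
]


@dataclass
class Community:
    """A live overlapping community: disjoint core and peripheral member sets."""

    cid: int
    core: set[str]
    peripheral: set[str] = field(default_factory=set)

    @property
    def members(self) -> set[str]:
        return self.core | self.peripheral


@dataclass(frozen=True)
class CommunityState:
    """A community as observed at one window boundary (immutable record)."""

    window: int
    cid: int
    members: frozenset[str]
    core_members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.core_members <= self.members:
            raise ValueError("core members must be a subset of members")


@dataclass
class CommunityCatalog:
    """Live communities plus the per-window observation history."""

    live: dict[int, Community] = field(default_factory=dict)
    history: list[CommunityState] = field(default_factory=list)
    next_cid: int = 1


class StreamingCommunityEngine:
    """Applies edge birth/death events and keeps community invariants.

    With ``check_invariants=True`` every processed event is followed by an
    exhaustive verification (triangle membership of every core, peripheral
    adjacency, disjointness, minimum core size) — O(n^3) per event, intended
    for tests and debugging.
    """

    def __init__(self, check_invariants: bool = False) -> None:
        self.adj: dict[str, set[str]] = {}
        self.catalog = CommunityCatalog()
        self.node_core: dict[str, set[int]] = {}
        self.check_invariants = check_invariants

    # -- helpers ---------------------------------------------------------

    def _neighbors(self, x: str) -> set[str]:
        return self.adj.get(x, set())

    def _core_cids(self, x: str) -> set[int]:
        return self.node_core.get(x, set())

    def _promote(self, x: str, cid: int, queue: deque[tuple[str, int]]) -> None:
        com = self.catalog.live[cid]
        if x in com.core:
            return
        com.peripheral.discard(x)
        com.core.add(x)
        self.node_core.setdefault(x, set()).add(cid)
        queue.append((x, cid))

    def _new_community(self, core: set[str], queue: deque[tuple[str, int]]) -> int:
        cid = self.catalog.next_cid
        self.catalog.next_cid += 1
        self.catalog.live[cid] = Community(cid=cid, core=set(), peripheral=set())
        for x in sorted(core):
            self._promote(x, cid, queue)
        return cid

    def _cascade(self, queue: deque[tuple[str, int]], affected: set[int]) -> None:
        # a promotion of x in community c can only create new core pairs
        # (x, y) with y core in c, so re-check just x's triangles against c
        while queue:
            x, cid = queue.popleft()
            affected.add(cid)
            com = self.catalog.live.get(cid)
            if com is None or x not in com.core:
                continue
            for y in sorted(self._neighbors(x) & com.core):
                for z in sorted(self._neighbors(x) & self._neighbors(y)):
                    if z not in com.core:
                        self._promote(z, cid, queue)

    def _refresh_peripherals(self, cids: set[int]) -> None:
        for cid in sorted(cids):
            com = self.catalog.live.get(cid)
            if com is None:
                continue
            periph: set[str] = set()
            for x in com.core:
                periph |= self._neighbors(x)
            com.peripheral = periph - com.core

    def _merge_duplicates(self) -> None:
        # communities whose core sets coincide collapse onto the smaller cid
        seen: dict[frozenset[str], int] = {}
        drop: list[int] = []
        for cid in sorted(self.catalog.live):
            key = frozenset(self.catalog.live[cid].core)
            if key in seen:
                drop.append(cid)
            else:
                seen[key] = cid
        for cid in drop:
            self._dissolve(cid)

    def _dissolve(self, cid: int) -> None:
        com = self.catalog.live.pop(cid)
        for x in com.core:
            self.node_core[x].discard(cid)

    # -- event handlers --------------------------------------------------

    def apply_birth(self, u: str, v: str) -> None:
        if v in self._neighbors(u):
            raise ValueError(f"duplicate birth of edge ({u}, {v})")
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

        affected: set[int] = set()
        queue: deque[tuple[str, int]] = deque()
        common = self._neighbors(u) & self._neighbors(v)
        if common:
            for z in sorted(common):
                matched = False
                for a, b, third in ((u, v, z), (u, z, v), (v, z, u)):
                    for cid in sorted(self._core_cids(a) & self._core_cids(b)):
                        matched = True
                        self._promote(third, cid, queue)
                if not matched:
                    self._new_community({u, v, z}, queue)
            self._cascade(queue, affected)
        else:
            # peripheral propagation: endpoints adjacent to a core member
            # join that community's periphery (refresh below realizes it)
            for x in (u, v):
                for y in self._neighbors(x):
                    affected |= self._core_cids(y)
        # membership of the endpoints' communities may gain peripherals
        affected |= self._core_cids(u) | self._core_cids(v)
        self._refresh_peripherals(affected)
        self._merge_duplicates()
        if self.check_invariants:
            self.verify_invariants()

    def apply_death(self, u: str, v: str) -> None:
        if v not in self._neighbors(u):
            raise ValueError(f"death of absent edge ({u}, {v})")
        self.adj[u].discard(v)
        self.adj[v].discard(u)

        affected = set(self._core_cids(u) | self._core_cids(v))
        # communities where an endpoint is peripheral may lose that peripheral
        for cid, com in self.catalog.live.items():
            if u in com.peripheral or v in com.peripheral:
                affected.add(cid)

        new_cids: set[int] = set()
        for cid in sorted(affected):
            com = self.catalog.live.get(cid)
            if com is None:
                continue
            self._demote_fixpoint(com)
            if len(com.core) < 3:
                self._dissolve(cid)
                continue
            new_cids |= self._split_if_disconnected(cid)

        survivors = {cid for cid in affected | new_cids if cid in self.catalog.live}
        self._refresh_peripherals(survivors)
        self._merge_duplicates()
        if self.check_invariants:
            self.verify_invariants()

    def _demote_fixpoint(self, com: Community) -> None:
        changed = True
        while changed:
            changed = False
            for x in sorted(com.core):
                if not self._in_all_core_triangle(x, com.core):
                    com.core.discard(x)
                    self.node_core[x].discard(com.cid)
                    com.peripheral.add(x)
                    changed = True

    def _in_all_core_triangle(self, x: str, core: set[str]) -> bool:
        nbrs = self._neighbors(x) & core
        for y in nbrs:
            if self._neighbors(y) & nbrs:
                return True
        return False

    def _split_if_disconnected(self, cid: int) -> set[int]:
        com = self.catalog.live[cid]
        comps = self._core_components(com.core)
        if len(comps) <= 1:
            return set()
        # the component holding the lexicographically smallest core member
        # keeps the old cid; others get fresh cids in order of smallest member
        comps.sort(key=min)
        keeper, rest = comps[0], comps[1:]
        for x in com.core - keeper:
            self.node_core[x].discard(cid)
        com.core = set(keeper)
        new_cids: set[int] = set()
        for comp in rest:
            # demotion already ran, so every component carries a triangle
            new_cid = self.catalog.next_cid
            self.catalog.next_cid += 1
            self.catalog.live[new_cid] = Community(cid=new_cid, core=set(comp))
            for x in comp:
                self.node_core.setdefault(x, set()).add(new_cid)
            new_cids.add(new_cid)
        return new_cids

    def _core_components(self, core: set[str]) -> list[set[str]]:
        remaining = set(core)
        comps: list[set[str]] = []
        while remaining:
            start = min(remaining)
            comp = {start}
            frontier = [start]
            while frontier:
                x = frontier.pop()
                for y in self._neighbors(x) & remaining - comp:
                    comp.add(y)
                    frontier.append(y)
            comps.append(comp)
            remaining -= comp
        return comps

    # -- observation and verification ------------------------------------

    def observe(self, window: int) -> None:
        for cid in sorted(self.catalog.live):
            com = self.catalog.live[cid]
            self.catalog.history.append(
                CommunityState(
                    window=window,
                    cid=cid,
                    members=frozenset(com.members),
                    core_members=frozenset(com.core),
                )
            )

    def verify_invariants(self) -> None:
        for cid, com in self.catalog.live.items():
            if com.core & com.peripheral:
                raise AssertionError(f"community {cid}: core/peripheral overlap")
            if len(com.core) < 3:
                raise AssertionError(f"community {cid}: core smaller than 3")
            for x in com.core:
                if not self._in_all_core_triangle(x, com.core):
                    raise AssertionError(f"community {cid}: core {x} lacks all-core triangle")
            for x in com.peripheral:
                if not self._neighbors(x) & com.core:
                    raise AssertionError(f"community {cid}: peripheral {x} not adjacent to core")
            for x in com.core:
                if cid not in self.node_core.get(x, set()):
                    raise AssertionError(f"index out of sync for {x} in {cid}")


def run_stream(
    stream: InteractionStream,
    observation_window: int = 1,
    check_invariants: bool = False,
) -> CommunityCatalog:
    """Process a stream and record live communities at window boundaries.

    Events are applied in stored order (deaths before births within a
    timestep). After every ``observation_window`` timesteps — and once after
    the final event if it does not land on a boundary — every live community
    is recorded as a :class:`CommunityState`.
    """
    if observation_window < 1:
        raise ValueError("observation_window must be a positive integer")
    engine = StreamingCommunityEngine(check_invariants=check_invariants)
    by_time: dict[int, list] = {}
    for ev in stream.events:
        by_time.setdefault(ev.time, []).append(ev)
    window = 0
    observed_at_end = False
    for t in range(1, stream.n_timesteps + 1):
        for ev in by_time.get(t, []):
            if ev.kind == "death":
                engine.apply_death(ev.u, ev.v)
            else:
                engine.apply_birth(ev.u, ev.v)
        if t % observation_window == 0:
            window += 1
            engine.observe(window)
            observed_at_end = t == stream.n_timesteps
    if stream.events and not observed_at_end:
        engine.observe(window + 1)
    return engine.catalog


def collect_candidate_features(
    catalog: CommunityCatalog, membership: str = "all"
) -> list[frozenset[str]]:
    """Deduplicated member sets of all observed community states.

    ``membership`` selects whether a candidate is the full member set
    (``"all"``, core plus peripheral) or the core only (``"core"``).
    Ordering is by (first observation window, cid); exact-duplicate member
    sets keep their first occurrence.
    """
    if membership not in ("all", "core"):
        raise ValueError("membership must be 'all' or 'core'")
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for state in sorted(catalog.history, key=lambda s: (s.window, s.cid)):
        members = state.members if membership == "all" else state.core_members
        if members not in seen:
            seen.add(members)
            out.append(members)
    return out


def build_membership_matrix(
    proteins: Sequence[str], candidates: Sequence[frozenset[str]]
) -> np.ndarray:
    """Binary matrix: entry (n, m) = 1 iff protein n belongs to candidate m."""
    mat = np.zeros((len(proteins), len(candidates)), dtype=float)
    for j, cand in enumerate(candidates):
        for i, p in enumerate(proteins):
            if p in cand:
                mat[i, j] = 1.0
    return mat


def write_catalog(catalog: CommunityCatalog, sink: IO[str]) -> None:
    sink.write("window\tcid\trole\tprotein\n")
    for state in sorted(catalog.history, key=lambda s: (s.window, s.cid)):
        for p in sorted(state.core_members):
            sink.write(f"{state.window}\t{state.cid}\tcore\t{p}\n")
        for p in sorted(state.members - state.core_members):
            sink.write(f"{state.window}\t{state.cid}\tperipheral\t{p}\n")


def write_candidates(candidates: Sequence[frozenset[str]], sink: IO[str]) -> None:
    sink.write("feature_index\tprotein\n")
    for j, cand in enumerate(candidates):
        for p in sorted(cand):
            sink.write(f"{j}\t{p}\n")


def read_candidates(source: IO[str]) -> list[frozenset[str]]:
    groups: dict[int, set[str]] = {}
    header = True
    for line in source:
        line = line.rstrip("\n")
        if header:
            header = False
            continue
        if not line:
            continue
        j, p = line.split("\t")
        groups.setdefault(int(j), set()).add(p)
    return [frozenset(groups[j]) for j in sorted(groups)]
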