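"""Dynamic PPI network construction via the 3-sigma activity rule.

A protein's temporal expression series yields a per-protein activity
threshold

    t(p) = mu(p) + 3 * sigma(p) * (1 - F(p)),      F(p) = 1 / (1 + sigma^2(p))

with mu the arithmetic mean and sigma^2 the sample variance (n - 1
denominator). The protein is *active* at time i when its expression level
EV_i(p) >= t(p). A snapshot of the dynamic network at time i keeps exactly
the static edges whose two endpoints are both active at i. Consecutive
snapshots are differenced into an interaction stream of edge birth/death
events (u, v, t) that downstream community discovery consumes.

Constant series have sigma = 0, hence F = 1 and t = mu: such proteins are
active everywhere. Higher fluctuation (larger sigma) pushes the threshold
further above the mean, so only pronounced expression peaks count as active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Literal

import numpy as np

from .io import AlignedDataset, StaticPPINetwork, canonical_edge

__all__ = [
    "ActivityProfile",
    "DynamicNetwork",
    "InteractionEvent",
    "InteractionStream",
    "compute_activity_profile",
    "compute_activity_profiles",
    "build_snapshots",
    "build_snapshots_from",
    "build_stream",
    "replay_stream",
    "stream_stats",
    "cycle_average",
    "write_stream",
    "read_stream",
    "write_snapshots",
]

Kind = Literal["birth", "death"]
# within one timestep deaths are replayed before births, so an edge that
# vanishes and reappears never duplicates during replay
_KIND_ORDER = {"death": 0, "birth": 1}


@dataclass(frozen=True)
class ActivityProfile:
    """Per-protein activity statistics and the resulting active flags."""

    protein: str
    mu: float
    var: float
    fluct: float
    threshold: float
    active: np.ndarray  # bool vector over timepoints


@dataclass(frozen=True)
class DynamicNetwork:
    """Ordered edge-set snapshots E_1..E_T over a static node set."""

    static: StaticPPINetwork
    snapshots: tuple[frozenset[tuple[str, str]], ...]

    def __post_init__(self) -> None:
        if len(self.snapshots) < 2:
            raise ValueError("a dynamic network needs at least 2 snapshots")
        for t, snap in enumerate(self.snapshots, start=1):
            if not snap <= self.static.edges:
                raise ValueError(f"snapshot {t} contains edges outside the static network")

    @property
    def n_timesteps(self) -> int:
        return len(self.snapshots)


@dataclass(frozen=True, order=True)
class InteractionEvent:
    """One edge birth or death at an integer timestep (pair held sorted)."""

    time: int
    kind_order: int
    u: str
    v: str

    @property
    def kind(self) -> Kind:
        return "death" if self.kind_order == 0 else "birth"

    @staticmethod
    def make(time: int, kind: Kind, u: str, v: str) -> "InteractionEvent":
        if u == v:
            raise ValueError("self-loop event")
        a, b = canonical_edge(u, v)
        return InteractionEvent(time=time, kind_order=_KIND_ORDER[kind], u=a, v=b)


@dataclass(frozen=True)
class InteractionStream:
    """Time-ordered edge birth/death events; replay reproduces the snapshots."""

    events: tuple[InteractionEvent, ...]
    n_timesteps: int

    def __post_init__(self) -> None:
        if list(self.events) != sorted(self.events):
            raise ValueError("events are not in canonical order")


def compute_activity_profile(series: np.ndarray | Iterable[float], protein: str = "") -> ActivityProfile:
    """3-sigma statistics of one expression series (length >= 2).

    Returns mu, the sample variance, the fluctuation F = 1/(1+var) and the
    activity threshold t = mu + 3*sigma*(1-F), plus per-time active flags
    (EV_i >= t).
    """
    x = np.asarray(list(series) if not isinstance(series, np.ndarray) else series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression series must be 1-D with at least 2 timepoints")
    if not np.isfinite(x).all():
        raise ValueError("expression series contains non-finite values")
    mu = float(x.sum() / x.size)
    var = float(((x - mu) ** 2).sum() / (x.size - 1))
    var = max(var, 0.0)
    fluct = 1.0 / (1.0 + var)
    threshold = mu + 3.0 * np.sqrt(var) * (1.0 - fluct)
    return ActivityProfile(
        protein=protein,
        mu=mu,
        var=var,
        fluct=fluct,
        threshold=threshold,
        active=x >= threshold,
    )


def compute_activity_profiles(dataset: AlignedDataset) -> dict[str, ActivityProfile]:
    """Activity profile for every protein with an expression row."""
    expr = dataset.expression
    return {
        p: compute_activity_profile(expr.values[i], protein=p)
        for i, p in enumerate(expr.proteins)
    }


def build_snapshots_from(
    network: StaticPPINetwork,
    expression,
    profiles: dict[str, ActivityProfile] | None = None,
    first_snapshot_static: bool = True,
) -> DynamicNetwork:
    """Per-timepoint subnetworks of edges whose endpoints are both active.

    Proteins without an expression row are treated as always active. With
    ``first_snapshot_static`` (the default) the first snapshot is the full
    static edge set, so the stream opens by generating every static edge.
    """
    T = expression.n_timepoints
    if T < 2:
        raise ValueError("need at least 2 expression timepoints")
    if profiles is None:
        profiles = {
            p: compute_activity_profile(expression.values[i], protein=p)
            for i, p in enumerate(expression.proteins)
        }

    def active_at(p: str, t: int) -> bool:
        prof = profiles.get(p)
        return True if prof is None else bool(prof.active[t])

    snaps: list[frozenset[tuple[str, str]]] = []
    for t in range(T):
        if t == 0 and first_snapshot_static:
            snaps.append(network.edges)
            continue
        snaps.append(
            frozenset(e for e in network.edges if active_at(e[0], t) and active_at(e[1], t))
        )
    return DynamicNetwork(static=network, snapshots=tuple(snaps))


def build_snapshots(
    dataset: AlignedDataset,
    profiles: dict[str, ActivityProfile] | None = None,
    first_snapshot_static: bool = True,
) -> DynamicNetwork:
    """:func:`build_snapshots_from` applied to an aligned dataset."""
    return build_snapshots_from(dataset.network, dataset.expression, profiles, first_snapshot_static)


def build_stream(dyn: DynamicNetwork) -> InteractionStream:
    """Difference consecutive snapshots into birth/death events.

    Time 1 emits a birth for every edge of E_1; for t >= 2 the births are
    E_t \\ E_{t-1} and the deaths E_{t-1} \\ E_t.
    """
    events: list[InteractionEvent] = []
    prev: frozenset[tuple[str, str]] = frozenset()
    for t, snap in enumerate(dyn.snapshots, start=1):
        for u, v in snap - prev:
            events.append(InteractionEvent.make(t, "birth", u, v))
        for u, v in prev - snap:
            events.append(InteractionEvent.make(t, "death", u, v))
        prev = snap
    events.sort()
    return InteractionStream(events=tuple(events), n_timesteps=dyn.n_timesteps)


def replay_stream(stream: InteractionStream) -> list[frozenset[tuple[str, str]]]:
    """Reconstruct the snapshot edge sets by applying the events in order."""
    current: set[tuple[str, str]] = set()
    snaps: list[frozenset[tuple[str, str]]] = []
    by_time: dict[int, list[InteractionEvent]] = {}
    for ev in stream.events:
        by_time.setdefault(ev.time, []).append(ev)
    for t in range(1, stream.n_timesteps + 1):
        for ev in by_time.get(t, []):
            e = (ev.u, ev.v)
            if ev.kind == "death":
                if e not in current:
                    raise ValueError(f"death of absent edge {e} at time {t}")
                current.remove(e)
            else:
                if e in current:
                    raise ValueError(f"birth of present edge {e} at time {t}")
                current.add(e)
        snaps.append(frozenset(current))
    return snaps


def stream_stats(dyn: DynamicNetwork, stream: InteractionStream) -> list[dict[str, int]]:
    """Per-time table of EdgeNum, NodeNum (non-isolated), NewEdge, VanishEdge."""
    births: dict[int, int] = {}
    deaths: dict[int, int] = {}
    for ev in stream.events:
        d = births if ev.kind == "birth" else deaths
        d[ev.time] = d.get(ev.time, 0) + 1
    rows = []
    for t, snap in enumerate(dyn.snapshots, start=1):
        nodes = {x for e in snap for x in e}
        rows.append(
            {
                "time": t,
                "EdgeNum": len(snap),
                "NodeNum": len(nodes),
                "NewEdge": births.get(t, 0),
                "VanishEdge": deaths.get(t, 0),
            }
        )
    return rows


def cycle_average(values: np.ndarray, period: int) -> np.ndarray:
    """Average an expression matrix across repeated cycles of ``period`` points.

    Off by default in the pipeline; useful when a time course covers several
    identical experimental cycles and one representative cycle is wanted.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if period < 2 or n % period != 0:
        raise ValueError("period must be >= 2 and divide the number of timepoints")
    k = n // period
    return values.reshape(values.shape[0], k, period).mean(axis=1)


def write_stream(stream: InteractionStream, sink: IO[str]) -> None:
    sink.write(f"# timesteps={stream.n_timesteps}\n")
    for ev in stream.events:
        sink.write(f"{ev.time}\t{ev.kind}\t{ev.u}\t{ev.v}\n")


def read_stream(source: IO[str]) -> InteractionStream:
    events: list[InteractionEvent] = []
    n_timesteps = 0
    for line in source:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            if "timesteps=" in line:
                n_timesteps = int(line.split("timesteps=")[1])
            continue
        t, kind, u, v = line.split("\t")
        events.append(InteractionEvent.make(int(t), kind, u, v))  # type: ignore[arg-type]
    events.sort()
    n_timesteps = max(n_timesteps, max((e.time for e in events), default=0))
    return InteractionStream(events=tuple(events), n_timesteps=n_timesteps)


def write_snapshots(dyn: DynamicNetwork, sink: IO[str]) -> None:
    for t, snap in enumerate(dyn.snapshots, start=1):
        for u, v in sorted(snap):
            sink.write(f"{t}\t{u}\t{v}\n")
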