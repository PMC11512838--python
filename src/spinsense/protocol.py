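"""Event-driven simulation of a centrifugal disc's fluidic network.

A disc is a set of chambers connected by two kinds of passive valves
whose state depends only on rotational speed:

* a **capillary valve** pins the liquid meniscus at a sudden channel
  expansion and bursts — permanently — the first time the speed reaches
  its burst RPM, releasing the entire source chamber downstream;
* a **siphon valve** must first *prime* (liquid creeping over the siphon
  crest by capillarity, which happens near rest, or hydrostatically when
  the source fills above the crest volume) and then empties its source
  once the disc spins at or above its transfer speed.

Replaying a piecewise-constant RPM schedule against a disc emits a
chronological list of liquid-transfer events. Transfers are modelled as
atomic at the triggering instant — the description of the platform gives
burst thresholds and step order, not flow rates — and cascade within a
single instant through already-open paths in source-before-target order.

:func:`default_elisa_disc` ships the sandwich-ELISA disc: sample in the
detection chamber, two wash chambers (burst 700 and 900 RPM), a TMB
substrate chamber (burst 1400 RPM) and a detection→waste siphon that
primes at rest and transfers at 300 RPM.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import ChamberOverflowError, InvalidArgument
from .synth import RotationProfile

__all__ = [
    "Chamber",
    "CapillaryValve",
    "SiphonValve",
    "DiscConfig",
    "TransferEvent",
    "ProtocolReport",
    "default_elisa_disc",
    "canonical_elisa_schedule",
    "simulate_protocol",
    "verify_elisa_sequence",
]


@dataclass
class Chamber:
    id: str
    capacity: float = float("inf")  # µL
    contents: list[tuple[str, float]] = field(default_factory=list)

    def volume(self) -> float:
        return sum(v for _, v in self.contents)

    def validate(self) -> None:
        if any(v < 0 for _, v in self.contents):
            raise InvalidArgument(f"chamber {self.id!r} holds a negative volume")
        if self.volume() > self.capacity + 1e-9:
            raise InvalidArgument(
                f"chamber {self.id!r} loaded beyond its capacity"
            )


@dataclass
class CapillaryValve:
    id: str
    source: str
    target: str
    burst_rpm: float
    state: str = "closed"  # once "open", never closes

    def validate(self) -> None:
        if self.burst_rpm <= 0:
            raise InvalidArgument(f"valve {self.id!r}: burst_rpm must be positive")
        if self.state not in ("closed", "open"):
            raise InvalidArgument(f"valve {self.id!r}: bad state {self.state!r}")


@dataclass
class SiphonValve:
    """Siphon with a prime/transfer cycle.

    Primes when the source is nonempty and the disc is at or below
    ``prime_rpm_max`` (capillary creep near rest), or — when
    ``prime_volume_ul`` is set — whenever the source volume reaches that
    crest volume, which is how wash buffer poured into an empty chamber
    at full speed still finds its way over the crest. Once primed, it
    empties the source the moment the speed is at or above
    ``transfer_rpm_min``, then unprimes.
    """

    id: str
    source: str
    target: str
    prime_rpm_max: float = 100.0
    transfer_rpm_min: float = 300.0
    prime_volume_ul: float | None = None
    primed: bool = False

    def validate(self) -> None:
        if not self.prime_rpm_max < self.transfer_rpm_min:
            raise InvalidArgument(
                f"siphon {self.id!r}: prime_rpm_max must be below transfer_rpm_min"
            )


@dataclass
class DiscConfig:
    chambers: list[Chamber]
    capillary_valves: list[CapillaryValve] = field(default_factory=list)
    siphon_valves: list[SiphonValve] = field(default_factory=list)

    def chamber(self, cid: str) -> Chamber:
        for c in self.chambers:
            if c.id == cid:
                return c
        raise InvalidArgument(f"unknown chamber {cid!r}")

    def validate(self) -> None:
        ids = [c.id for c in self.chambers]
        if len(set(ids)) != len(ids):
            raise InvalidArgument("duplicate chamber ids")
        for c in self.chambers:
            c.validate()
        edges = []
        for v in [*self.capillary_valves, *self.siphon_valves]:
            v.validate()
            for end in (v.source, v.target):
                if end not in ids:
                    raise InvalidArgument(
                        f"valve {v.id!r} references unknown chamber {end!r}"
                    )
            edges.append((v.source, v.target))
        self._check_acyclic(edges)

    @staticmethod
    def _check_acyclic(edges: list[tuple[str, str]]) -> None:
        adj: dict[str, list[str]] = {}
        for a, b in edges:
            adj.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in adj.get(node, []):
                if state.get(nxt) == 1:
                    raise InvalidArgument("transfer paths contain a cycle")
                if state.get(nxt, 0) == 0:
                    visit(nxt)
            state[node] = 2

        for node in list(adj):
            if state.get(node, 0) == 0:
                visit(node)

    def total_volume(self) -> float:
        return sum(c.volume() for c in self.chambers)


@dataclass(frozen=True)
class TransferEvent:
    time: float  # s
    rpm: float
    liquid_id: str
    source: str
    target: str
    volume: float  # µL
    valve_id: str


def default_elisa_disc() -> DiscConfig:
    """The built-in sandwich-ELISA disc.

    Detection chamber preloaded with 100 µL sample (+ detector
    antibody), two 100 µL wash chambers with capillary valves bursting
    at 700 and 900 RPM, a 70 µL TMB substrate chamber bursting at
    1400 RPM, and a detection→waste siphon (primes at rest or when the
    detection chamber fills past 80 µL; transfers at ≥ 300 RPM). Inlet
    capacities are 1.1x their load so overflow checking is meaningful;
    waste is unbounded.
    """
    disc = DiscConfig(
        chambers=[
            Chamber("detection", capacity=150.0, contents=[("sample", 100.0)]),
            Chamber("wash1", capacity=110.0, contents=[("wash1", 100.0)]),
            Chamber("wash2", capacity=110.0, contents=[("wash2", 100.0)]),
            Chamber("tmb", capacity=77.0, contents=[("TMB", 70.0)]),
            Chamber("waste"),
        ],
        capillary_valves=[
            CapillaryValve("cv_wash1", "wash1", "detection", burst_rpm=700.0),
            CapillaryValve("cv_wash2", "wash2", "detection", burst_rpm=900.0),
            CapillaryValve("cv_tmb", "tmb", "detection", burst_rpm=1400.0),
        ],
        siphon_valves=[
            SiphonValve(
                "siphon_waste",
                "detection",
                "waste",
                prime_rpm_max=100.0,
                transfer_rpm_min=300.0,
                prime_volume_ul=80.0,
            )
        ],
    )
    disc.validate()
    return disc


def canonical_elisa_schedule(step: float = 10.0) -> RotationProfile:
    """The speed sequence that drives the full assay: rest → 300 (sample
    out) → rest → 700 (wash 1) → 900 (wash 2) → rest → 1400 (TMB in)."""
    speeds = [0.0, 300.0, 0.0, 700.0, 900.0, 0.0, 1400.0]
    return RotationProfile([(i * step, r) for i, r in enumerate(speeds)])


def _transfer(
    disc: DiscConfig,
    source: Chamber,
    target: Chamber,
    valve_id: str,
    time: float,
    rpm: float,
    events: list[TransferEvent],
) -> None:
    moved = source.contents
    total = sum(v for _, v in moved)
    if total <= 0:
        return
    if target.volume() + total > target.capacity + 1e-9:
        raise ChamberOverflowError(target.id, target.volume() + total, target.capacity)
    for liquid, vol in moved:
        if vol > 0:
            events.append(
                TransferEvent(time, rpm, liquid, source.id, target.id, vol, valve_id)
            )
            target.contents.append((liquid, vol))
    source.contents = []


def simulate_protocol(
    disc: DiscConfig, profile: RotationProfile
) -> list[TransferEvent]:
    """Replay an RPM schedule against a disc and emit transfer events.

    Segments are processed in time order. Within one instant, capillary
    valves at or above their burst RPM fire in ascending burst order,
    then siphons; transfers cascade through already-open paths until the
    state is stable, so liquid poured into a chamber whose outlet is
    open moves on at the same timestamp. Total liquid volume is
    conserved; a transfer that would exceed a chamber's capacity raises
    :class:`ChamberOverflowError` naming the chamber. The input disc is
    not mutated.
    """
    disc = copy.deepcopy(disc)
    disc.validate()
    events: list[TransferEvent] = []

    for t, rpm in profile.segments:
        # cascade until no valve can fire at this instant
        for _ in range(10 * (len(disc.capillary_valves) + len(disc.siphon_valves)) + 10):
            fired = False
            for cv in sorted(disc.capillary_valves, key=lambda v: v.burst_rpm):
                if cv.state == "closed" and rpm >= cv.burst_rpm:
                    cv.state = "open"
                    src = disc.chamber(cv.source)
                    if src.volume() > 0:
                        _transfer(disc, src, disc.chamber(cv.target), cv.id, t, rpm, events)
                        fired = True
                elif cv.state == "open":
                    src = disc.chamber(cv.source)
                    if rpm >= cv.burst_rpm and src.volume() > 0:
                        _transfer(disc, src, disc.chamber(cv.target), cv.id, t, rpm, events)
                        fired = True
            for sv in disc.siphon_valves:
                src = disc.chamber(sv.source)
                if not sv.primed and src.volume() > 0:
                    if rpm <= sv.prime_rpm_max or (
                        sv.prime_volume_ul is not None
                        and src.volume() >= sv.prime_volume_ul - 1e-9
                    ):
                        sv.primed = True
                if sv.primed and rpm >= sv.transfer_rpm_min and src.volume() > 0:
                    _transfer(disc, src, disc.chamber(sv.target), sv.id, t, rpm, events)
                    sv.primed = False
                    fired = True
            if not fired:
                break
    return events


@dataclass(frozen=True)
class ProtocolReport:
    passed: bool
    checks: dict[str, bool]
    failures: tuple[str, ...]


def verify_elisa_sequence(events: list[TransferEvent]) -> ProtocolReport:
    """Check a transfer-event list against the assay's step order.

    Flags: the sample is evacuated to waste before any wash reaches the
    detection chamber; wash 1 arrives before wash 2; TMB is the last
    liquid delivered to detection and is never flushed out; and volume
    is conserved along every liquid's path (what leaves a chamber never
    exceeds what arrived there).
    """
    checks: dict[str, bool] = {}
    failures: list[str] = []

    def arrival(liquid: str) -> int | None:
        for i, e in enumerate(events):
            if e.liquid_id == liquid and e.target == "detection":
                return i
        return None

    sample_out = next(
        (i for i, e in enumerate(events) if e.liquid_id == "sample" and e.target == "waste"),
        None,
    )
    checks["sample_evacuated"] = sample_out is not None
    if sample_out is None:
        failures.append("no sample evacuation")

    wash_arrivals = [i for i in (arrival("wash1"), arrival("wash2")) if i is not None]
    checks["sample_before_washes"] = sample_out is not None and all(
        sample_out < i for i in wash_arrivals
    )
    if not checks["sample_before_washes"]:
        failures.append("sample not evacuated before washing")

    a1, a2 = arrival("wash1"), arrival("wash2")
    checks["wash_order"] = a1 is not None and a2 is not None and a1 < a2
    if not checks["wash_order"]:
        failures.append("wash1 does not precede wash2")

    tmb_in = arrival("TMB")
    tmb_flushed = any(e.liquid_id == "TMB" and e.source == "detection" for e in events)
    arrivals = [i for i, e in enumerate(events) if e.target == "detection"]
    checks["tmb_last_and_retained"] = (
        tmb_in is not None and tmb_in == max(arrivals, default=-1) and not tmb_flushed
    )
    if not checks["tmb_last_and_retained"]:
        failures.append("TMB not delivered last or was flushed")

    # conservation: per liquid and chamber, outflow never exceeds inflow
    # plus whatever the chamber could have held initially (its first
    # outflow); subsequent outflows must be backed by recorded inflows.
    conserved = True
    liquids = {e.liquid_id for e in events}
    for liquid in liquids:
        flows: dict[str, float] = {}
        for e in events:
            if e.liquid_id != liquid:
                continue
            flows.setdefault(e.source, 0.0)
            flows.setdefault(e.target, 0.0)
            if flows[e.source] + 1e-9 < e.volume and flows[e.source] > 0:
                conserved = False
            flows[e.source] -= e.volume
            flows[e.target] += e.volume
        # a liquid may originate in exactly one chamber (negative net)
        origins = [c for c, v in flows.items() if v < -1e-9]
        if len(origins) > 1:
            conserved = False
    checks["volume_conserved"] = conserved
    if not conserved:
        failures.append("volume not conserved along a liquid path")

    return ProtocolReport(
        passed=not failures, checks=checks, failures=tuple(failures)
    )
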