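"""Exact stochastic simulation of single-plasmin fibrin fiber lysis.

One plasmin molecule lands on the perimeter of a protofibril lattice
(:mod:`fiberlysis.geometry`) and exposes, degrades, and crawls across binding
doublets until it unbinds (free plasmin is assumed to be instantly inhibited
by alpha2-antiplasmin, so the run ends), every doublet is degraded, or —
when ``stop_at_cleavage`` — the configured cleavage fraction is reached and
the fiber is assumed to snap under tension.

Each protofibril carries 6 binding doublets; one starts exposed and five
start cryptic. Doublet states: cryptic N, exposed N00/N03 (nothing/plasmin
bound), degraded phi00/phi03. The 11 reactions and their propensities are
documented in :mod:`fiberlysis._kernel`, which holds the compiled Gillespie
loop that :func:`simulate_run` executes. The functions here
(:func:`init_state`, :func:`local_propensities`, :func:`apply_reaction`)
are the readable, step-at-a-time form of the same model; they consume random
numbers in exactly the same pattern as the kernel, so a trajectory stepped in
Python from a given seed is bitwise-identical to the kernel's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .geometry import CrossSection, FiberSpec

__all__ = [
    "ABSENT",
    "BASELINE_RATES",
    "RateSet",
    "SimConfig",
    "ProtofibrilState",
    "FiberState",
    "RunResult",
    "RunawayError",
    "DOUBLETS_PER_PROTOFIBRIL",
    "fraction_threshold_counts",
    "threshold_count",
    "init_state",
    "local_propensities",
    "apply_reaction",
    "simulate_run",
]

#: Plasmin-location sentinel once the molecule has unbound.
ABSENT = -1

#: Binding doublets per protofibril cross-section (the 6 chain pairs).
DOUBLETS_PER_PROTOFIBRIL = 6

#: First-crossing fractions recorded by every run: 0.01, 0.02, ..., 1.00.
FRACTION_GRID = np.round(np.arange(1, _kernel.N_FRACTIONS + 1) / 100.0, 2)


class RunawayError(RuntimeError):
    """A trajectory exceeded the ``max_events`` safety cap."""


@dataclass(frozen=True)
class RateSet:
    """The four kinetic rate constants, all in 1/s.

    ``k_unbind`` — plasmin unbinding from fibrin; ``k_crawl`` — plasmin
    crawling between doublets/protofibrils; ``k_deg`` — degradation of a
    doublet by plasmin; ``k_exp`` — plasmin-mediated exposure of a cryptic
    doublet. Defaults are the baseline literature estimates.
    """

    k_unbind: float = 0.05
    k_crawl: float = 57.6
    k_deg: float = 5.0
    k_exp: float = 5.0

    def __post_init__(self) -> None:
        for name in ("k_unbind", "k_crawl", "k_deg", "k_exp"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


BASELINE_RATES = RateSet()


@dataclass(frozen=True)
class SimConfig:
    """Per-run simulation options.

    ``cleavage_fraction`` is the fraction of doublets that must be degraded
    for the fiber to snap (default 2/3). ``stop_at_cleavage`` ends the run at
    that point; disable it to follow degradation until plasmin unbinds or the
    cross-section is fully degraded (fraction-sweep analyses).
    """

    cleavage_fraction: float = 2.0 / 3.0
    record_fractions: bool = True
    record_events: bool = False
    stop_at_cleavage: bool = True
    max_events: int = 20_000_000

    def __post_init__(self) -> None:
        if not 0 < self.cleavage_fraction <= 1:
            raise ValueError(
                f"cleavage_fraction must be in (0, 1], got {self.cleavage_fraction}"
            )
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")


@dataclass(frozen=True)
class ProtofibrilState:
    """Doublet-state counts at one protofibril: always summing to 6."""

    N00: int
    N03: int
    phi00: int
    phi03: int
    N_cryptic: int

    def __post_init__(self) -> None:
        counts = (self.N00, self.N03, self.phi00, self.phi03, self.N_cryptic)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative doublet count: {counts}")
        if sum(counts) != DOUBLETS_PER_PROTOFIBRIL:
            raise ValueError(f"doublet counts must sum to 6: {counts}")
        if self.N03 + self.phi03 > 1:
            raise ValueError("at most one plasmin-bound doublet per fiber")

    @property
    def degraded(self) -> int:
        return self.phi00 + self.phi03


@dataclass
class FiberState:
    """Mutable SSA state of one fiber cross-section.

    Unbound doublet counts are stored per protofibril; the single bound
    doublet is implied by ``plasmin_location`` / ``plasmin_on_degraded``.
    """

    cross_section: CrossSection
    n00: np.ndarray  # exposed, unbound
    phi00: np.ndarray  # degraded, unbound
    cryptic: np.ndarray
    plasmin_location: int = ABSENT
    plasmin_on_degraded: bool = False
    time_s: float = 0.0
    degraded_count: int = field(default=0)
    first_degradation: int = ABSENT

    def protofibril(self, i: int) -> ProtofibrilState:
        here = i == self.plasmin_location
        on_phi = here and self.plasmin_on_degraded
        on_n = here and not self.plasmin_on_degraded
        return ProtofibrilState(
            N00=int(self.n00[i]),
            N03=int(on_n),
            phi00=int(self.phi00[i]),
            phi03=int(on_phi),
            N_cryptic=int(self.cryptic[i]),
        )

    @property
    def total_doublets(self) -> int:
        return DOUBLETS_PER_PROTOFIBRIL * self.cross_section.n_protofibrils

    def degraded_map(self) -> np.ndarray:
        m = self.phi00.copy()
        if self.plasmin_location != ABSENT and self.plasmin_on_degraded:
            m[self.plasmin_location] += 1
        return m

    def check_invariants(self) -> None:
        bound = 1 if self.plasmin_location != ABSENT else 0
        tot = int(self.n00.sum() + self.phi00.sum() + self.cryptic.sum()) + bound
        if tot != self.total_doublets:
            raise AssertionError("doublet count not conserved")
        if np.any(self.n00 < 0) or np.any(self.phi00 < 0) or np.any(self.cryptic < 0):
            raise AssertionError("negative doublet count")


@dataclass(frozen=True)
class RunResult:
    """Outcome of one SSA trajectory."""

    success: bool
    cleavage_time_s: Optional[float]
    fraction_times_s: dict  # fraction (0.01..1.00) -> first-crossing time or None
    final_map: np.ndarray  # degraded doublets per protofibril, 0..6
    initial_plasmin: int
    first_degradation: Optional[int]
    n_events: int
    end_time_s: float
    max_fraction_reached: float
    status: int
    side: int
    event_log: Optional[list] = None  # [(time_s, reaction id 1..11, protofibril)]
    seed: Optional[int] = None

    @property
    def event_arrays(self):
        if self.event_log is None:
            return None
        t = np.array([e[0] for e in self.event_log])
        r = np.array([e[1] for e in self.event_log], dtype=np.int8)
        p = np.array([e[2] for e in self.event_log], dtype=np.int64)
        return t, r, p


def threshold_count(fraction: float, total: int) -> int:
    """Smallest degraded-doublet count that reaches ``fraction`` of ``total``.

    Ties at exact equality count as reached; a small epsilon guards against
    float products like (2/3)*294 landing a hair above the integer 196.
    """
    return int(math.ceil(fraction * total - 1e-9))


def fraction_threshold_counts(total: int) -> np.ndarray:
    """Degraded-count thresholds for the 1%-step fraction grid."""
    return np.array(
        [threshold_count(f, total) for f in FRACTION_GRID], dtype=np.int64
    )


# ---------------------------------------------------------------------------
# Step-at-a-time reference implementation
# ---------------------------------------------------------------------------


def _uniform(rng) -> float:
    # RandomState exposes random_sample (the draw the compiled kernel's
    # MT19937 stream makes); Generator exposes random.
    if hasattr(rng, "random_sample"):
        return float(rng.random_sample())
    return float(rng.random())


def init_state(cs: CrossSection, rng) -> FiberState:
    """Fresh cross-section with plasmin on a uniformly chosen edge protofibril.

    Every protofibril starts with 1 exposed and 5 cryptic doublets; the
    plasmin binds the exposed doublet of its protofibril.
    """
    n = cs.n_protofibrils
    state = FiberState(
        cross_section=cs,
        n00=np.ones(n, dtype=np.int64),
        phi00=np.zeros(n, dtype=np.int64),
        cryptic=np.full(n, 5, dtype=np.int64),
    )
    loc = int(cs.edge_indices[int(_uniform(rng) * len(cs.edge_indices))])
    state.plasmin_location = loc
    state.plasmin_on_degraded = False
    state.n00[loc] -= 1
    return state


def local_propensities(state: FiberState, rates: RateSet) -> np.ndarray:
    """The 11 reaction propensities (1/s) at the plasmin's protofibril.

    All reactions require plasmin; with plasmin absent the vector is zero.
    R10/R11 additionally require the protofibril to have a neighbor.
    """
    a = np.zeros(11)
    loc = state.plasmin_location
    if loc == ABSENT:
        return a
    x1 = int(state.n00[loc])
    x3 = int(state.phi00[loc])
    x5 = int(state.cryptic[loc])
    x2 = 0 if state.plasmin_on_degraded else 1
    x4 = 1 - x2
    if x1 < 0 or x3 < 0 or x5 < 0 or x1 + x2 + x3 + x4 + x5 != DOUBLETS_PER_PROTOFIBRIL:
        raise AssertionError("inconsistent protofibril state")
    k = rates
    nn = state.cross_section.degree(loc)
    a[0] = k.k_unbind * x2
    a[1] = k.k_deg * x1
    a[2] = k.k_deg * x2
    a[3] = k.k_unbind * x4
    a[4] = k.k_exp * x5
    a[5] = k.k_crawl * x2 * x3
    a[6] = k.k_crawl * x1 * x4
    a[7] = k.k_crawl * x2 * x1
    a[8] = k.k_crawl * x4 * x3
    a[9] = k.k_crawl * x2 if nn > 0 else 0.0
    a[10] = k.k_crawl * x4 if nn > 0 else 0.0
    return a


def apply_reaction(state: FiberState, reaction: int, rng=None) -> FiberState:
    """Apply reaction ``reaction`` (1..11) in place and return the state.

    ``rng`` is required for R10/R11, which draw the destination protofibril
    (uniform over direct neighbors) and then the doublet bound there (uniform
    over that neighbor's non-cryptic doublets). Raises ``ValueError`` when
    the reaction has zero propensity in the current state.
    """
    if not 1 <= reaction <= 11:
        raise ValueError(f"reaction id must be 1..11, got {reaction}")
    loc = state.plasmin_location
    if loc == ABSENT:
        raise ValueError("no plasmin present; no reaction can fire")
    on_phi = state.plasmin_on_degraded
    x1 = int(state.n00[loc])
    x3 = int(state.phi00[loc])
    x5 = int(state.cryptic[loc])
    x2 = 0 if on_phi else 1
    x4 = 1 - x2

    def _require(ok: bool) -> None:
        if not ok:
            raise ValueError(f"reaction R{reaction} has zero propensity here")

    if reaction == 1:
        _require(x2 == 1)
        state.n00[loc] += 1
        state.plasmin_location = ABSENT
    elif reaction == 2:
        _require(x1 > 0)
        state.n00[loc] -= 1
        state.phi00[loc] += 1
        state.degraded_count += 1
        if state.first_degradation == ABSENT:
            state.first_degradation = loc
    elif reaction == 3:
        _require(x2 == 1)
        state.plasmin_on_degraded = True
        state.degraded_count += 1
        if state.first_degradation == ABSENT:
            state.first_degradation = loc
    elif reaction == 4:
        _require(x4 == 1)
        state.phi00[loc] += 1
        state.plasmin_location = ABSENT
    elif reaction == 5:
        _require(x5 > 0)
        state.cryptic[loc] -= 1
        state.n00[loc] += 1
    elif reaction == 6:
        _require(x2 == 1 and x3 > 0)
        state.n00[loc] += 1
        state.phi00[loc] -= 1
        state.plasmin_on_degraded = True
    elif reaction == 7:
        _require(x4 == 1 and x1 > 0)
        state.phi00[loc] += 1
        state.n00[loc] -= 1
        state.plasmin_on_degraded = False
    elif reaction == 8:
        _require(x2 == 1 and x1 > 0)
    elif reaction == 9:
        _require(x4 == 1 and x3 > 0)
    else:  # R10 / R11
        cs = state.cross_section
        nn = cs.degree(loc)
        _require(nn > 0 and (x2 == 1 if reaction == 10 else x4 == 1))
        if rng is None:
            raise ValueError("R10/R11 need an rng for destination choice")
        if reaction == 10:
            state.n00[loc] += 1
        else:
            state.phi00[loc] += 1
        off = cs.neighbor_offsets[loc]
        dest = int(cs.neighbors_flat[off + int(_uniform(rng) * nn)])
        m = int(state.n00[dest] + state.phi00[dest])
        j = int(_uniform(rng) * m)
        if j < state.n00[dest]:
            state.n00[dest] -= 1
            state.plasmin_on_degraded = False
        else:
            state.phi00[dest] -= 1
            state.plasmin_on_degraded = True
        state.plasmin_location = dest
    return state


def step(state: FiberState, rates: RateSet, rng) -> Optional[int]:
    """Advance one Gillespie event in place; return the reaction id fired.

    Returns None (leaving the state untouched) when the total propensity is
    zero. Draw order matches the compiled kernel: waiting-time uniform,
    reaction uniform, then any destination draws.
    """
    a = local_propensities(state, rates)
    # Sequential accumulation, matching the kernel's summation order exactly.
    a0 = 0.0
    for ai in a:
        a0 += float(ai)
    if a0 <= 0.0:
        return None
    u = _uniform(rng)
    state.time_s += -math.log(1.0 - u) / a0
    v = _uniform(rng) * a0
    acc = 0.0
    rid = 11
    for i in range(11):
        acc += a[i]
        if v < acc:
            rid = i + 1
            break
    apply_reaction(state, rid, rng)
    return rid


# ---------------------------------------------------------------------------
# Full-trajectory simulation (compiled kernel)
# ---------------------------------------------------------------------------


def _kernel_args(cs: CrossSection, rates: RateSet, config: SimConfig):
    total = DOUBLETS_PER_PROTOFIBRIL * cs.n_protofibrils
    return (
        cs.neighbors_flat,
        cs.neighbor_offsets,
        cs.edge_indices,
        cs.n_protofibrils,
        rates.k_unbind,
        rates.k_crawl,
        rates.k_deg,
        rates.k_exp,
        threshold_count(config.cleavage_fraction, total),
        fraction_threshold_counts(total),
        config.stop_at_cleavage,
    )


def simulate_run(
    spec: FiberSpec | CrossSection,
    rates: RateSet,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> RunResult:
    """One seeded, reproducible SSA trajectory on the fiber's cross-section."""
    cs = spec.cross_section() if isinstance(spec, FiberSpec) else spec
    total = DOUBLETS_PER_PROTOFIBRIL * cs.n_protofibrils
    (
        status,
        cleave_time,
        frac_times,
        deg_map,
        degraded,
        t,
        init_loc,
        first_deg,
        _snap_map,
        _snap_time,
        _snapped,
        n_events,
        ev_t,
        ev_r,
        ev_p,
    ) = _kernel.run_one(
        *_kernel_args(cs, rates, config),
        -1,
        config.record_events,
        config.max_events,
        int(seed),
    )
    if status == _kernel.STATUS_RUNAWAY:
        raise RunawayError(
            f"trajectory exceeded max_events={config.max_events} (seed {seed})"
        )
    fraction_times = {
        float(f): (None if math.isnan(ft) else float(ft))
        for f, ft in zip(FRACTION_GRID, frac_times)
    }
    event_log = None
    if config.record_events:
        event_log = [
            (float(a), int(b), int(c)) for a, b, c in zip(ev_t, ev_r, ev_p)
        ]
    return RunResult(
        success=not math.isnan(cleave_time),
        cleavage_time_s=None if math.isnan(cleave_time) else float(cleave_time),
        fraction_times_s=fraction_times,
        final_map=np.asarray(deg_map),
        initial_plasmin=int(init_loc),
        first_degradation=None if first_deg < 0 else int(first_deg),
        n_events=int(n_events),
        end_time_s=float(t),
        max_fraction_reached=float(degraded) / total,
        status=int(status),
        side=cs.side,
        event_log=event_log,
        seed=int(seed),
    )


def simulate_run_reference(
    spec: FiberSpec | CrossSection,
    rates: RateSet,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> RunResult:
    """Pure-Python twin of :func:`simulate_run` built from the step functions.

    Slow; exists so tests can check the compiled kernel against the readable
    implementation trajectory-for-trajectory (both consume the seeded
    MT19937 stream identically).
    """
    cs = spec.cross_section() if isinstance(spec, FiberSpec) else spec
    total = DOUBLETS_PER_PROTOFIBRIL * cs.n_protofibrils
    cleave_count = threshold_count(config.cleavage_fraction, total)
    frac_counts = fraction_threshold_counts(total)
    rng = np.random.RandomState(int(seed))
    state = init_state(cs, rng)
    init_loc = state.plasmin_location
    fraction_times: dict = {float(f): None for f in FRACTION_GRID}
    next_frac = 0
    cleave_time = None
    event_log: list = [] if config.record_events else None  # type: ignore
    n_events = 0
    status = _kernel.STATUS_RUNNING
    while status == _kernel.STATUS_RUNNING:
        src = state.plasmin_location
        rid = step(state, rates, rng)
        if rid is None:
            status = _kernel.STATUS_QUIESCENT
            break
        n_events += 1
        if event_log is not None:
            event_log.append((state.time_s, rid, src))
        if rid in (1, 4):
            status = _kernel.STATUS_UNBOUND
        while next_frac < len(frac_counts) and state.degraded_count >= frac_counts[next_frac]:
            fraction_times[float(FRACTION_GRID[next_frac])] = state.time_s
            next_frac += 1
        if cleave_time is None and state.degraded_count >= cleave_count:
            cleave_time = state.time_s
            if config.stop_at_cleavage and status == _kernel.STATUS_RUNNING:
                status = _kernel.STATUS_CLEAVED
        if state.degraded_count >= total and status == _kernel.STATUS_RUNNING:
            status = _kernel.STATUS_FULLY_DEGRADED
        if status == _kernel.STATUS_RUNNING and n_events >= config.max_events:
            raise RunawayError(f"trajectory exceeded max_events (seed {seed})")
    return RunResult(
        success=cleave_time is not None,
        cleavage_time_s=cleave_time,
        fraction_times_s=fraction_times,
        final_map=state.degraded_map(),
        initial_plasmin=init_loc,
        first_degradation=None
        if state.first_degradation == ABSENT
        else state.first_degradation,
        n_events=n_events,
        end_time_s=state.time_s,
        max_fraction_reached=state.degraded_count / total,
        status=int(status),
        side=cs.side,
        event_log=event_log,
        seed=int(seed),
    )
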