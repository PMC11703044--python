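"""Ensembles of independent lysis trajectories and their summary statistics.

The model is stochastic, so results are reported over many independent
Gillespie runs (10,000 by default): the cleavage success rate, the median and
5th/95th percentiles of cleavage time over successful runs, per-fraction
first-crossing statistics, and degradation-map snapshots. Per-run seeds are
spawned from the master seed, so ensembles are reproducible and independent
of execution order or thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .geometry import CrossSection, FiberSpec
from .ssa import (
    DOUBLETS_PER_PROTOFIBRIL,
    FRACTION_GRID,
    RateSet,
    RunResult,
    RunawayError,
    SimConfig,
    fraction_threshold_counts,
    threshold_count,
)

__all__ = [
    "EnsembleSummary",
    "DegradationMap",
    "RunsTable",
    "spawn_seeds",
    "run_ensemble",
    "parameter_sweep",
    "fraction_sweep",
    "snapshot_at",
    "representative_run",
    "count_fully_degraded",
]

SWEEPABLE = ("k_unbind", "k_crawl", "k_degexp")


def spawn_seeds(master_seed: int, n: int, key: int = 0) -> np.ndarray:
    """Derive ``n`` independent per-run seeds (< 2**31) from a master seed.

    ``key`` distinguishes independent seed blocks drawn from the same master
    seed (e.g. successive batches, or the sub-experiments of a script).
    """
    ss = np.random.SeedSequence([int(master_seed), int(key)])
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


@dataclass(frozen=True)
class RunsTable:
    """Raw per-run arrays of an ensemble (one row per trajectory)."""

    seeds: np.ndarray
    success: np.ndarray  # bool
    cleavage_time_s: np.ndarray  # float, NaN where unsuccessful
    fraction_times_s: np.ndarray  # (n_runs, 100), NaN where never crossed
    max_fraction_reached: np.ndarray  # final degraded fraction per run
    end_time_s: np.ndarray
    statuses: np.ndarray
    snapshot_maps: Optional[np.ndarray] = None  # (n_runs, n_proto) when taken
    snapshot_ok: Optional[np.ndarray] = None


@dataclass(frozen=True)
class EnsembleSummary:
    """Summary statistics over independent runs.

    Percentiles use linear interpolation (numpy default) over successful
    runs only; they are None when no run succeeded. Per-fraction medians are
    computed only over runs that reached the fraction.
    """

    n_runs: int
    n_success: int
    success_rate: float
    median_cleavage_s: Optional[float]
    p05_cleavage_s: Optional[float]
    p95_cleavage_s: Optional[float]
    per_fraction_median_s: dict
    per_fraction_success: dict
    max_fraction_reached: float
    runs: Optional[RunsTable] = field(default=None, repr=False)

    def as_row(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "n_success": self.n_success,
            "success_rate": self.success_rate,
            "median_s": self.median_cleavage_s,
            "p05_s": self.p05_cleavage_s,
            "p95_s": self.p95_cleavage_s,
        }


@dataclass(frozen=True)
class DegradationMap:
    """Degraded-doublet counts per protofibril at a snapshot fraction."""

    counts: np.ndarray  # length side**2, values 0..6
    side: int
    snapshot_fraction: float
    snapshot_time_s: Optional[float]
    initial_plasmin: Optional[int] = None
    first_degradation: Optional[int] = None

    def grid(self) -> np.ndarray:
        return self.counts.reshape(self.side, self.side)


def _resolve_cs(spec: FiberSpec | CrossSection) -> CrossSection:
    return spec.cross_section() if isinstance(spec, FiberSpec) else spec


def _run_batch(
    cs: CrossSection,
    rates: RateSet,
    config: SimConfig,
    seeds: np.ndarray,
    snap_fraction: Optional[float] = None,
    n_threads: int = 1,
) -> RunsTable:
    total = DOUBLETS_PER_PROTOFIBRIL * cs.n_protofibrils
    snap_count = (
        threshold_count(snap_fraction, total) if snap_fraction is not None else -1
    )
    args = (
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
        snap_count,
        config.max_events,
        np.asarray(seeds, dtype=np.int64),
    )
    if n_threads > 1:
        import numba

        # more threads than the machine has are silently clamped; per-run
        # seeding makes results identical for any thread count anyway
        n_eff = min(int(n_threads), numba.config.NUMBA_NUM_THREADS)
        if n_eff > 1:
            numba.set_num_threads(n_eff)
            out = _kernel.run_many_parallel(*args)
        else:
            out = _kernel.run_many(*args)
    else:
        out = _kernel.run_many(*args)
    statuses, cleave, fracs, final_frac, end_time, snaps, snap_ok = out
    if np.any(statuses == _kernel.STATUS_RUNAWAY):
        bad = np.asarray(seeds)[statuses == _kernel.STATUS_RUNAWAY]
        raise RunawayError(
            f"{bad.size} trajectories exceeded max_events={config.max_events}"
        )
    return RunsTable(
        seeds=np.asarray(seeds),
        success=~np.isnan(cleave),
        cleavage_time_s=cleave,
        fraction_times_s=fracs,
        max_fraction_reached=final_frac,
        end_time_s=end_time,
        statuses=statuses,
        snapshot_maps=snaps if snap_fraction is not None else None,
        snapshot_ok=snap_ok if snap_fraction is not None else None,
    )


def summarize(runs: RunsTable, keep_runs: bool = False) -> EnsembleSummary:
    """Build an :class:`EnsembleSummary` from raw per-run arrays."""
    n = len(runs.seeds)
    succ = runs.success
    n_success = int(succ.sum())
    times = runs.cleavage_time_s[succ]
    if n_success:
        p05, med, p95 = (float(v) for v in np.percentile(times, [5, 50, 95]))
    else:
        p05 = med = p95 = None
    per_med: dict = {}
    per_succ: dict = {}
    for j, f in enumerate(FRACTION_GRID):
        col = runs.fraction_times_s[:, j]
        reached = ~np.isnan(col)
        per_succ[float(f)] = float(reached.mean())
        per_med[float(f)] = float(np.median(col[reached])) if reached.any() else None
    return EnsembleSummary(
        n_runs=n,
        n_success=n_success,
        success_rate=n_success / n,
        median_cleavage_s=med,
        p05_cleavage_s=p05,
        p95_cleavage_s=p95,
        per_fraction_median_s=per_med,
        per_fraction_success=per_succ,
        max_fraction_reached=float(runs.max_fraction_reached.max()),
        runs=runs if keep_runs else None,
    )


def run_ensemble(
    spec: FiberSpec | CrossSection,
    rates: RateSet = RateSet(),
    config: SimConfig = SimConfig(),
    n_runs: int = 10_000,
    master_seed: int = 0,
    keep_runs: bool = False,
    snap_fraction: Optional[float] = None,
    n_threads: int = 1,
    seed_key: int = 0,
) -> EnsembleSummary:
    """Run ``n_runs`` independent trajectories and summarize them."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cs = _resolve_cs(spec)
    seeds = spawn_seeds(master_seed, n_runs, key=seed_key)
    runs = _run_batch(cs, rates, config, seeds, snap_fraction, n_threads)
    return summarize(runs, keep_runs=keep_runs or snap_fraction is not None)


def parameter_sweep(
    base: RateSet,
    which: str,
    values: Sequence[float],
    spec: FiberSpec | CrossSection = FiberSpec(72.7),
    config: SimConfig = SimConfig(),
    n_runs: int = 10_000,
    master_seed: int = 0,
    n_threads: int = 1,
) -> pd.DataFrame:
    """Vary one rate (or the tied pair k_deg=k_exp) over ``values``.

    Returns one summary row per value. Each value gets its own seed block so
    rows are independent ensembles.
    """
    if which not in SWEEPABLE:
        raise ValueError(f"which must be one of {SWEEPABLE}, got {which!r}")
    cs = _resolve_cs(spec)
    rows = []
    for i, v in enumerate(values):
        if which == "k_degexp":
            rates = RateSet(base.k_unbind, base.k_crawl, v, v)
        elif which == "k_unbind":
            rates = RateSet(v, base.k_crawl, base.k_deg, base.k_exp)
        else:
            rates = RateSet(base.k_unbind, v, base.k_deg, base.k_exp)
        s = run_ensemble(
            cs, rates, config, n_runs, master_seed, seed_key=i, n_threads=n_threads
        )
        rows.append({"param": which, "value": float(v), **s.as_row()})
    return pd.DataFrame(rows)


def fraction_sweep(
    spec: FiberSpec | CrossSection,
    rates: RateSet = RateSet(),
    n_runs: int = 10_000,
    master_seed: int = 0,
    config: SimConfig = SimConfig(),
    n_threads: int = 1,
) -> pd.DataFrame:
    """First-crossing statistics of every fraction 0.01..1.00.

    Runs proceed with no early stop (until plasmin unbinds or the
    cross-section is fully degraded). For each fraction, the median and
    5th/95th percentiles are taken over the runs that reached it; ``success``
    is the share of runs reaching it. The returned frame carries the
    ensemble-wide maximum fraction reached in ``attrs['max_fraction_reached']``.
    """
    cs = _resolve_cs(spec)
    cfg = SimConfig(
        cleavage_fraction=config.cleavage_fraction,
        record_fractions=True,
        record_events=False,
        stop_at_cleavage=False,
        max_events=config.max_events,
    )
    seeds = spawn_seeds(master_seed, n_runs)
    runs = _run_batch(cs, rates, cfg, seeds, n_threads=n_threads)
    rows = []
    for j, f in enumerate(FRACTION_GRID):
        col = runs.fraction_times_s[:, j]
        reached = ~np.isnan(col)
        k = int(reached.sum())
        if k:
            p05, med, p95 = np.percentile(col[reached], [5, 50, 95])
        else:
            p05 = med = p95 = np.nan
        rows.append(
            {
                "fraction": float(f),
                "median_s": float(med),
                "p05_s": float(p05),
                "p95_s": float(p95),
                "success": k / n_runs,
                "n_reached": k,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["max_fraction_reached"] = float(runs.max_fraction_reached.max())
    return df


def snapshot_at(run: RunResult, pct: float) -> DegradationMap:
    """Reconstruct the degradation map at first crossing of fraction ``pct``.

    Replays the run's event log: each R2/R3 event adds one degraded doublet
    at its protofibril. Raises ``ValueError`` when the run has no event log
    or never reached ``pct``.
    """
    if run.event_log is None:
        raise ValueError("run has no event log; simulate with record_events=True")
    n_proto = run.side * run.side
    total = DOUBLETS_PER_PROTOFIBRIL * n_proto
    need = threshold_count(pct, total)
    counts = np.zeros(n_proto, dtype=np.int64)
    degraded = 0
    for t, rid, p in run.event_log:
        if rid in (2, 3):
            counts[p] += 1
            degraded += 1
            if degraded >= need:
                return DegradationMap(
                    counts=counts,
                    side=run.side,
                    snapshot_fraction=pct,
                    snapshot_time_s=t,
                    initial_plasmin=run.initial_plasmin,
                    first_degradation=run.first_degradation,
                )
    raise ValueError(
        f"run never reached fraction {pct} "
        f"(max reached {run.max_fraction_reached:.3f})"
    )


def representative_run(runs: Sequence[RunResult]) -> RunResult:
    """The successful run whose cleavage time is nearest the ensemble median.

    Ties break toward the earliest run in the sequence.
    """
    times = [r.cleavage_time_s for r in runs if r.success]
    if not times:
        raise ValueError("no successful runs")
    med = float(np.median(times))
    best = None
    best_d = np.inf
    for r in runs:
        if not r.success:
            continue
        d = abs(r.cleavage_time_s - med)
        if d < best_d:
            best, best_d = r, d
    return best


def count_fully_degraded(dmap: DegradationMap | np.ndarray) -> int:
    """Number of protofibrils with all 6 doublets degraded."""
    counts = dmap.counts if isinstance(dmap, DegradationMap) else np.asarray(dmap)
    return int((counts == DOUBLETS_PER_PROTOFIBRIL).sum())
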