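"""Numba kernels for the Gillespie simulation of single-plasmin fiber lysis.

The model state per protofibril is the count vector (N00, N03, phi00, phi03,
N_cryptic); exactly one plasmin molecule exists, so N03 + phi03 summed over
the cross-section is 1 while it is bound. The kernels store only the unbound
counts (n00, phi00, cryptic) per protofibril plus the plasmin location and
whether it sits on a degraded doublet; the bound doublet is implicit.

Reactions (ids 1..11, propensities evaluated at the plasmin's protofibril
with x1=N00, x2=N03, x3=phi00, x4=phi03, x5=N_cryptic):

  R1  k_unbind*x2   plasmin unbinds from N03 -> N00 (run terminates)
  R2  k_deg*x1      degrade an N00 -> phi00
  R3  k_deg*x2      degrade the bound doublet, N03 -> phi03
  R4  k_unbind*x4   plasmin unbinds from phi03 -> phi00 (run terminates)
  R5  k_exp*x5      expose a cryptic doublet -> N00
  R6  k_crawl*x2*x3 crawl N03 -> phi00 at same protofibril
  R7  k_crawl*x1*x4 crawl phi03 -> N00 at same protofibril
  R8  k_crawl*x2*x1 crawl N03 -> N00 (null event: state unchanged)
  R9  k_crawl*x4*x3 crawl phi03 -> phi00 (null event)
  R10 k_crawl*x2    crawl from N03 to a neighboring protofibril
  R11 k_crawl*x4    crawl from phi03 to a neighboring protofibril

R10/R11 pick a direct neighbor uniformly, then bind a uniformly chosen
non-cryptic doublet there (exposed or degraded). On a 1x1 grid there are no
neighbors and R10/R11 propensities are zero.

Random-number consumption per event is fixed (one uniform for the waiting
time, one for the reaction, and for R10/R11 one for the neighbor and one for
the doublet) so that the pure-Python reference path in :mod:`fiberlysis.ssa`
can reproduce kernel trajectories bitwise from the same seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

# Termination statuses.
STATUS_RUNNING = 0
STATUS_UNBOUND = 1
STATUS_FULLY_DEGRADED = 2
STATUS_CLEAVED = 3
STATUS_QUIESCENT = 4  # total propensity zero (all rates zero edge case)
STATUS_RUNAWAY = 5  # max_events exceeded

N_FRACTIONS = 100  # the 0.01, 0.02, ..., 1.00 first-crossing grid


@njit(cache=True)
def run_one(
    nbr_flat,
    nbr_off,
    edge_idx,
    n_proto,
    k_unbind,
    k_crawl,
    k_deg,
    k_exp,
    cleave_count,
    frac_counts,
    stop_at_cleavage,
    snap_count,
    record_events,
    max_events,
    seed,
):
    """One exact SSA trajectory. Returns the full per-run record."""
    np.random.seed(seed)
    total = 6 * n_proto

    n00 = np.ones(n_proto, np.int64)
    phi00 = np.zeros(n_proto, np.int64)
    cry = np.full(n_proto, 5, np.int64)
    deg_map = np.zeros(n_proto, np.int64)

    loc = edge_idx[int(np.random.random() * len(edge_idx))]
    init_loc = loc
    n00[loc] -= 1  # plasmin occupies the one exposed doublet
    on_phi = False

    t = 0.0
    degraded = 0
    frac_times = np.full(N_FRACTIONS, np.nan)
    next_frac = 0
    cleave_time = np.nan
    snap_map = np.zeros(n_proto, np.int64)
    snap_time = np.nan
    snapped = snap_count <= 0
    first_deg = -1
    n_events = 0
    status = STATUS_RUNNING

    cap = max_events if record_events else 0
    ev_time = np.empty(cap, np.float64)
    ev_rid = np.empty(cap, np.int8)
    ev_loc = np.empty(cap, np.int64)

    a = np.empty(11, np.float64)
    while status == STATUS_RUNNING:
        x1 = n00[loc]
        x3 = phi00[loc]
        x5 = cry[loc]
        x2 = 0 if on_phi else 1
        x4 = 1 - x2
        nn = nbr_off[loc + 1] - nbr_off[loc]

        a[0] = k_unbind * x2
        a[1] = k_deg * x1
        a[2] = k_deg * x2
        a[3] = k_unbind * x4
        a[4] = k_exp * x5
        a[5] = k_crawl * x2 * x3
        a[6] = k_crawl * x1 * x4
        a[7] = k_crawl * x2 * x1
        a[8] = k_crawl * x4 * x3
        a[9] = k_crawl * x2 if nn > 0 else 0.0
        a[10] = k_crawl * x4 if nn > 0 else 0.0
        a0 = 0.0
        for i in range(11):
            a0 += a[i]
        if a0 <= 0.0:
            status = STATUS_QUIESCENT
            break

        u = np.random.random()
        t += -np.log(1.0 - u) / a0
        v = np.random.random() * a0
        rid = 10
        acc = 0.0
        for i in range(11):
            acc += a[i]
            if v < acc:
                rid = i
                break

        src = loc
        if rid == 0:  # R1 unbind from N03
            n00[loc] += 1
            status = STATUS_UNBOUND
        elif rid == 1:  # R2 degrade N00
            n00[loc] -= 1
            phi00[loc] += 1
            deg_map[loc] += 1
            degraded += 1
            if first_deg < 0:
                first_deg = loc
        elif rid == 2:  # R3 degrade bound N03
            on_phi = True
            deg_map[loc] += 1
            degraded += 1
            if first_deg < 0:
                first_deg = loc
        elif rid == 3:  # R4 unbind from phi03
            phi00[loc] += 1
            status = STATUS_UNBOUND
        elif rid == 4:  # R5 expose cryptic
            cry[loc] -= 1
            n00[loc] += 1
        elif rid == 5:  # R6 N03 -> phi00 locally
            n00[loc] += 1
            phi00[loc] -= 1
            on_phi = True
        elif rid == 6:  # R7 phi03 -> N00 locally
            phi00[loc] += 1
            n00[loc] -= 1
            on_phi = False
        elif rid == 7 or rid == 8:  # R8/R9 null events
            pass
        else:  # R10/R11 crawl to a neighbor
            if rid == 9:
                n00[loc] += 1
            else:
                phi00[loc] += 1
            dest = nbr_flat[nbr_off[loc] + int(np.random.random() * nn)]
            m = n00[dest] + phi00[dest]
            j = int(np.random.random() * m)
            if j < n00[dest]:
                n00[dest] -= 1
                on_phi = False
            else:
                phi00[dest] -= 1
                on_phi = True
            loc = dest

        if record_events:
            if n_events >= cap:
                status = STATUS_RUNAWAY
                break
            ev_time[n_events] = t
            ev_rid[n_events] = rid + 1
            ev_loc[n_events] = src
        n_events += 1

        while next_frac < N_FRACTIONS and degraded >= frac_counts[next_frac]:
            frac_times[next_frac] = t
            next_frac += 1
        if np.isnan(cleave_time) and degraded >= cleave_count:
            cleave_time = t
            if stop_at_cleavage and status == STATUS_RUNNING:
                status = STATUS_CLEAVED
        if not snapped and degraded >= snap_count:
            snap_map[:] = deg_map
            snap_time = t
            snapped = True
        if degraded >= total and status == STATUS_RUNNING:
            status = STATUS_FULLY_DEGRADED
        if status == STATUS_RUNNING and n_events >= max_events:
            status = STATUS_RUNAWAY

    return (
        status,
        cleave_time,
        frac_times,
        deg_map,
        degraded,
        t,
        init_loc,
        first_deg,
        snap_map,
        snap_time,
        snapped and snap_count > 0,
        n_events,
        ev_time[:n_events],
        ev_rid[:n_events],
        ev_loc[:n_events],
    )


@njit(cache=True)
def run_many(
    nbr_flat,
    nbr_off,
    edge_idx,
    n_proto,
    k_unbind,
    k_crawl,
    k_deg,
    k_exp,
    cleave_count,
    frac_counts,
    stop_at_cleavage,
    snap_count,
    max_events,
    seeds,
):
    """Serial ensemble driver: one independent trajectory per seed."""
    n = len(seeds)
    statuses = np.empty(n, np.int8)
    cleave = np.full(n, np.nan)
    fracs = np.full((n, N_FRACTIONS), np.nan)
    final_frac = np.zeros(n)
    end_time = np.zeros(n)
    snaps = np.zeros((n, n_proto), np.int16)
    snap_ok = np.zeros(n, np.bool_)
    total = 6.0 * n_proto
    for i in range(n):
        (
            status,
            cleave_time,
            frac_times,
            _deg_map,
            degraded,
            t,
            _init_loc,
            _first_deg,
            snap_map,
            _snap_time,
            snapped,
            _n_events,
            _et,
            _er,
            _el,
        ) = run_one(
            nbr_flat,
            nbr_off,
            edge_idx,
            n_proto,
            k_unbind,
            k_crawl,
            k_deg,
            k_exp,
            cleave_count,
            frac_counts,
            stop_at_cleavage,
            snap_count,
            False,
            max_events,
            seeds[i],
        )
        statuses[i] = status
        cleave[i] = cleave_time
        fracs[i] = frac_times
        final_frac[i] = degraded / total
        end_time[i] = t
        if snapped:
            snaps[i] = snap_map.astype(np.int16)
            snap_ok[i] = True
    return statuses, cleave, fracs, final_frac, end_time, snaps, snap_ok


@njit(cache=True, parallel=True)
def run_many_parallel(
    nbr_flat,
    nbr_off,
    edge_idx,
    n_proto,
    k_unbind,
    k_crawl,
    k_deg,
    k_exp,
    cleave_count,
    frac_counts,
    stop_at_cleavage,
    snap_count,
    max_events,
    seeds,
):
    """Threaded ensemble driver; bitwise-identical to :func:`run_many`.

    Each loop iteration seeds the executing thread's generator with its own
    per-run seed before drawing, so results do not depend on the schedule or
    thread count.
    """
    n = len(seeds)
    statuses = np.empty(n, np.int8)
    cleave = np.full(n, np.nan)
    fracs = np.full((n, N_FRACTIONS), np.nan)
    final_frac = np.zeros(n)
    end_time = np.zeros(n)
    snaps = np.zeros((n, n_proto), np.int16)
    snap_ok = np.zeros(n, np.bool_)
    total = 6.0 * n_proto
    for i in prange(n):
        (
            status,
            cleave_time,
            frac_times,
            _deg_map,
            degraded,
            t,
            _init_loc,
            _first_deg,
            snap_map,
            _snap_time,
            snapped,
            _n_events,
            _et,
            _er,
            _el,
        ) = run_one(
            nbr_flat,
            nbr_off,
            edge_idx,
            n_proto,
            k_unbind,
            k_crawl,
            k_deg,
            k_exp,
            cleave_count,
            frac_counts,
            stop_at_cleavage,
            snap_count,
            False,
            max_events,
            seeds[i],
        )
        statuses[i] = status
        cleave[i] = cleave_time
        fracs[i] = frac_times
        final_frac[i] = degraded / total
        end_time[i] = t
        if snapped:
            snaps[i] = snap_map.astype(np.int16)
            snap_ok[i] = True
    return statuses, cleave, fracs, final_frac, end_time, snaps, snap_ok
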