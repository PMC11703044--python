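# fiberlysis

Stochastic simulation of **single fibrin fiber lysis by one plasmin
molecule**, with ensemble statistics, spatial-autocorrelation analysis of
degradation patterns, and fiber-diameter comparison tools.

## The problem

Blood clots are stabilized by a mesh of fibrin fibers. Plasmin, the
fibrinolytic protease, degrades fibrin at discrete sites along a fiber, and
the fiber is ultimately cut transversely at a single location. Macroscale
models of clot lysis cannot say how that happens at the scale of one fiber
cross-section: how fast a single plasmin molecule can chew through a
cross-section, how often it lets go before the fiber fails, how localized
the damage is, and how all of this depends on fiber diameter. This package
is for researchers in fibrinolysis modeling who want a fast, reproducible,
fully seeded implementation of that microscale picture.

## The model

A fiber of diameter *d* (nm) that is a fraction *p* protein, built from
4.8 nm protofibrils, contains

    n = p · d² / 23.04

protofibril cross-sections, arranged as a square lattice of side
round(√n) (72.7 nm at p = 0.21 → a 7 × 7 grid). Each protofibril carries 6
**binding doublets** (pairs of plasmin binding sites representing its six
polypeptide chains): initially 1 exposed and 5 cryptic. One plasmin molecule
lands on a uniformly chosen perimeter protofibril and the system evolves by
an exact Gillespie (SSA) simulation of 11 reactions — plasmin unbinding
(rate k_unbind per bound doublet), exposure of cryptic doublets
(k_exp × #cryptic), degradation of exposed doublets (k_deg per doublet),
and crawling between doublets and to 4-connected neighbor protofibrils
(k_crawl). Free plasmin is assumed to be instantly inhibited by
α2-antiplasmin, so unbinding ends the run. The fiber **cleaves** when a
threshold fraction (default 2/3) of its doublets is degraded — a proxy for
tension snapping the partially degraded fiber.

Baseline rates (1/s): k_unbind = 0.05, k_crawl = 57.6, k_deg = k_exp = 5.

On top of single runs the package provides:

- **ensembles** — success rate, median/5th/95th-percentile cleavage times,
  per-fraction first-crossing statistics, parameter sweeps (`ensemble`);
- **spatial statistics** — Moran's I of per-protofibril degraded-doublet
  counts under the binary direct-neighbor weights matrix (`spatial`);
- **diameter analysis** — apparent diameters from Gaussian fits to
  fluorescence intensity profiles (4σ), diameter scaling, OLS regression,
  and matching degradation fractions to a fixed cleavage-time-vs-diameter
  slope (`diameter`), plus a synthetic profile generator.

The Gillespie inner loop is JIT-compiled (numba); a 10,000-run ensemble on
the 7 × 7 grid takes a few seconds on one core. A pure-Python step-by-step
implementation of the same model ships alongside and is held to
bitwise-identical trajectories in the test suite.

## Worked example

```python
from fiberlysis import FiberSpec, RateSet, SimConfig, run_ensemble

fiber = FiberSpec(72.7)
summary = run_ensemble(fiber, RateSet(), SimConfig(), n_runs=10_000, master_seed=1)
```

Running `python examples/baseline_ensemble.py` (which does exactly this)
prints:

```
fiber: 72.7 nm -> 7x7 protofibril grid
runs: 10000, successful cleavages: 3133
success rate: 31.33%
cleavage time: median 22.88 s (5th-95th pct 20.67-25.49 s)
```

Meaning: with baseline kinetics, a single plasmin molecule degrades 2/3 of
a thin fiber's cross-section before unbinding in about 31% of attempts, and
when it succeeds the fiber cleaves in roughly 23 s. The success rate is set
almost entirely by the race between the unbinding clock (k_unbind) and the
cleavage time; the cleavage time itself is set by the exposure, degradation,
and crawling rates.

The other `examples/` scripts each demonstrate one capability: rate sweeps
(`parameter_sweeps.py`), degradation-map snapshots of a representative run
(`degradation_snapshots.py`), Moran's I clustering analysis
(`spatial_autocorrelation.py`), and the diameter workflow from synthetic
intensity profiles through fraction matching (`diameter_comparison.py`).

There is also a thin CLI:

```bash
fiberlysis simulate --runs 10000 --seed 1 --out out/
fiberlysis sweep --param k_degexp --values 5,10,20,50 --runs 10000 --out out/
fiberlysis moran --maps 1000 --seed 1 --out out/
```

Every output directory gets a `manifest.json` sufficient to reproduce the
run bitwise.

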