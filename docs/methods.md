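# Methods

## Model

The unit of simulation is one fibrin fiber cross-section, reduced to a
square lattice of protofibril cross-sections. The protofibril count follows
from area bookkeeping: a fiber of diameter *d* nm at protein fraction *p*,
built from solid 4.8 nm protofibril cylinders, needs n = p·d²/23.04
protofibrils; the lattice side is √n rounded half-away-from-zero. With the
default p = 0.21 the nine supported diameters 72.7–280.4 nm give sides
7–27. The lattice is 4-connected; the same adjacency serves plasmin
crawling and the spatial weights of the Moran's I analysis, so one
connectivity choice governs both.

Each protofibril holds 6 binding doublets in one of five classes: cryptic
N, exposed N00/N03, degraded φ00/φ03 (suffix 03 = plasmin bound). Doublets
within a protofibril are exchangeable — only class counts are tracked — and
a single plasmin molecule exists. The continuous-time Markov jump process
has 11 reactions, evaluated at the plasmin's protofibril with local counts
x1 = N00, x2 = N03, x3 = φ00, x4 = φ03, x5 = N:

| id  | propensity        | effect |
|-----|-------------------|--------|
| R1  | k_unbind·x2       | unbind from N03 (run ends) |
| R2  | k_deg·x1          | degrade an N00 → φ00 |
| R3  | k_deg·x2          | degrade the bound doublet → φ03 |
| R4  | k_unbind·x4       | unbind from φ03 (run ends) |
| R5  | k_exp·x5          | expose a cryptic doublet → N00 |
| R6  | k_crawl·x2·x3     | crawl N03 → φ00 (same protofibril) |
| R7  | k_crawl·x1·x4     | crawl φ03 → N00 |
| R8  | k_crawl·x2·x1     | crawl N03 → N00 (null event) |
| R9  | k_crawl·x4·x3     | crawl φ03 → φ00 (null event) |
| R10 | k_crawl·x2        | crawl to a neighboring protofibril |
| R11 | k_crawl·x4        | crawl to a neighboring protofibril |

R10/R11 choose a direct neighbor uniformly, then a uniformly chosen
non-cryptic doublet there (plasmin may land on degraded doublets but cannot
degrade them further). On a 1×1 lattice R10/R11 are zeroed (no
destination). Unbinding terminates the run because free plasmin is taken to
be instantly inhibited by α2-antiplasmin; rebinding and within-cross-section
diffusion are neglected. The simulation is an exact SSA: exponential
waiting times from the total propensity, reaction choice proportional to
propensity.

Cleavage is a tension proxy: the fiber is considered cut when the degraded
fraction of its 6·side² doublets first reaches a threshold (default 2/3;
ties at exact equality count, and threshold counts are computed as
ceil(f·total − 1e−9) to keep mathematically integer products such as
(2/3)·294 = 196 from rounding up). Every run also records first-crossing
times of each fraction 0.01…1.00.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| k_unbind | plasmin unbinding from fibrin | 0.05 | 1/s |
| k_crawl  | plasmin crawling rate | 57.6 | 1/s |
| k_deg    | degradation of an exposed doublet | 5 | 1/s |
| k_exp    | exposure of a cryptic doublet | 5 | 1/s |
| diameter | fiber diameter | 72.7 | nm |
| protein fraction | protein share of cross-section area | 0.21 | — |
| cleavage fraction | degraded share at which the fiber snaps | 2/3 | — |

These rate constants are literature-derived baselines; most have not been
measured directly, which is why the sweep utilities vary one at a time
(k_deg and k_exp always move together, reflecting that both are
plasmin-mediated and equally uncertain). k_unbind sets the success rate
almost alone — success ≈ P(Exp(k_unbind) exceeds the would-be cleavage
time) — while k_deg/k_exp and k_crawl set the cleavage time.

## Ensembles and statistics

Ensembles default to 10,000 independent runs; per-run seeds are spawned from
a master seed via numpy's SeedSequence (masked below 2³¹), so results are
identical regardless of execution order or thread count, and a threaded
driver is available that is bitwise-equal to the serial one. Percentiles use
numpy's linear interpolation (type 7). Per-fraction medians are computed
only over runs that reached the fraction; the shrinking denominator at high
fractions is reported alongside (`success`, `n_reached`).

Moran's I uses binary, unstandardized direct-neighbor weights:
I = (n/W)·Σᵢⱼwᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σᵢ(xᵢ−x̄)², on per-protofibril
degraded-doublet counts (0–6) snapshotted at the first crossing of a
fraction (default 54%). The ensemble version collects a fixed number of
qualifying maps (default 1000) rather than a fixed number of attempts, so
parameter sets with different success rates yield equal sample sizes.
Normality-based variance and z-score are provided for single maps;
ensemble results report the median coefficient. Constant-valued maps (never
observed in practice) would be dropped with a count kept.

The diameter module mirrors the microscopy workflow: a 1D intensity profile
is fit with amplitude·exp(−(x−μ)²/2σ²) + c by least squares (background c
fit jointly — equivalent to subtracting a constant background, and more
robust), and the apparent diameter is 4σ. Cohorts are scaled by the
second-smallest apparent diameter (an outlier-robust reference: the
smallest measured fiber can sit far below the rest). Model diameters are
scaled by 72.7 nm so the thinnest simulated fiber sits at 1.0.
`match_fractions` anchors a fixed-slope line at one diameter's median time
and inverts each diameter's monotone fraction→time table by linear
interpolation on the 1% fraction grid, flagging diameters whose reachable
time range does not contain the line.

## Synthetic data

The profile generator (`make_profile_fixture`) emulates a background-limited
epifluorescence line profile: Gaussian fiber + constant background +
i.i.d. Gaussian noise, seeded. It does not emulate diffraction sidelobes,
pixelation, photobleaching, or spatially varying background, so
profile-fitting tests demonstrate estimator correctness on well-specified
input, not robustness to real microscope artifacts. No experimental
diameter/cleavage cohort is bundled; the diameter examples generate a
synthetic cohort with a known linear time–diameter law and label it as such.

## Numerical and design choices

- **Two implementations, one model.** The production path is a numba-JIT
  Gillespie kernel (~10⁷ events/s); the readable path
  (`init_state`/`local_propensities`/`apply_reaction`/`step`) consumes the
  seeded MT19937 stream in the same order, and the suite asserts
  bitwise-identical trajectories. Independent correctness anchors: on a
  side-1 fiber with crawling off the model is a small CTMC whose success
  probability and conditional mean cleavage time are solved exactly by
  linear algebra and compared against the SSA; with only unbinding active,
  run lengths are checked against the exponential law (KS test); Moran's I
  is checked against a brute-force double loop.
- **Crawl destination.** "Neighbor first, then doublet" was chosen over
  "uniform over all neighboring doublets". The alternative weights
  destinations by their non-cryptic doublet count, pulling plasmin toward
  already-degraded regions; it slows median cleavage at baseline from
  ~23 s to ~38 s and raises median Moran's I from ~0.26 to ~0.54. The
  neighbor-first rule treats the hop as the elementary event, matching the
  propensity form (R10/R11 rates do not scale with destination counts).
- **Rounding and ties.** Grid side rounds half away from zero; fraction
  crossings count ties as reached; representative-run ties break toward the
  earliest run.
- **Degenerate inputs.** Zero rates are allowed (a fully quiescent state
  terminates the run explicitly); a `max_events` cap guards against
  non-terminating parameter choices and raises rather than truncating.
- **Problem sizes.** Default ensembles are 10,000 runs and 1,000 Moran
  maps — the sizes at which the reported statistics stabilize (median
  standard error well under the tolerance bands used in the tests); the
  examples use 300–5,000 runs since they only illustrate the API.

## Known limitations

- Doublets are well-mixed within a protofibril: the model tracks class
  counts, not doublet positions within the stack of six. Spatially resolved
  crawling (adjacent-doublet hops) would slow effective inter-protofibril
  transport and increase degradation clustering; the ensemble statistics —
  cleavage-time medians, success rates, and especially Moran's I — are
  sensitive to this abstraction.
- One plasmin molecule per cross-section; no plasminogen/tPA activation
  chemistry, no explicit α2-antiplasmin species, no crosslinked (FXIIIa)
  fibrin, no mechanical tension model beyond the cleavage-fraction
  threshold.
- The apparent-diameter estimate is a relative, diffraction-limited proxy;
  no PSF modeling or super-resolution correction is attempted.
- Success rates are reported as simple proportions; no confidence intervals
  are attached (at n = 10,000 the binomial standard error is ≤ 0.5 pp).
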