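"""Rate-constant sweeps: which kinetic step controls what?

Varies one rate at a time from baseline (the exposure and degradation rates
move together) and prints the ensemble summaries. Unbinding controls how
often lysis succeeds; exposure/degradation and crawling control how fast.
"""

from fiberlysis import FiberSpec, RateSet, parameter_sweep

fiber = FiberSpec(72.7)
N = 5000  # per value; enough for stable medians in a demo

for which, values in [
    ("k_unbind", [0.0, 0.025, 0.05, 0.075, 0.1]),
    ("k_degexp", [5, 10, 20, 35, 50]),
    ("k_crawl", [10, 30, 57.6, 90, 120]),
]:
    df = parameter_sweep(RateSet(), which, values, fiber, n_runs=N, master_seed=2)
    print(f"--- sweep over {which} (1/s), {N} runs per value ---")
    print(
        df[["value", "success_rate", "median_s", "p05_s", "p95_s"]]
        .round(3)
        .to_string(index=False)
    )
    print()

print("Raising the unbinding rate leaves the median time almost unchanged")
print("but collapses the success rate; faster exposure/degradation or")
print("faster crawling both shorten the median cleavage time, with")
print("diminishing returns once another step becomes rate limiting.")
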