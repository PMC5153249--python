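"""Single-exponential mRNA-recruitment kinetics: rates, endpoints, fold changes.

Simulates replicate time courses at the fast (native mRNA with eIF3,
0.27/min) and slow (model mRNA without eIF3, 0.02/min) recruitment rates,
fits each with y(t) = A*(1 - exp(-k t)), aggregates, and reports the fold
difference in rates.
"""

import numpy as np

from picshift import (
    NoiseModel,
    TimeCourseDesign,
    aggregate_replicates,
    fit_single_exponential,
    rate_ratio,
    simulate_timecourse,
)

noise = NoiseModel(sigma=0.02, seed=0)

conditions = {
    "native mRNA + eIF3": TimeCourseDesign(
        tuple(np.geomspace(0.5, 60.0, 8)), amplitude=0.8, k=0.27, n_replicates=4
    ),
    "model mRNA - eIF3": TimeCourseDesign(
        tuple(np.geomspace(5.0, 120.0, 8)), amplitude=0.8, k=0.02, n_replicates=4
    ),
}

best = {}
for label, design in conditions.items():
    fits = [fit_single_exponential(tc) for tc in simulate_timecourse(design, noise)]
    rates = aggregate_replicates([f.k_obs for f in fits if f.rate_resolved])
    ends = aggregate_replicates([f.endpoint for f in fits])
    best[label] = fits[0]
    print(f"{label}: k_obs = {rates.mean:.3f} +/- {rates.sem:.3f} /min "
          f"(true {design.k}), endpoint = {ends.mean:.2f} +/- {ends.sem:.2f}")

fold = rate_ratio(best["native mRNA + eIF3"], best["model mRNA - eIF3"])
print(f"\neIF3 accelerates recruitment of its fast condition "
      f"{fold:.1f}-fold over the slow one (first replicates compared)")

# a reaction complete before the first sample: rate unresolved, endpoint kept
fast = TimeCourseDesign((0.25, 0.5, 1.0, 2.0, 4.0, 8.0), 0.9, 20.0, n_replicates=1)
fit = fit_single_exponential(simulate_timecourse(fast, noise)[0])
print(f"\nsub-resolution reaction: rate_resolved={fit.rate_resolved}, "
      f"endpoint={fit.endpoint:.2f} (report the rate only as a bound)")
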