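"""Score the engine on simulated cohorts with known ground truth.

Simulates three cohorts of 90 samples (9 groups of 10) drawn from 21
ground-truth signatures inside a 79-signature synthetic reference at
increasing noise, runs the full assignment engine on each, and scores
signature presence/absence against the ground truth.
"""

from sigassign import (
    SimulationConfig,
    benchmark_noise_levels,
    sbs96_alphabet,
    synthetic_signatures,
)

reference = synthetic_signatures(79, sbs96_alphabet(), seed=7)
sim = SimulationConfig(
    n_groups=9,
    samples_per_group=10,
    n_ground_truth=21,
    signatures_per_group=4,
    seed=3,
)
summary = benchmark_noise_levels(reference, sim, noise_levels=(0.0, 0.05, 0.10))
print(summary.to_string(index=False))

# Precision stays near 1 (the engine rarely invents signatures) while
# sensitivity is bounded by the activity distribution: ground-truth
# signatures whose contribution falls below the removal threshold's
# detectability floor (roughly 10% of the catalog's L2 mass) are
# deliberately pruned by the sparsity mechanism and count as misses.
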