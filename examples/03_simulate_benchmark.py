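"""Build the synthetic RNA-Seq benchmark and inspect the sampling designs.

Shows the five sampling designs (all 180 samples), generates NB counts for
the 31 variable + constant genes, and prints count-matrix properties.
"""

import fieldfit as ff
from fieldfit.benchmark import benchmark_conditions

for design in ("2h", "4h", "6h", "8h", "12h"):
    sched = ff.sampling_design(design, 2008)
    per_day = len(sched) // 15
    print(f"design {design:>3}: {len(sched)} samples, {per_day} per sampling date")

schedule, weather = benchmark_conditions("4h")
truths = ff.truth_library(seed=7, constant_genes=50)
counts = ff.nb_counts(truths, schedule, weather, seed=8)

print(f"\ncount matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"library sizes: {counts.sum().min()} - {counts.sum().max()} reads")
n_const = sum(t.is_constant for t in truths)
print(f"{len(truths) - n_const} variable genes (clock / temperature response / age), "
      f"{n_const} constant genes stabilizing the counts-per-million scale")
print("\n2008 field schedule fixture:", len(ff.schedule_fixture_2008()), "samples;",
      "2009 evaluation fixture:", len(ff.schedule_fixture_2009()), "samples")
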