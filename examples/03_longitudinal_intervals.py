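"""Detect time intervals where taxon abundance differs between groups.

Aggregates OTUs to families, CSS-normalizes and log-transforms, then fits
per-group smoothing splines of abundance against study week.  Maximal runs
where the group curves separate are scored by their signed area and tested
by permuting group labels at the infant level.
"""

import numpy as np

from preterm_maturity import microbiome, pipeline, simulate

config = simulate.SimulationConfig(n_infants=40, prop_growth_failure=0.5,
                                   delay_weeks=3.0, seed=5)
metadata, _ = simulate.generate_metadata(config)
counts = simulate.generate_counts(metadata, config)

run = pipeline.RunConfig(out_dir="scratch/example_intervals", n_perm=499, seed=0)
intervals = pipeline.run_timeseries(run, table=counts, metadata=metadata)

sig = intervals[intervals["p_adjusted"] < 0.05]
print(f"{len(intervals)} candidate intervals, {len(sig)} significant after BH")
for _, row in sig.head(8).iterrows():
    print(
        f"  {row.feature_id:<30s} weeks {row.t_start:4.1f}-{row.t_end:4.1f} "
        f"{row.direction:<12s} area={row.area:6.1f}  q={row.p_adjusted:.3f}"
    )
print(
    "each line is a window in which one growth group's normalized abundance "
    "ran above the other's; the planted delay shifts age-discriminatory "
    "families between the groups"
)
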