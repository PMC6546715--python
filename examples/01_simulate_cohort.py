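"""Generate a synthetic longitudinal preterm cohort and inspect its design.

Builds the default study-sized cohort (58 infants, weekly samples over study
weeks 0-9, a 3-week maturation delay planted in the growth-failure group)
and prints the design margins.  Every table derives from the single seed.
"""

from preterm_maturity import simulate

config = simulate.SimulationConfig(seed=42)
metadata, profiles, counts, metabolites, truth = simulate.generate_cohort(config)

n_gf = (metadata.groupby("infant_id")["group"].first() == "growth_failure").sum()
print(f"infants: {config.n_infants} ({n_gf} growth failure)")
print(f"stool samples: {counts.n_samples}, OTUs: {counts.n_features}")
print(f"metabolite panel: {len(metabolites.metabolite_ids)} analytes")
print(f"PMA range: {metadata.pma_weeks.min():.1f}-{metadata.pma_weeks.max():.1f} weeks")
print(f"planted delay: {truth['delay_weeks']} weeks on {len(truth['age_taxa'])} taxa")

# The library sizes are log-normal around the study's median read depth;
# every column of the count table sums to its drawn library size.
totals = counts.counts.sum(axis=0)
print(f"median library size: {int(totals.median())} reads")
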