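"""Generate one synthetic city and summarise what the generator produced.

The generator emulates a large northern city's summer mortality: Poisson
daily deaths with a designed heat effect above 23 degC that is strongest in
the lowest-SES tercile, truncated-Gaussian ages, and AR(1)+seasonal weather.
"""
import dylld as d

config = d.SimulationConfig(n_years=6, seed=42)
weather = d.generate_temperature_series(config, 6 * 92)
table = d.generate_life_table(config.max_age, config.sex_gap_years)
deaths, truth = d.generate_deaths(config, weather, table)

print(f"summers simulated:        {config.n_years}")
print(f"deaths per summer:        {len(deaths) / config.n_years:.0f}")
print(f"mean daily temperature:   {weather['temperature_c'].mean():.2f} degC "
      f"(SD {weather['temperature_c'].std(ddof=1):.2f})")
print(f"mean YLL per death:       {truth.mean_yll_per_death:.1f} years")
print(f"designed heat threshold:  {config.true_threshold_c} degC")
print(f"designed log-RR gradient: {config.group_heat_log_rr} (low/mid/high SES)")
# The tercile gradient means a hot day (say +3 degC above threshold) raises
# death counts by ~31% in the most deprived areas but only ~6% in the most
# advantaged ones -- that asymmetry is what the DYLLD index measures.
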