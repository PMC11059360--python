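"""Substrate residency from simulated binding traces.

Generates three replicate distance traces per kinetic preset (the
desk-scale analogue of three 1-microsecond MD runs), applies the
3.5-8 Angstrom bound-distance window, and aggregates the replicate
occupancies the way trajectory studies report them.
"""

from slc26kit import residency, synthetic

for preset in (synthetic.PRESET_CL, synthetic.PRESET_SO4, synthetic.PRESET_OX):
    traces = [synthetic.simulate_binding_trace(preset, n_frames=100_000, seed=s)
              for s in (1, 2, 3)]
    stat = residency.aggregate_replicates(traces)
    print(f"{preset.name:10s}  stationary target {preset.stationary_bound:5.2f}  "
          f"estimated {stat.as_percent()}  "
          f"(per replicate: {[round(f, 3) for f in stat.per_replicate_fractions]})")

# The chloride-like preset hovers near 82% occupancy, the absorbing
# sulfate-like preset is bound 100% of the time, and the oxalate-like
# preset near 65% - the relative residence ranking SO4 > Cl > oxalate.

trace = synthetic.simulate_binding_trace(synthetic.PRESET_CL, 100_000, seed=1)
overlap = residency.site_intersection_fraction(trace)
print(f"\nfraction of frames where a bound chloride overlaps the sulfate site "
      f"(6-8 A band): {overlap:.3f}")
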