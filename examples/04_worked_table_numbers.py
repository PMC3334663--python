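"""Worked-number checks against the published summary tables.

Recomputes derived columns of the published tables from their printed
inputs: percent differences from group means, Tb.N from BV/TV and Tb.Th,
the total-compartment plate thickness from the medial/lateral values, VOI
heights from the scan geometry, and the scoring-scale extremes.
"""

import osteoct as o
from osteoct import reference_tables as rt

trab = rt.trabecular_summary().set_index(["parameter", "compartment", "week"])

print("percent differences (MIA vs control) recomputed from group means:")
for param, comp, week in [("BV", "total", 2), ("BV", "lateral", 2),
                          ("BV", "medial", 10), ("Tb.Sp", "total", 2),
                          ("Tb.Sp", "lateral", 10)]:
    row = trab.loc[(param, comp, week)]
    d = o.percent_difference(row["mia_mean"], row["control_mean"])
    print(f"  {param:6} {comp:8} week {week:>2}: "
          f"{row['mia_mean']:6.1f} vs {row['control_mean']:6.1f} "
          f"-> %d = {d:+6.1f}")

bvtv = trab.loc[("BV/TV", "medial", 2), "mia_mean"]
tbth = trab.loc[("Tb.Th", "medial", 2), "mia_mean"]
print(f"\nTb.N = (BV/TV)/Tb.Th = ({bvtv}%)/({tbth} μm) "
      f"= {o.trabecular_number(bvtv, tbth):.1f} /mm")

plate = rt.plate_summary().set_index(["compartment", "week"])
med = plate.loc[("medial", 6), "mia_mean"]
lat = plate.loc[("lateral", 6), "mia_mean"]
print(f"total Pl.Th (6-week MIA) = mean({med}, {lat}) "
      f"= {o.total_compartment(med, lat):.0f} μm")

print(f"\nVOI height: 52 slices x 8.7 μm = "
      f"{o.voi_height(52, 8.7):.2f} mm")
print(f"full stack: 1800 slices x 8.7 μm = "
      f"{o.voi_height(1800, 8.7):.0f} mm")
print(f"OARSI scale maximum: grade 6 x stage 4 = {o.oarsi(6, 4).score}")
n, total = rt.CYST_COUNT
print(f"subchondral cyst prevalence: {n}/{total} = {100 * n / total:.0f} %")
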