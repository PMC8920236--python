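"""Physical conversions: conductivity to salinity, flowmeter volume, CPUE,
carbon biomass, and counting-design precision."""

import numpy as np

import plankweave as pw

# PSS-78: standard seawater defining point and a fresh-water reading
print("42.914 mS/cm @ 15 C (in situ) ->",
      round(pw.ec_to_salinity(42.914, 15.0, input_type="in_situ"), 3))
print("0.2 mS/cm  @ 22 C (specific conductance) ->",
      round(float(pw.ec_to_salinity(0.2, 22.0)), 4))

# volume of a 10-minute tow from flowmeter counts
vol = pw.flowmeter_volume(10000, 0.0269, 0.0616)
print(f"flowmeter volume: {vol:.2f} m^3")

# CPUE from a 25% subsample of the catch
print("CPUE:", pw.compute_cpue(100, 0.25, vol), "individuals/m^3")

# counting-design math for the 200-400/ml, 5-20 aliquot protocol
design = pw.CountingDesign(target_concentration_range=(200, 400),
                           subsample_count_range=(5, 20))
print("organisms counted per sample:", pw.count_bounds(design))
print("precision at 400 organisms: +/-", pw.poisson_precision_percent(400), "%")

# carbon biomass with literature conversion values; gaps stay missing
import pandas as pd

catch = pd.DataFrame({
    "Taxlifestage": ["Tortanus Adult", "Synchaeta Adult"],
    "CPUE": [12.0, 40.0],
})
table = [pw.BiomassEntry("Tortanus Adult", 2.0, "literature")]
print(pw.biomass(catch, table)[["Taxlifestage", "CPUE", "BPUE"]].to_string(index=False))
# BPUE is ug C per m^3; the rotifer has no literature value, so its
# biomass is missing rather than zero.
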