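"""Generate a synthetic multi-survey program and integrate it.

Three surveys count the same copepod community at different taxonomic
resolutions and publish in different dialects (long records, a coded wide
table).  We standardize them to one long schema, apply the zero-vs-missing
correction, and split into an environment table and a catch table keyed by
SampleID.
"""

import tempfile
from pathlib import Path

import pandas as pd

import plankweave as pw
from plankweave.standardize import bind_and_split, read_survey, zeros_to_na

cfg = pw.make_resolution_scenario("tortanus", seed=1)
result = pw.simulate_program(cfg)

with tempfile.TemporaryDirectory() as tmp:
    result.write(tmp)
    frames = [
        read_survey(Path(tmp) / f"survey_{name}.csv", scfg)
        for name, scfg in result.survey_configs.items()
    ]

bound = pd.concat(frames, ignore_index=True)
corrected, unlisted = zeros_to_na(bound, result.taxa_lists)
env, catch = bind_and_split(corrected)

print(f"surveys: {sorted(env['Source'].unique())}")
print(f"{len(env)} samples, {len(catch)} catch records, {len(unlisted)} unlisted")
print(catch.head(4).to_string(index=False))
# Each catch row is one taxon/life stage in one sample, CPUE in
# individuals per cubic meter; the environment table holds one row per
# sample with volume, station and water-quality fields (NA when a survey
# does not measure them).
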