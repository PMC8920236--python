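"""Shared fixtures: a small copepod taxonomy, per-survey taxa lists, and a
helper running the standardize stage on simulator output in memory."""

import sys
from pathlib import Path

import pandas as pd
import pytest

import plankweave as pw
from plankweave.standardize import bind_and_split, read_survey, zeros_to_na

# make the independent reference implementations importable
sys.path.insert(0, str(Path(__file__).parent / "reference"))


@pytest.fixture(scope="session")
def tortanus_tree() -> pw.TaxonomyTree:
    """Genus Tortanus with three species, a second genus, and a lone phylum."""
    N = pw.TaxonNode.from_ladder
    ladder = {"phylum": "Arthropoda", "class": "Copepoda", "order": "Calanoida", "family": "Tortanidae"}
    return pw.build_taxonomy(
        [
            N("Tortanus discaudatus", "Species", **ladder, genus="Tortanus",
              species="Tortanus discaudatus"),
            N("Tortanus dextrilobatus", "Species", **ladder, genus="Tortanus",
              species="Tortanus dextrilobatus"),
            N("Tortanus", "Genus", **ladder, genus="Tortanus"),
            N("Acartiella sinensis", "Species", phylum="Arthropoda", **{"class": "Copepoda"},
              order="Calanoida", family="Acartiidae", genus="Acartiella",
              species="Acartiella sinensis"),
            N("Annelida", "Phylum", phylum="Annelida"),
        ]
    )


@pytest.fixture(scope="session")
def survey_lists() -> pw.TaxaList:
    """One splitter survey (species + bin) and two lumpers (bin only)."""
    E = pw.TaxaListEntry
    entries = [
        E("20mm", "Meso", "Tortanus discaudatus", "Adult", 1995),
        E("20mm", "Meso", "Tortanus dextrilobatus", "Adult", 1995),
        E("20mm", "Meso", "Tortanus", "Adult", 1995),
        E("20mm", "Meso", "Acartiella sinensis", "Adult", 1995),
        E("20mm", "Meso", "Annelida", "Adult", 1995),
        E("EMP", "Meso", "Tortanus", "Adult", 1972),
        E("EMP", "Meso", "Acartiella sinensis", "Adult", 1972),
        E("FMWT", "Meso", "Tortanus", "Adult", 2005),
        E("FMWT", "Meso", "Acartiella sinensis", "Adult", 2005),
    ]
    return pw.TaxaList(entries)


def run_standardize(result: pw.SimulationResult, tmp_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """simulate_program output -> (environment, catch-with-sample-metadata)."""
    frames = []
    result.write(tmp_path)
    for name, cfg in result.survey_configs.items():
        frames.append(read_survey(tmp_path / f"survey_{name}.csv", cfg))
    bound = pd.concat(frames, ignore_index=True)
    corrected, _ = zeros_to_na(bound, result.taxa_lists)
    env, catch = bind_and_split(corrected)
    catch = catch.merge(env[["SampleID", "Source", "SizeClass", "Year"]], on="SampleID")
    return env, catch
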