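"""Synthetic multi-survey zooplankton program generator.

Emulates the structure of a set of long-term monitoring programs — fixed
stations sampled monthly or fortnightly, per-survey taxa lists that differ
in resolution and change through time, species introductions, net volumes
from flowmeters, and Poisson counting of diluted subsamples — with a known
ground truth, so every stage of the integration pipeline is testable
without any real download.

The abundance model is deliberately minimal: each leaf taxon has a
lognormal latent density (individuals per m^3) with an optional seasonal
modulation; organisms are binned by each survey into the lowest active
category covering their taxon (the "spp." bin semantics of the real
surveys); the enumerated count of a category is
Poisson(density x volume x subsample fraction x gear efficiency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import ConfigError, InputError
from .standardize import SurveyConfig, TaxonCode, write_table
from .taxonomy import (
    RANKS,
    Rank,
    TaxaList,
    TaxaListEntry,
    TaxonNode,
    TaxonomyTree,
    build_taxonomy,
)

__all__ = [
    "TaxonSpec",
    "ListEntrySpec",
    "SurveySpec",
    "SimConfig",
    "SimulationResult",
    "simulate_program",
    "make_resolution_scenario",
    "SCENARIOS",
]


class TaxonSpec(BaseModel):
    """One leaf taxon of the simulated community."""

    taxname: str
    lifestage: str = "Adult"
    mean_density: float = Field(gt=0)   # lognormal mean, individuals/m^3
    sigma: float = Field(default=0.5, ge=0)  # log-space SD
    seasonal_amplitude: float = Field(default=0.0, ge=0, le=1)
    intro_year: Optional[int] = None
    carbon_mass_micrograms: Optional[float] = None


class ListEntrySpec(BaseModel):
    """A counted category on one survey's taxa list."""

    taxname: str
    lifestage: str = "Adult"
    start_year: int
    end_year: Optional[int] = None
    restart_year: Optional[int] = None


class SurveySpec(BaseModel):
    """One monitoring program."""

    name: str
    size_class: str = "Meso"
    stations: list[str]
    months: list[int] = Field(default_factory=lambda: list(range(1, 13)))
    frequency: int = Field(default=1, ge=1, le=2)  # samples per station-month
    taxa_list: list[ListEntrySpec]
    gear_efficiency: dict[str, float] = Field(default_factory=dict)  # leaf taxname -> [0,1]
    dialect: str = "long"            # "long" or "wide"
    cpue_per_liter: bool = False     # report CPUE in individuals/L
    code_prefix: Optional[str] = None  # emit species codes instead of names

    def efficiency(self, taxname: str) -> float:
        return self.gear_efficiency.get(taxname, 1.0)


class SimConfig(BaseModel):
    """Full description of a simulated multi-survey program."""

    seed: int = 0
    start_year: int = 2000
    end_year: int = 2010
    surveys: list[SurveySpec]
    taxonomy: list[dict]             # TaxonNode ladders (taxname, level, ranks)
    taxa: list[TaxonSpec]
    volume_mean: float = Field(default=16.0, gt=0)   # m^3, typical 10-min tow
    volume_sigma: float = Field(default=0.15, ge=0)  # log-space SD
    subsample_fraction: float = Field(default=0.06, gt=0, le=1)

    def years(self) -> range:
        if self.start_year > self.end_year:
            raise ConfigError("start_year > end_year")
        return range(self.start_year, self.end_year + 1)


@dataclass
class SimulationResult:
    """Everything the downstream pipeline and the tests need."""

    tables: dict[str, pd.DataFrame]          # survey name -> dialect table
    survey_configs: dict[str, SurveyConfig]  # descriptors for read_survey
    taxa_lists: TaxaList
    tree: TaxonomyTree
    truth: pd.DataFrame                      # per-taxon mean densities etc.
    efficiencies: pd.DataFrame               # survey x taxon efficiency

    def write(self, out_dir) -> list[Path]:
        from .taxonomy import write_taxa_lists_csv, write_taxonomy_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables.items():
            p = out / f"survey_{name}.csv"
            write_table(df, p)
            written.append(p)
        for name, cfg in self.survey_configs.items():
            p = out / f"survey_{name}.json"
            p.write_text(cfg.model_dump_json(indent=2))
            written.append(p)
        p = out / "taxa_lists.csv"
        write_taxa_lists_csv(self.taxa_lists, p)
        written.append(p)
        p = out / "taxonomy.csv"
        write_taxonomy_csv(self.tree, p)
        written.append(p)
        p = out / "truth.csv"
        self.truth.to_csv(p, index=False, na_rep="NA")
        written.append(p)
        p = out / "efficiencies.csv"
        self.efficiencies.to_csv(p, index=False, na_rep="NA")
        written.append(p)
        return written


def _build_tree(config: SimConfig) -> TaxonomyTree:
    nodes = []
    for spec in config.taxonomy:
        ranks = {k: v for k, v in spec.items() if k in {r.name.lower() for r in RANKS}}
        nodes.append(TaxonNode.from_ladder(spec["taxname"], spec["level"], **ranks))
    return build_taxonomy(nodes)


def _seasonal(amplitude: float, month: int) -> float:
    # mean-one annual cycle peaking in June
    return 1.0 + amplitude * math.sin(2.0 * math.pi * (month - 3) / 12.0)


def simulate_program(config: SimConfig) -> SimulationResult:
    """Run the generator; deterministic for a fixed seed.

    Censoring: a record exists only for categories active on the survey's
    list that year.  Introduced taxa contribute zero density before their
    introduction year (their categories, when active, record 0 — the
    convention the real surveys used).  Organisms of a leaf taxon land in
    the lowest active category covering it.
    """
    tree = _build_tree(config)
    taxa = {t.taxname: t for t in config.taxa}
    entries = [
        TaxaListEntry(
            survey=s.name, size_class=s.size_class, taxname=le.taxname,
            lifestage=le.lifestage, start_year=le.start_year,
            end_year=le.end_year, restart_year=le.restart_year,
            intro_year=_intro_for_category(le, taxa, tree),
        )
        for s in config.surveys
        for le in s.taxa_list
    ]
    lists = TaxaList(entries)

    root = np.random.SeedSequence(config.seed)
    streams = {s.name: np.random.default_rng(child)
               for s, child in zip(config.surveys, root.spawn(len(config.surveys)))}

    frames = {}
    for survey in config.surveys:
        rng = streams[survey.name]
        rows = []
        for year in config.years():
            for month in survey.months:
                for occurrence in range(survey.frequency):
                    day = 1 + 14 * occurrence
                    dt = pd.Timestamp(year=year, month=month, day=day, hour=10)
                    for station in survey.stations:
                        rows.extend(
                            _sample(rng, survey, config, lists, tree, taxa, dt, station)
                        )
        frames[survey.name] = pd.DataFrame(rows)

    tables, survey_configs = {}, {}
    for survey in config.surveys:
        tables[survey.name], survey_configs[survey.name] = _to_dialect(frames[survey.name], survey)

    truth = pd.DataFrame(
        [
            {
                "Taxname": t.taxname, "Lifestage": t.lifestage,
                "MeanDensity": t.mean_density, "Sigma": t.sigma,
                "SeasonalAmplitude": t.seasonal_amplitude, "Intro": t.intro_year,
            }
            for t in config.taxa
        ]
    )
    efficiencies = pd.DataFrame(
        [
            {"Survey": s.name, "Taxname": t.taxname, "Efficiency": s.efficiency(t.taxname)}
            for s in config.surveys
            for t in config.taxa
        ]
    )
    return SimulationResult(
        tables=tables, survey_configs=survey_configs, taxa_lists=lists,
        tree=tree, truth=truth, efficiencies=efficiencies,
    )


def _intro_for_category(le: ListEntrySpec, taxa: dict[str, TaxonSpec], tree: TaxonomyTree) -> Optional[int]:
    spec = taxa.get(le.taxname)
    if spec is not None:
        return spec.intro_year
    # a bin inherits an introduction year only if every member is introduced
    members = [t for t in taxa.values()
               if le.taxname in tree and t.taxname in tree and tree.is_descendant(t.taxname, le.taxname)]
    intros = [t.intro_year for t in members]
    if members and all(i is not None for i in intros):
        return min(intros)
    return None


def _sample(rng, survey: SurveySpec, config: SimConfig, lists: TaxaList,
            tree: TaxonomyTree, taxa: dict[str, TaxonSpec], dt: pd.Timestamp, station: str):
    year, month = dt.year, dt.month
    volume = float(rng.lognormal(math.log(config.volume_mean) - 0.5 * config.volume_sigma ** 2,
                                 config.volume_sigma))
    frac = config.subsample_fraction

    # latent leaf densities for this sample
    lam_by_category: dict[tuple[str, str], float] = {}
    active: dict[tuple[str, str], bool] = {}
    for t in taxa.values():
        # category the survey files this leaf under, this year
        cat = _category_for_leaf(t, survey, lists, tree, year)
        if cat is None:
            continue
        active.setdefault(cat, True)
        if t.intro_year is not None and year < t.intro_year:
            continue  # truly absent before introduction
        mu = math.log(t.mean_density) - 0.5 * t.sigma ** 2
        density = float(rng.lognormal(mu, t.sigma)) * _seasonal(t.seasonal_amplitude, month)
        lam_by_category[cat] = lam_by_category.get(cat, 0.0) + density * survey.efficiency(t.taxname)

    rows = []
    for (name, ls) in sorted(active):
        lam = lam_by_category.get((name, ls), 0.0)
        count = int(rng.poisson(lam * volume * frac))
        rows.append(
            {
                "Source": survey.name, "Station": station, "Datetime": dt,
                "SizeClass": survey.size_class, "Volume": volume,
                "Taxname": name, "Lifestage": ls,
                "CPUE": count / frac / volume,
            }
        )
    return rows


def _category_for_leaf(t: TaxonSpec, survey: SurveySpec, lists: TaxaList,
                       tree: TaxonomyTree, year: int) -> Optional[tuple[str, str]]:
    node = tree.node(t.taxname)
    for r in range(node.level, Rank.Phylum - 1, -1):
        anc = node.names[Rank(r)]
        if lists.active(survey.name, survey.size_class, anc, t.lifestage, year):
            return (anc, t.lifestage)
    return None


def _to_dialect(df: pd.DataFrame, survey: SurveySpec) -> tuple[pd.DataFrame, SurveyConfig]:
    """Render the standard long frame in the survey's published dialect."""
    cfg = SurveyConfig(name=survey.name, size_class=survey.size_class)
    out = df.copy()
    if out.empty:
        return out, cfg
    if survey.cpue_per_liter:
        out["CPUE"] = out["CPUE"] / 1000.0
        cfg.unit_factors = {"CPUE": 1000.0}

    if survey.code_prefix is not None:
        cats = sorted(set(zip(out["Taxname"], out["Lifestage"])))
        codes = {cat: f"{survey.code_prefix}{i:03d}" for i, cat in enumerate(cats)}
        cfg.species_codes = {
            code: TaxonCode(taxname=name, lifestage=ls) for (name, ls), code in codes.items()
        }
        out["SpeciesCode"] = [codes[c] for c in zip(out["Taxname"], out["Lifestage"])]
        out = out.drop(columns=["Taxname", "Lifestage"])
        cfg.code_column = "SpeciesCode"

    if survey.dialect == "wide":
        if survey.code_prefix is None:
            raise ConfigError("wide dialect requires code_prefix")
        id_cols = ["Source", "Station", "Datetime", "SizeClass", "Volume"]
        out = out.pivot_table(index=id_cols, columns="SpeciesCode",
                              values="CPUE", aggfunc="first").reset_index()
        out.columns.name = None
        cfg.fmt = "wide"
        cfg.columns = {c: c for c in id_cols}
    elif survey.dialect != "long":
        raise ConfigError(f"unknown dialect: {survey.dialect!r}")
    return out, cfg


# ---------------------------------------------------------------------------
# canned scenarios mirroring the classic harmonization situations

_TORTANUS_TAXONOMY = [
    {"taxname": "Tortanus discaudatus", "level": "Species", "phylum": "Arthropoda",
     "class": "Copepoda", "order": "Calanoida", "family": "Tortanidae",
     "genus": "Tortanus", "species": "Tortanus discaudatus"},
    {"taxname": "Tortanus dextrilobatus", "level": "Species", "phylum": "Arthropoda",
     "class": "Copepoda", "order": "Calanoida", "family": "Tortanidae",
     "genus": "Tortanus", "species": "Tortanus dextrilobatus"},
    {"taxname": "Tortanus sp. C", "level": "Species", "phylum": "Arthropoda",
     "class": "Copepoda", "order": "Calanoida", "family": "Tortanidae",
     "genus": "Tortanus", "species": "Tortanus sp. C"},
    {"taxname": "Tortanus", "level": "Genus", "phylum": "Arthropoda",
     "class": "Copepoda", "order": "Calanoida", "family": "Tortanidae",
     "genus": "Tortanus"},
    {"taxname": "Acartiella sinensis", "level": "Species", "phylum": "Arthropoda",
     "class": "Copepoda", "order": "Calanoida", "family": "Acartiidae",
     "genus": "Acartiella", "species": "Acartiella sinensis"},
    {"taxname": "Annelida", "level": "Phylum", "phylum": "Annelida"},
]

_BASE_TAXA = [
    {"taxname": "Tortanus discaudatus", "mean_density": 40.0, "sigma": 0.4},
    {"taxname": "Tortanus dextrilobatus", "mean_density": 25.0, "sigma": 0.4},
    {"taxname": "Tortanus sp. C", "mean_density": 5.0, "sigma": 0.4},
    {"taxname": "Acartiella sinensis", "mean_density": 80.0, "sigma": 0.4},
]


def _survey(name, stations, taxa_list, **kw) -> dict:
    return {
        "name": name, "size_class": "Meso", "stations": stations,
        "months": [4, 5, 6, 7], "taxa_list": taxa_list, **kw,
    }


def make_resolution_scenario(kind: str, seed: int = 0) -> SimConfig:
    """Canned configurations reproducing the classic worked situations.

    ``tortanus``   — one survey splits a genus into species + residual bin,
                     two others lump the whole genus.
    ``orphan``     — a phylum counted by a single survey with no shared
                     higher category: dropped in community mode.
    ``time-change``— a survey promotes a genus to species-level counting
                     mid-series.
    ``intro-lag``  — an introduced species enters the counts one year after
                     its introduction.
    """
    if kind not in SCENARIOS:
        raise InputError(f"unknown scenario {kind!r}; choose from {sorted(SCENARIOS)}")
    return SCENARIOS[kind](seed)


def _scenario_tortanus(seed: int) -> SimConfig:
    splitter = [
        {"taxname": "Tortanus discaudatus", "start_year": 1995},
        {"taxname": "Tortanus dextrilobatus", "start_year": 1995},
        {"taxname": "Tortanus", "start_year": 1995},
        {"taxname": "Acartiella sinensis", "start_year": 1995},
    ]
    lumper = [
        {"taxname": "Tortanus", "start_year": 1972},
        {"taxname": "Acartiella sinensis", "start_year": 1972},
    ]
    return SimConfig(
        seed=seed, start_year=2008, end_year=2010,
        taxonomy=_TORTANUS_TAXONOMY,
        taxa=_BASE_TAXA,
        surveys=[
            _survey("TWENTYMM", ["701", "704"], splitter),
            _survey("EMPLIKE", ["NZ028", "NZ054"], lumper),
            _survey("FMWTLIKE", ["507"], lumper, dialect="wide", code_prefix="Z"),
        ],
    )


def _scenario_orphan(seed: int) -> SimConfig:
    cfg = _scenario_tortanus(seed)
    cfg.taxa.append(TaxonSpec(taxname="Annelida", mean_density=2.0, sigma=0.3))
    cfg.surveys[0].taxa_list.append(ListEntrySpec(taxname="Annelida", start_year=1995))
    return cfg


def _scenario_time_change(seed: int) -> SimConfig:
    cfg = _scenario_tortanus(seed)
    cfg.start_year, cfg.end_year = 1996, 2010
    # the splitter only separated species from 2000; before that, bin only
    cfg.surveys[0].taxa_list = [
        ListEntrySpec(taxname="Tortanus discaudatus", start_year=2000),
        ListEntrySpec(taxname="Tortanus dextrilobatus", start_year=2000),
        ListEntrySpec(taxname="Tortanus", start_year=1995),
        ListEntrySpec(taxname="Acartiella sinensis", start_year=1995),
    ]
    return cfg


def _scenario_intro_lag(seed: int) -> SimConfig:
    cfg = _scenario_tortanus(seed)
    cfg.start_year, cfg.end_year = 1990, 2010
    cfg.taxa.append(
        TaxonSpec(taxname="Tortanus dextrilobatus2", mean_density=10.0, sigma=0.3, intro_year=1993)
    )
    # modeled as its own species so the introduction drives its category
    cfg.taxonomy.append(
        {"taxname": "Tortanus dextrilobatus2", "level": "Species", "phylum": "Arthropoda",
         "class": "Copepoda", "order": "Calanoida", "family": "Tortanidae",
         "genus": "Tortanus", "species": "Tortanus dextrilobatus2"}
    )
    for s in cfg.surveys:
        s.taxa_list = [le for le in s.taxa_list]
    cfg.surveys[0].taxa_list.append(
        ListEntrySpec(taxname="Tortanus dextrilobatus2", start_year=1994)
    )
    return cfg


SCENARIOS = {
    "tortanus": _scenario_tortanus,
    "orphan": _scenario_orphan,
    "time-change": _scenario_time_change,
    "intro-lag": _scenario_intro_lag,
}


def make_calibration_config(seed: int = 0, *, orphan: bool = False,
                            years: tuple[int, int] = (1998, 2010)) -> SimConfig:
    """A ~1,500-sample two-survey program for quantitative validation.

    Two mesozooplankton surveys sampling 5 fixed stations monthly over the
    year range (2 x 5 x 12 x n_years samples), one publishing long records
    and one a coded wide table.  One survey splits the genus while the
    other lumps it, so community harmonization is exercised; the moderate
    lognormal spread (sigma 0.25) keeps the Monte-Carlo error of a mean
    over ~750 samples per survey near 1%, appropriate for recovery checks
    at the few-percent level.  ``orphan=True`` adds a taxon counted by a
    single survey, which community mode must drop.
    """
    splitter = [
        {"taxname": "Tortanus discaudatus", "start_year": 1972},
        {"taxname": "Tortanus dextrilobatus", "start_year": 1972},
        {"taxname": "Tortanus", "start_year": 1972},
        {"taxname": "Acartiella sinensis", "start_year": 1972},
    ]
    lumper = [
        {"taxname": "Tortanus", "start_year": 1972},
        {"taxname": "Acartiella sinensis", "start_year": 1972},
    ]
    taxa = [
        {"taxname": "Tortanus discaudatus", "mean_density": 40.0, "sigma": 0.25},
        {"taxname": "Tortanus dextrilobatus", "mean_density": 25.0, "sigma": 0.25},
        {"taxname": "Tortanus sp. C", "mean_density": 5.0, "sigma": 0.25},
        {"taxname": "Acartiella sinensis", "mean_density": 80.0, "sigma": 0.25},
    ]
    taxonomy = [dict(t) for t in _TORTANUS_TAXONOMY]
    surveys = [
        _survey("SPLITTER", [f"S{i}" for i in range(1, 6)], splitter,
                months=list(range(1, 13))),
        _survey("LUMPER", [f"L{i}" for i in range(1, 6)], lumper,
                months=list(range(1, 13)), dialect="wide", code_prefix="Z"),
    ]
    if orphan:
        taxa.append({"taxname": "Annelida", "mean_density": 3.0, "sigma": 0.25})
        surveys[0]["taxa_list"] = surveys[0]["taxa_list"] + [
            {"taxname": "Annelida", "start_year": 1972}
        ]
    return SimConfig(
        seed=seed, start_year=years[0], end_year=years[1],
        taxonomy=taxonomy, taxa=taxa, surveys=surveys,
    )


def make_gear_comparison_config(seed: int = 0) -> SimConfig:
    """Two gears sampling the same stations and dates with planted efficiencies.

    The "net" gear catches Limnoithona-like taxa at 20% efficiency while the
    "pump" misses a large calanoid at 20%; one taxon is caught equally.  The
    planted truth lets matched-sample comparisons be checked end to end.
    """
    taxonomy = [dict(t) for t in _TORTANUS_TAXONOMY] + [
        {"taxname": "Limnoithona tetraspina", "level": "Species", "phylum": "Arthropoda",
         "class": "Copepoda", "order": "Cyclopoida", "family": "Oithonidae",
         "genus": "Limnoithona", "species": "Limnoithona tetraspina"},
        {"taxname": "Synchaeta bicornis", "level": "Species", "phylum": "Rotifera",
         "class": "Monogononta", "order": "Flosculariaceae", "family": "Synchaetidae",
         "genus": "Synchaeta", "species": "Synchaeta bicornis"},
    ]
    taxa = [
        {"taxname": "Limnoithona tetraspina", "mean_density": 200.0, "sigma": 0.25},
        {"taxname": "Synchaeta bicornis", "mean_density": 120.0, "sigma": 0.25},
        {"taxname": "Acartiella sinensis", "mean_density": 60.0, "sigma": 0.25},
        {"taxname": "Tortanus discaudatus", "mean_density": 30.0, "sigma": 0.25},
    ]
    shared_list = [
        {"taxname": "Limnoithona tetraspina", "start_year": 1972},
        {"taxname": "Synchaeta bicornis", "start_year": 1972},
        {"taxname": "Acartiella sinensis", "start_year": 1972},
        {"taxname": "Tortanus discaudatus", "start_year": 1972},
    ]
    stations = ["NZ028", "NZ054", "NZ060"]
    net = _survey("NET", stations, shared_list, months=list(range(1, 13)))
    net["size_class"] = "Meso"
    net["gear_efficiency"] = {"Limnoithona tetraspina": 0.2, "Synchaeta bicornis": 0.2}
    pump = _survey("PUMP", stations, shared_list, months=list(range(1, 13)))
    pump["size_class"] = "Micro"
    pump["gear_efficiency"] = {"Tortanus discaudatus": 0.2}
    return SimConfig(
        seed=seed, start_year=2006, end_year=2010,
        taxonomy=taxonomy, taxa=taxa, surveys=[net, pump],
    )
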