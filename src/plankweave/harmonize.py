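"""Taxonomic-resolution harmonization across surveys and through time.

Surveys count the same organisms at different taxonomic resolutions: one
program separates *Tortanus discaudatus* and *Tortanus dextrilobatus* plus
a residual *Tortanus* "spp." bin, while others lump the whole genus into
the bin.  A naive multi-survey analysis would read that methodological
difference as a biological pattern.

Two resolutions are implemented:

* **community mode** — every category counted by all surveys is kept; any
  category not counted everywhere is summed (within each sample) up to its
  lowest ancestor whose "spp." bin is on every survey's list, and the
  summed constituents are removed so nothing is counted twice.  Categories
  with no such ancestor (orphans) are dropped.  The output is exclusive
  and safe for community-level analysis.
* **taxa-of-interest mode** — for requested taxa, an "All X" group sums
  every category in X's clade while retaining the constituents.  Organisms
  are deliberately double-counted, so the output is flagged non-exclusive.

A temporal correction reduces each survey's list to its coarsest state
over a year range (a category survives only if counted every year), with a
time-lag exception so recently introduced species that entered the counts
shortly after arriving are not discarded.  A conservation validator checks
that harmonization only ever moves catch between categories, never
creates or destroys it.

Throughout, the "spp."/higher-rank bins are *other* categories: within a
survey they exclude the lower taxa that survey counts separately.  Because
kept (all-survey) categories are excluded from the bins of every survey
consistently, summing bin + rolled-up constituents yields groups that are
comparable across surveys without double counting.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InputError, PlanMismatchError
from .taxonomy import NOT_COUNTED, RANKS, Rank, TaxaList, TaxaListEntry, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "Action",
    "PlanEntry",
    "HarmonizationPlan",
    "plan_community",
    "apply_plan",
    "plan_taxa_of_interest",
    "time_correct",
    "ConservationReport",
    "validate_conservation",
    "write_plan_csv",
    "build_community_table",
]


class Action(enum.Enum):
    KEEP = "KEEP"
    SUM_TO = "SUM_TO"
    DROP = "DROP"


@dataclass(frozen=True)
class PlanEntry:
    """Disposition of one (survey, taxon/life-stage) input category."""

    survey: str
    taxname: str
    lifestage: str
    action: Action
    group: Optional[str] = None        # output group taxname (SUM_TO)
    group_level: Optional[Rank] = None
    reason: str = ""


@dataclass
class HarmonizationPlan:
    """Explicit, auditable mapping from input categories to output groups.

    ``groups`` maps an output key ``(group taxname, lifestage)`` to the
    registry of absorbed input categories per survey.  ``exclusive`` is
    True for community mode (each record contributes to at most one output
    row) and False for taxa-of-interest mode.
    """

    size_class: str
    entries: list[PlanEntry] = field(default_factory=list)
    groups: dict[tuple[str, str], dict[str, list[str]]] = field(default_factory=dict)
    group_levels: dict[tuple[str, str], Rank] = field(default_factory=dict)
    orphans: list[PlanEntry] = field(default_factory=list)
    exclusive: bool = True
    surveys: tuple[str, ...] = ()

    def action_for(self, survey: str, taxname: str, lifestage: str) -> Optional[PlanEntry]:
        return self._index().get((survey, taxname, lifestage))

    def _index(self):
        if not hasattr(self, "_idx") or len(self._idx) != len(self.entries):
            self._idx = {(e.survey, e.taxname, e.lifestage): e for e in self.entries}
        return self._idx


def plan_community(
    lists: TaxaList,
    tree: TaxonomyTree,
    surveys: Sequence[str],
    size_class: str,
    year_range: Optional[tuple[int, int]] = None,
) -> HarmonizationPlan:
    """Build the exclusive least-common-resolution plan (community mode).

    For every category not counted by all surveys, the target is the
    lowest rank whose ancestor bin (same life stage) is on every survey's
    list; constituents of a formed group — including the bin itself — map
    SUM_TO that group, categories counted everywhere and absorbed by no
    group map KEEP, and categories with no all-survey ancestor are DROPped
    as orphans.  Deterministic: output order is sorted.
    """
    surveys = list(surveys)
    if not surveys:
        raise InputError("community plan requires at least one survey")
    years = None if year_range is None else range(year_range[0], year_range[1] + 1)
    if years is not None and len(years) == 0:
        raise InputError("inverted year range")

    cats_by_survey = {s: lists.categories(s, size_class, years) for s in surveys}
    universe = sorted(set().union(*cats_by_survey.values()))
    universal = {c for c in universe if all(c in cats_by_survey[s] for s in surveys)}

    # pass 1: target of every non-universal category
    target_of: dict[tuple[str, str], Optional[tuple[str, Rank]]] = {}
    for name, ls in universe:
        if (name, ls) in universal:
            continue
        node = tree.node(name)
        target = None
        for r in range(node.level, Rank.Phylum - 1, -1):
            anc = node.names[Rank(r)]
            if (anc, ls) in universal:
                target = (anc, Rank(r))
                break
        target_of[(name, ls)] = target
    group_keys = {(anc, ls): rank for (name, ls), t in target_of.items() if t is not None
                  for anc, rank in [t]}

    plan = HarmonizationPlan(size_class=size_class, exclusive=True, surveys=tuple(surveys))
    plan.group_levels = dict(group_keys)
    for key in group_keys:
        plan.groups[key] = {s: [] for s in surveys}

    for name, ls in universe:
        is_universal = (name, ls) in universal
        present_in = [s for s in surveys if (name, ls) in cats_by_survey[s]]
        if is_universal and (name, ls) in group_keys:
            # the bin seeding a group is itself a constituent of that group
            for s in present_in:
                e = PlanEntry(s, name, ls, Action.SUM_TO, group=name,
                              group_level=group_keys[(name, ls)], reason="group bin")
                plan.entries.append(e)
                plan.groups[(name, ls)][s].append(name)
            continue
        if is_universal:
            for s in present_in:
                plan.entries.append(PlanEntry(s, name, ls, Action.KEEP))
            continue
        target = target_of[(name, ls)]
        if target is None:
            for s in present_in:
                e = PlanEntry(s, name, ls, Action.DROP,
                              reason="no higher-rank category counted by all surveys")
                plan.entries.append(e)
                plan.orphans.append(e)
            continue
        anc, rank = target
        for s in present_in:
            plan.entries.append(PlanEntry(s, name, ls, Action.SUM_TO, group=anc, group_level=rank))
            plan.groups[(anc, ls)][s].append(name)

    logger.info(
        "plan_community[%s]: %d categories, %d groups, %d orphan entries",
        size_class, len(universe), len(plan.groups), len(plan.orphans),
    )
    return plan


def plan_taxa_of_interest(
    taxa: Sequence[str],
    lists: TaxaList,
    tree: TaxonomyTree,
    surveys: Sequence[str],
    size_class: str,
    year_range: Optional[tuple[int, int]] = None,
) -> HarmonizationPlan:
    """Build the non-exclusive "All X" plan (taxa-of-interest mode).

    Every category stays (KEEP); for each requested taxon X an additional
    summed group "All X" absorbs every counted category in X's clade, per
    survey.  Because constituents are retained alongside the sums, the
    output double-counts organisms and must not feed community analyses.
    """
    surveys = list(surveys)
    if not surveys:
        raise InputError("taxa-of-interest plan requires at least one survey")
    years = None if year_range is None else range(year_range[0], year_range[1] + 1)
    cats_by_survey = {s: lists.categories(s, size_class, years) for s in surveys}
    universe = sorted(set().union(*cats_by_survey.values()))

    plan = HarmonizationPlan(size_class=size_class, exclusive=False, surveys=tuple(surveys))
    for name, ls in universe:
        for s in surveys:
            if (name, ls) in cats_by_survey[s]:
                plan.entries.append(PlanEntry(s, name, ls, Action.KEEP))

    for x in taxa:
        node = tree.node(x)  # raises for unknown taxa
        members = [(name, ls) for name, ls in universe if tree.is_descendant(name, x)]
        if not members:
            warnings.warn(f"requested taxon {x!r} is counted by no survey", stacklevel=2)
            continue
        for ls in sorted({ls for _, ls in members}):
            key = (f"All {x}", ls)
            plan.groups[key] = {
                s: [name for name, l2 in members if l2 == ls and (name, l2) in cats_by_survey[s]]
                for s in surveys
            }
            plan.group_levels[key] = node.level
    return plan


def apply_plan(catch: pd.DataFrame, plan: HarmonizationPlan, *, na_rule: str = "ignore") -> pd.DataFrame:
    """Apply a harmonization plan to a catch table, sample by sample.

    Aggregation happens strictly within SampleID — data from different
    samples are never mixed.  For a summed group, missing constituent
    CPUEs are skipped (``na_rule="ignore"``, default: NA means unknown,
    not zero) unless every constituent in the sample is missing, in which
    case the group is missing; ``na_rule="propagate"`` makes any missing
    constituent poison the group.
    """
    if na_rule not in ("ignore", "propagate"):
        raise InputError(f"unknown na_rule: {na_rule!r}")
    required = {"SampleID", "Source", "Taxname", "Lifestage", "CPUE"}
    missing = required - set(catch.columns)
    if missing:
        raise InputError(f"catch table lacks columns: {sorted(missing)}")

    idx = plan._index()
    keys = list(zip(catch["Source"], catch["Taxname"], catch["Lifestage"]))
    entries = [idx.get(k) for k in keys]
    if plan.exclusive:
        unknown = [k for k, e in zip(keys, entries) if e is None]
        if unknown:
            raise PlanMismatchError(f"records with categories absent from plan: {sorted(set(unknown))[:5]}")
        actions = np.array([e.action.value for e in entries])
        kept = catch[actions == Action.KEEP.value].copy()
        summed_src = catch[actions == Action.SUM_TO.value].copy()
        if len(summed_src):
            summed_src["_group"] = [e.group for e, a in zip(entries, actions) if a == Action.SUM_TO.value]
            summed = _aggregate_groups(summed_src, plan, na_rule)
        else:
            summed = summed_src.head(0)
        out = pd.concat([kept, summed], ignore_index=True)
    else:
        # non-exclusive: all rows retained, plus one summed row per group
        group_frames = []
        for (gname, ls), constituents in plan.groups.items():
            member_names = set().union(*(set(v) for v in constituents.values()))
            sub = catch[(catch["Lifestage"] == ls) & (catch["Taxname"].isin(member_names))].copy()
            if sub.empty:
                continue
            sub["_group"] = gname
            group_frames.append(_aggregate_groups(sub, plan, na_rule, lifestage=ls))
        out = pd.concat([catch.copy()] + group_frames, ignore_index=True)

    out = out.drop(columns=[c for c in ("_group",) if c in out.columns])
    out["Taxlifestage"] = out["Taxname"].str.cat(out["Lifestage"], sep=" ")
    sort_cols = [c for c in ("SampleID", "Taxlifestage") if c in out.columns]
    return out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def _aggregate_groups(sub: pd.DataFrame, plan: HarmonizationPlan, na_rule: str, lifestage=None) -> pd.DataFrame:
    def _combine(s: pd.Series) -> float:
        if na_rule == "propagate" and s.isna().any():
            return np.nan
        if s.notna().sum() == 0:
            return np.nan
        return float(s.sum(skipna=True))

    keys = ["SampleID", "_group", "Lifestage"]
    carried = [c for c in ("Source", "SizeClass") if c in sub.columns]
    agg = {"CPUE": _combine}
    for c in carried:
        agg[c] = "first"
    if "Undersampled" in sub.columns:
        agg["Undersampled"] = "any"
    g = sub.groupby(keys, sort=False).agg(agg).reset_index()
    g = g.rename(columns={"_group": "Taxname"})
    return g


def time_correct(
    lists: TaxaList,
    year_range: tuple[int, int],
    intro_lag: float = 0.0,
) -> TaxaList:
    """Reduce taxa lists to their coarsest state over a year range.

    Within each survey x size class, a category survives only if it was
    counted in *every* year of the range — except introduced taxa first
    counted within ``intro_lag`` years of their introduction, which
    survive from their first counted year onward (``intro_lag=math.inf``
    retains every introduced taxon).
    """
    start, end = year_range
    if start > end:
        raise InputError("inverted year range")
    if intro_lag < 0:
        raise InputError("intro_lag must be >= 0 (or infinite)")
    years = range(start, end + 1)

    by_cat: dict[tuple[str, str, str, str], list[TaxaListEntry]] = {}
    for e in lists:
        by_cat.setdefault((e.survey, e.size_class, e.taxname, e.lifestage), []).append(e)

    kept: list[TaxaListEntry] = []
    for key, entries in by_cat.items():
        counted_all = all(any(e.counted_in(y) for e in entries) for y in years)
        if counted_all:
            kept.extend(entries)
            continue
        intro = next((e.intro_year for e in entries if e.intro_year is not None), None)
        if intro is not None:
            first_counted = min(e.start_year for e in entries)
            if first_counted - intro <= intro_lag:
                kept.extend(entries)
    return TaxaList(kept)


@dataclass
class ConservationReport:
    """Outcome of the total-catch conservation check."""

    totals: pd.DataFrame            # SampleID, RawTotal, HarmonizedTotal, DroppedTotal
    slope: float
    intercept: float
    r_squared: float
    max_abs_delta: float            # after crediting DROPped catch back
    max_rel_delta: float

    @property
    def conserved(self) -> bool:
        return self.max_rel_delta < 1e-9


def validate_conservation(
    raw: pd.DataFrame,
    harmonized: pd.DataFrame,
    plan: HarmonizationPlan,
) -> ConservationReport:
    """Check that harmonization conserves total catch per sample.

    Regresses the harmonized per-sample total CPUE on the raw total
    (OLS with intercept, plain R^2), and verifies exact equality once the
    catch of DROPped categories is excluded from the raw side — dropped
    orphans are the only legitimate source of difference.
    """
    raw_ids = set(raw["SampleID"])
    harm_ids = set(harmonized["SampleID"])
    if raw_ids != harm_ids:
        raise AlignmentError(
            f"sample sets differ: {len(raw_ids - harm_ids)} only in raw, "
            f"{len(harm_ids - raw_ids)} only in harmonized"
        )
    raw_tot = raw.groupby("SampleID")["CPUE"].sum(min_count=1).rename("RawTotal")
    harm_tot = harmonized.groupby("SampleID")["CPUE"].sum(min_count=1).rename("HarmonizedTotal")

    idx = plan._index()
    dropped_mask = [
        (e := idx.get(k)) is not None and e.action is Action.DROP
        for k in zip(raw["Source"], raw["Taxname"], raw["Lifestage"])
    ]
    dropped = raw[np.array(dropped_mask, dtype=bool)] if len(raw) else raw.head(0)
    drop_tot = dropped.groupby("SampleID")["CPUE"].sum(min_count=1).rename("DroppedTotal")

    totals = pd.concat([raw_tot, harm_tot, drop_tot], axis=1).fillna({"DroppedTotal": 0.0})
    x = totals["RawTotal"].fillna(0.0).to_numpy()
    y = totals["HarmonizedTotal"].fillna(0.0).to_numpy()
    if len(totals) >= 2 and np.ptp(x) > 0:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2
    else:
        slope, intercept, r2 = np.nan, np.nan, np.nan

    delta = y - (x - totals["DroppedTotal"].to_numpy())
    scale = np.maximum(np.abs(x), 1.0)
    report = ConservationReport(
        totals=totals.reset_index(),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        max_abs_delta=float(np.max(np.abs(delta))) if len(delta) else 0.0,
        max_rel_delta=float(np.max(np.abs(delta) / scale)) if len(delta) else 0.0,
    )
    if not report.conserved:
        logger.warning("conservation violated: max relative delta %.3g", report.max_rel_delta)
    return report


def write_plan_csv(plan: HarmonizationPlan, path) -> None:
    """Serialize a plan to an auditable CSV (input category -> action -> group)."""
    rows = [
        {
            "Survey": e.survey, "SizeClass": plan.size_class,
            "Taxname": e.taxname, "Lifestage": e.lifestage,
            "Action": e.action.value,
            "Group": e.group,
            "GroupLevel": e.group_level.name if e.group_level is not None else None,
            "Reason": e.reason or None,
        }
        for e in plan.entries
    ]
    pd.DataFrame(rows, columns=["Survey", "SizeClass", "Taxname", "Lifestage", "Action", "Group", "GroupLevel", "Reason"]).to_csv(
        path, index=False, na_rep="NA"
    )


def build_community_table(
    harmonized: pd.DataFrame,
    env: pd.DataFrame,
    tree: Optional[TaxonomyTree] = None,
    stations: Optional[pd.DataFrame] = None,
    undersampled: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Join harmonized catch with sample, taxonomy and station information.

    Produces the analysis-ready single table: one row per sample x output
    category with environment fields, the taxon's rank ladder, station
    coordinates, and undersampling flags attached.
    """
    out = harmonized.merge(env, on="SampleID", how="left", suffixes=("", "_env"))
    out = out.drop(columns=[c for c in out.columns if c.endswith("_env")])
    if tree is not None:
        tax = tree.to_frame()
        out = out.merge(tax, on="Taxname", how="left")
    if stations is not None:
        cols = [c for c in ("Latitude", "Longitude") if c in out.columns]
        out = out.drop(columns=cols).merge(stations, on=["Source", "Station"], how="left")
    if undersampled is not None and len(undersampled):
        flagged = set(undersampled.loc[undersampled["FlaggedGear"] != "none", "Taxlifestage"])
        out["Undersampled"] = out["Taxlifestage"].isin(flagged) | out.get("Undersampled", False)
    return out
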