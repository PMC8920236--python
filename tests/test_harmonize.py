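"""Harmonization plans, their application, temporal correction, conservation.

The community-mode planner is cross-checked against a naive exhaustive
search written with plain dicts and loops (no package machinery), and the
per-sample conservation accounting against a brute-force re-summation.
"""

import math

import numpy as np
import pandas as pd
import pytest

import plankweave as pw
from plankweave.errors import AlignmentError, InputError, PlanMismatchError
from plankweave.harmonize import Action

RANK_NAMES = ["Phylum", "Class", "Order", "Family", "Genus", "Species"]

SURVEYS = ["20mm", "EMP", "FMWT"]


@pytest.fixture()
def community_plan(survey_lists, tortanus_tree):
    return pw.plan_community(survey_lists, tortanus_tree, SURVEYS, "Meso", (2006, 2015))


def _catch(rows):
    df = pd.DataFrame(rows, columns=["SampleID", "Source", "Taxname", "Lifestage", "CPUE"])
    df["Taxlifestage"] = df["Taxname"] + " " + df["Lifestage"]
    return df


class TestPlanCommunity:
    def test_tortanus_rolls_to_genus_and_species_removed(self, community_plan):
        for survey in SURVEYS:
            e = community_plan.action_for(survey, "Tortanus", "Adult")
            assert e.action is Action.SUM_TO and e.group == "Tortanus"
        for sp in ("Tortanus discaudatus", "Tortanus dextrilobatus"):
            e = community_plan.action_for("20mm", sp, "Adult")
            assert e.action is Action.SUM_TO and e.group == "Tortanus"
        assert community_plan.group_levels[("Tortanus", "Adult")] == pw.Rank.Genus

    def test_single_survey_phylum_is_orphan(self, community_plan):
        e = community_plan.action_for("20mm", "Annelida", "Adult")
        assert e.action is Action.DROP
        assert [o.taxname for o in community_plan.orphans] == ["Annelida"]

    def test_universal_category_kept(self, community_plan):
        for survey in SURVEYS:
            assert community_plan.action_for(survey, "Acartiella sinensis", "Adult").action is Action.KEEP

    def test_identical_lists_all_keep(self, tortanus_tree):
        entries = [pw.TaxaListEntry(s, "Meso", "Tortanus", "Adult", 1995) for s in SURVEYS]
        plan = pw.plan_community(pw.TaxaList(entries), tortanus_tree, SURVEYS, "Meso")
        assert all(e.action is Action.KEEP for e in plan.entries)
        assert not plan.orphans and not plan.groups

    def test_empty_survey_set_rejected(self, survey_lists, tortanus_tree):
        with pytest.raises(InputError):
            pw.plan_community(survey_lists, tortanus_tree, [], "Meso")

    def test_exclusivity_registry(self, community_plan):
        """Each (survey, category) contributes to exactly one output or is dropped."""
        seen = {}
        for e in community_plan.entries:
            key = (e.survey, e.taxname, e.lifestage)
            assert key not in seen
            seen[key] = e.action
        constituents = [
            (survey, name, ls)
            for (gname, ls), reg in community_plan.groups.items()
            for survey, names in reg.items()
            for name in names
        ]
        assert len(constituents) == len(set(constituents))
        for key in constituents:
            assert seen[key] is Action.SUM_TO


class TestApplyPlan:
    def test_within_sample_summation(self, community_plan):
        catch = _catch([
            ("s1", "20mm", "Tortanus discaudatus", "Adult", 2.0),
            ("s1", "20mm", "Tortanus dextrilobatus", "Adult", 3.0),
            ("s1", "20mm", "Tortanus", "Adult", 1.0),
        ])
        out = pw.apply_plan(catch, community_plan)
        assert out["Taxname"].tolist() == ["Tortanus"]
        assert out["CPUE"].iloc[0] == pytest.approx(6.0)

    def test_identity_plan_is_noop(self, tortanus_tree):
        entries = [pw.TaxaListEntry(s, "Meso", "Acartiella sinensis", "Adult", 1995) for s in SURVEYS]
        plan = pw.plan_community(pw.TaxaList(entries), tortanus_tree, SURVEYS, "Meso")
        catch = _catch([("s1", "EMP", "Acartiella sinensis", "Adult", 5.0)])
        out = pw.apply_plan(catch, plan)
        assert out[["SampleID", "Taxname", "CPUE"]].equals(catch[["SampleID", "Taxname", "CPUE"]])

    def test_na_skipped_unless_all_na(self, community_plan):
        catch = _catch([
            ("s1", "20mm", "Tortanus discaudatus", "Adult", np.nan),
            ("s1", "20mm", "Tortanus", "Adult", 1.5),
            ("s2", "20mm", "Tortanus discaudatus", "Adult", np.nan),
            ("s2", "20mm", "Tortanus", "Adult", np.nan),
        ])
        out = pw.apply_plan(catch, community_plan).set_index("SampleID")
        assert out.loc["s1", "CPUE"] == pytest.approx(1.5)
        assert np.isnan(out.loc["s2", "CPUE"])

    def test_na_propagate_mode(self, community_plan):
        catch = _catch([
            ("s1", "20mm", "Tortanus discaudatus", "Adult", np.nan),
            ("s1", "20mm", "Tortanus", "Adult", 1.5),
        ])
        out = pw.apply_plan(catch, community_plan, na_rule="propagate")
        assert np.isnan(out["CPUE"].iloc[0])

    def test_category_absent_from_plan_rejected(self, community_plan):
        catch = _catch([("s1", "EMP", "Eurytemora affinis", "Adult", 1.0)])
        with pytest.raises(PlanMismatchError):
            pw.apply_plan(catch, community_plan)

    def test_sample_order_invariance(self, community_plan):
        rng = np.random.default_rng(7)
        rows = [
            (f"s{i}", "20mm", name, "Adult", float(rng.uniform(0, 10)))
            for i in range(20)
            for name in ("Tortanus discaudatus", "Tortanus", "Acartiella sinensis")
        ]
        catch = _catch(rows)
        shuffled = catch.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = pw.apply_plan(catch, community_plan)
        b = pw.apply_plan(shuffled, community_plan)
        pd.testing.assert_frame_equal(a, b)

    def test_idempotence_on_harmonized_output(self, survey_lists, tortanus_tree, community_plan):
        """Re-planning on the output's implied lists changes nothing."""
        catch = _catch([
            ("s1", "20mm", "Tortanus discaudatus", "Adult", 2.0),
            ("s1", "20mm", "Tortanus", "Adult", 1.0),
            ("s1", "20mm", "Acartiella sinensis", "Adult", 4.0),
        ])
        once = pw.apply_plan(catch, community_plan)
        out_entries = [
            pw.TaxaListEntry(s, "Meso", name, ls, 1995)
            for s in SURVEYS
            for name, ls in {(r.Taxname, r.Lifestage) for r in once.itertuples()}
        ]
        plan2 = pw.plan_community(pw.TaxaList(out_entries), tortanus_tree, SURVEYS, "Meso")
        twice = pw.apply_plan(once.assign(Source="20mm"), plan2)
        assert np.allclose(
            twice.sort_values("Taxname")["CPUE"], once.sort_values("Taxname")["CPUE"]
        )


class TestTaxaOfInterest:
    def test_all_group_plus_retained_constituents(self, survey_lists, tortanus_tree):
        plan = pw.plan_taxa_of_interest(["Tortanus"], survey_lists, tortanus_tree, SURVEYS, "Meso")
        assert not plan.exclusive
        catch = _catch([
            ("s1", "20mm", "Tortanus discaudatus", "Adult", 2.0),
            ("s1", "20mm", "Tortanus dextrilobatus", "Adult", 3.0),
            ("s1", "20mm", "Tortanus", "Adult", 1.0),
        ])
        out = pw.apply_plan(catch, plan)
        by_name = out.set_index("Taxname")["CPUE"]
        assert by_name["All Tortanus"] == pytest.approx(6.0)
        for name in ("Tortanus", "Tortanus discaudatus", "Tortanus dextrilobatus"):
            assert name in by_name.index  # double-counting by design

    def test_degenerate_group_equals_single_category(self, survey_lists, tortanus_tree):
        plan = pw.plan_taxa_of_interest(["Acartiella sinensis"], survey_lists, tortanus_tree,
                                        SURVEYS, "Meso")
        catch = _catch([("s1", "EMP", "Acartiella sinensis", "Adult", 5.0)])
        out = pw.apply_plan(catch, plan).set_index("Taxname")["CPUE"]
        assert out["All Acartiella sinensis"] == out["Acartiella sinensis"] == 5.0

    def test_uncounted_taxon_warns_and_groups_empty(self, survey_lists, tortanus_tree):
        tree = pw.build_taxonomy(list(tortanus_tree) + [
            pw.TaxonNode.from_ladder("Nematoda", "Phylum", phylum="Nematoda")
        ])
        with pytest.warns(UserWarning):
            plan = pw.plan_taxa_of_interest(["Nematoda"], survey_lists, tree, SURVEYS, "Meso")
        assert not plan.groups

    def test_matches_community_group_per_sample(self, survey_lists, tortanus_tree, community_plan):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(15):
            rows += [
                (f"s{i}", "20mm", "Tortanus discaudatus", "Adult", float(rng.uniform(0, 5))),
                (f"s{i}", "20mm", "Tortanus dextrilobatus", "Adult", float(rng.uniform(0, 5))),
                (f"s{i}", "20mm", "Tortanus", "Adult", float(rng.uniform(0, 5))),
            ]
        catch = _catch(rows)
        community = pw.apply_plan(catch, community_plan)
        toi_plan = pw.plan_taxa_of_interest(["Tortanus"], survey_lists, tortanus_tree, SURVEYS, "Meso")
        toi = pw.apply_plan(catch, toi_plan)
        a = community.set_index("SampleID")["CPUE"].sort_index()
        b = toi[toi["Taxname"] == "All Tortanus"].set_index("SampleID")["CPUE"].sort_index()
        assert np.allclose(a, b)


class TestTimeCorrect:
    def _lists(self):
        E = pw.TaxaListEntry
        return pw.TaxaList([
            E("20mm", "Meso", "Tortanus", "Adult", 1990),
            E("20mm", "Meso", "Tortanus discaudatus", "Adult", 2000),
            E("20mm", "Meso", "Acartiella sinensis", "Adult", 1994, intro_year=1993),
        ])

    def test_late_promotion_removed_genus_kept(self):
        out = pw.time_correct(self._lists(), (1990, 2020))
        cats = {(e.taxname, e.lifestage) for e in out}
        assert ("Tortanus", "Adult") in cats
        assert ("Tortanus discaudatus", "Adult") not in cats

    def test_introduced_species_within_lag_retained(self):
        out = pw.time_correct(self._lists(), (1990, 2020), intro_lag=2)
        cats = {e.taxname for e in out}
        assert "Acartiella sinensis" in cats

    def test_introduced_species_outside_lag_removed(self):
        out = pw.time_correct(self._lists(), (1990, 2020), intro_lag=0)
        assert "Acartiella sinensis" not in {e.taxname for e in out}

    def test_infinite_lag_retains_all_introduced(self):
        E = pw.TaxaListEntry
        lists = pw.TaxaList(list(self._lists()) + [
            E("20mm", "Meso", "Tortanus dextrilobatus", "Adult", 2015, intro_year=1905),
        ])
        out = pw.time_correct(lists, (1990, 2020), intro_lag=math.inf)
        assert "Tortanus dextrilobatus" in {e.taxname for e in out}

    def test_inverted_range_rejected(self):
        with pytest.raises(InputError):
            pw.time_correct(self._lists(), (2020, 1990))

    def test_monotone_in_range(self):
        """Enlarging the year range never adds native categories."""
        small = {e.taxname for e in pw.time_correct(self._lists(), (2001, 2005))}
        large = {e.taxname for e in pw.time_correct(self._lists(), (1990, 2020))}
        assert large - {"Acartiella sinensis"} <= small


class TestConservation:
    def _random_catch(self, seed, n_samples=30):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_samples):
            for name in ("Tortanus discaudatus", "Tortanus dextrilobatus",
                         "Tortanus", "Acartiella sinensis", "Annelida"):
                rows.append((f"s{i}", "20mm", name, "Adult", float(rng.uniform(0, 20))))
        return _catch(rows)

    def test_no_drop_fixture_perfect_regression(self, tortanus_tree):
        entries = [
            pw.TaxaListEntry(s, "Meso", n, "Adult", 1990)
            for s in SURVEYS
            for n in ("Tortanus discaudatus", "Tortanus dextrilobatus", "Tortanus",
                      "Acartiella sinensis", "Annelida")
        ]
        plan = pw.plan_community(pw.TaxaList(entries), tortanus_tree, SURVEYS, "Meso")
        catch = self._random_catch(5)
        report = pw.validate_conservation(catch, pw.apply_plan(catch, plan), plan)
        assert report.slope == pytest.approx(1.0, abs=1e-12)
        assert report.intercept == pytest.approx(0.0, abs=1e-9)
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)
        assert report.max_abs_delta < 1e-9

    def test_delta_equals_dropped_cpue_per_sample(self, community_plan):
        """Brute-force accounting: raw minus harmonized equals dropped, sample by sample."""
        catch = self._random_catch(9)
        harmonized = pw.apply_plan(catch, community_plan)
        report = pw.validate_conservation(catch, harmonized, community_plan)
        raw_tot = catch.groupby("SampleID")["CPUE"].sum()
        harm_tot = harmonized.groupby("SampleID")["CPUE"].sum()
        dropped = catch[catch["Taxname"] == "Annelida"].groupby("SampleID")["CPUE"].sum()
        for sid in raw_tot.index:
            assert raw_tot[sid] - harm_tot[sid] == pytest.approx(dropped.get(sid, 0.0))
        assert report.conserved

    def test_mismatched_samples_rejected(self, community_plan):
        catch = self._random_catch(3)
        harmonized = pw.apply_plan(catch, community_plan)
        with pytest.raises(AlignmentError):
            pw.validate_conservation(catch.iloc[5:], harmonized, community_plan)


# ---------------------------------------------------------------------------
# exhaustive-search oracle for the community planner


def _random_instance(rng):
    """Random taxonomy + survey lists: <=5 surveys, <=40 taxa."""
    n_fam = rng.integers(1, 4)
    nodes, names = [], []
    for f in range(n_fam):
        fam = f"Fam{f}"
        nodes.append(pw.TaxonNode.from_ladder(
            fam, "Family", phylum="Arthropoda", **{"class": "Copepoda"},
            order="Calanoida", family=fam))
        names.append((fam, "Family"))
        for g in range(rng.integers(1, 4)):
            gen = f"Gen{f}_{g}"
            nodes.append(pw.TaxonNode.from_ladder(
                gen, "Genus", phylum="Arthropoda", **{"class": "Copepoda"},
                order="Calanoida", family=fam, genus=gen))
            names.append((gen, "Genus"))
            for s in range(rng.integers(1, 4)):
                sp = f"{gen} sp{s}"
                nodes.append(pw.TaxonNode.from_ladder(
                    sp, "Species", phylum="Arthropoda", **{"class": "Copepoda"},
                    order="Calanoida", family=fam, genus=gen, species=sp))
                names.append((sp, "Species"))
    tree = pw.build_taxonomy(nodes)
    surveys = [f"S{i}" for i in range(rng.integers(2, 6))]
    entries = []
    for s in surveys:
        for name, _level in names:
            if rng.random() < 0.55:
                entries.append(pw.TaxaListEntry(s, "Meso", name, "Adult", 1990))
    return tree, pw.TaxaList(entries), surveys


def _oracle_actions(tree, lists, surveys):
    """Naive exhaustive search, package machinery avoided on purpose."""
    cats = {s: {(e.taxname, e.lifestage) for e in lists if e.survey == s} for s in surveys}
    union = set().union(*cats.values())
    ladder = {n.taxname: [n.names[r] for r in range(n.level + 1)] for n in tree}
    actions = {}
    for name, ls in union:
        in_all = all((name, ls) in cats[s] for s in surveys)
        chain = ladder[name]
        if in_all:
            absorbed = False
            for other, ls2 in union:
                if ls2 != ls or (other, ls2) == (name, ls):
                    continue
                if all((other, ls2) in cats[s] for s in surveys):
                    continue  # universal categories never roll up
                # does `other` roll up to `name`?
                target = None
                for anc in reversed(ladder[other]):
                    if all((anc, ls2) in cats[s] for s in surveys):
                        target = anc
                        break
                if target == name:
                    absorbed = True
            actions[(name, ls)] = ("SUM_TO", name) if absorbed else ("KEEP", None)
            continue
        target = None
        for anc in reversed(chain):
            if all((anc, ls) in cats[s] for s in surveys):
                target = anc
                break
        actions[(name, ls)] = ("SUM_TO", target) if target else ("DROP", None)
    return actions


@pytest.mark.parametrize("seed", range(40))
def test_plan_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    tree, lists, surveys = _random_instance(rng)
    plan = pw.plan_community(lists, tree, surveys, "Meso")
    expected = _oracle_actions(tree, lists, surveys)
    got = {}
    for e in plan.entries:
        key = (e.taxname, e.lifestage)
        val = (e.action.value, e.group if e.action is Action.SUM_TO else None)
        assert got.setdefault(key, val) == val  # consistent across surveys
    assert got == expected
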