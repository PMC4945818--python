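"""Decision-tree and message-catalog tests."""

import dataclasses
import itertools

import pytest

from dietfeedback import (
    CatalogIntegrityError,
    InputError,
    resolve_feedback,
    top_contributors,
    validate_catalog,
)
from dietfeedback.goals import Goal
from dietfeedback.grading import BANDS
from dietfeedback.nutrients import NUTRIENTS, SUPPLEMENT_EXEMPT, default_registry
from dietfeedback.trees import (
    DecisionTree,
    MessageCatalog,
    FeedbackMessage,
    SALT_CANDIDATE_GROUPS,
    SFA_CANDIDATE_GROUPS,
    TreeBranch,
    frame_to_trees,
    tree_key,
    trees_to_frame,
)

from .conftest import make_graded

MODERATION_TREES = {"total_fat", "sfa", "salt"}


def goal_for(nutrient, band):
    color = {"recommended": "green"}.get(band)
    if color:
        return Goal(nutrient, 1, "maintain", "green")
    color = "red" if band in ("very low", "very high") else "amber"
    return Goal(nutrient, 1, "improve", color)


class TestShippedAssets:
    def test_sixteen_trees_cover_seventeen_nutrients(self, trees):
        assert len(trees) == 16
        assert {tree_key(n) for n in NUTRIENTS} == set(trees)

    def test_catalog_has_92_messages(self, catalog):
        assert len(catalog) == 92

    def test_shipped_assets_validate_cleanly(self, trees, catalog):
        assert validate_catalog(trees, catalog) == []

    def test_contributor_trees_have_seven_candidates(self, trees):
        for nid, groups in (("sfa", SFA_CANDIDATE_GROUPS), ("salt", SALT_CANDIDATE_GROUPS)):
            tree = trees[nid]
            assert tree.uses_contributors
            assert tree.candidate_food_groups == groups
            assert len(groups) == 7

    def test_simple_trees_do_not_use_contributors(self, trees):
        for tid, tree in trees.items():
            if tid not in ("sfa", "salt"):
                assert not tree.uses_contributors


class TestValidateCatalog:
    def test_dangling_message_reported(self, trees, catalog):
        broken = dict(trees)
        vit_c = broken["vitamin_c"]
        broken["vitamin_c"] = dataclasses.replace(
            vit_c,
            branches=vit_c.branches
            + (TreeBranch("low", "any", None, ("vitamin_c.nope",)),),
        )
        kinds = {f.kind for f in validate_catalog(broken, catalog)}
        assert "dangling message" in kinds

    def test_uncovered_band_reported(self, trees, catalog):
        broken = dict(trees)
        vit_c = broken["vitamin_c"]
        broken["vitamin_c"] = dataclasses.replace(
            vit_c,
            branches=tuple(b for b in vit_c.branches if b.band != "high"),
        )
        findings = validate_catalog(
            broken, catalog, expected_bands={"vitamin_c": BANDS}
        )
        assert any(
            f.kind == "uncovered band" and "high" in f.detail for f in findings
        )

    def test_duplicate_condition_reported(self, trees, catalog):
        broken = dict(trees)
        fib = broken["fiber"]
        broken["fiber"] = dataclasses.replace(
            fib, branches=fib.branches + (fib.branches[0],)
        )
        kinds = {f.kind for f in validate_catalog(broken, catalog)}
        assert "duplicate condition" in kinds

    def test_strict_mode_raises(self, trees, catalog):
        broken = dict(trees)
        fib = broken["fiber"]
        broken["fiber"] = dataclasses.replace(
            fib, branches=fib.branches + (fib.branches[0],)
        )
        with pytest.raises(CatalogIntegrityError):
            validate_catalog(broken, catalog, strict=True)


class TestTopContributors:
    def test_argmax_selection(self):
        contrib = {
            "dairy": 0.40,
            "red and processed meat": 0.25,
            "butter and spreads": 0.20,
            "cakes and biscuits": 0.15,
        }
        result = top_contributors(contrib, 2, SFA_CANDIDATE_GROUPS)
        assert result.group_names() == ("dairy", "red and processed meat")

    def test_tie_broken_by_candidate_list_order(self):
        contrib = {"fried foods": 0.30, "butter and spreads": 0.30, "dairy": 0.1}
        result = top_contributors(contrib, 2, SFA_CANDIDATE_GROUPS)
        # butter and spreads precedes fried foods in the candidate list
        assert result.group_names() == ("butter and spreads", "fried foods")

    def test_single_nonzero_share_gives_single_result(self):
        result = top_contributors({"cheese": 0.8}, 2, SALT_CANDIDATE_GROUPS)
        assert result.group_names() == ("cheese",)

    def test_groups_outside_candidates_ignored(self):
        result = top_contributors(
            {"chocolate": 0.9, "dairy": 0.1}, 2, SFA_CANDIDATE_GROUPS
        )
        assert result.group_names() == ("dairy",)

    def test_shares_non_increasing(self):
        contrib = dict(zip(SALT_CANDIDATE_GROUPS, (0.1, 0.3, 0.2, 0.15, 0.1, 0.1, 0.05)))
        result = top_contributors(contrib, 4, SALT_CANDIDATE_GROUPS)
        shares = [s for _, s in result.top_groups]
        assert shares == sorted(shares, reverse=True)

    def test_bad_k_rejected(self):
        with pytest.raises(InputError):
            top_contributors({"dairy": 1.0}, 0, SFA_CANDIDATE_GROUPS)


class TestResolveFeedback:
    def test_vitamin_c_low_without_supplement_single_food_message(
        self, trees, catalog, sample_profile
    ):
        profile = dataclasses.replace(sample_profile, supplement_intakes={})
        msgs = resolve_feedback(
            goal_for("vitamin_c", "low"),
            make_graded("vitamin_c", "low"),
            profile,
            trees["vitamin_c"],
            catalog,
        )
        assert [m.message_id for m in msgs] == ["vitamin_c.low.food"]

    def test_vitamin_c_low_with_supplement_switches_branch(
        self, trees, catalog, sample_profile
    ):
        msgs = resolve_feedback(
            goal_for("vitamin_c", "low"),
            make_graded("vitamin_c", "low"),
            sample_profile,  # takes a vitamin C supplement
            trees["vitamin_c"],
            catalog,
        )
        assert [m.message_id for m in msgs] == ["vitamin_c.low.supp"]

    def test_sfa_very_high_general_plus_two_contributors(
        self, trees, catalog, sample_profile
    ):
        msgs = resolve_feedback(
            goal_for("sfa", "very high"),
            make_graded("sfa", "very high"),
            sample_profile,
            trees["sfa"],
            catalog,
        )
        ids = [m.message_id for m in msgs]
        assert ids == [
            "sfa.very_high",
            "sfa.group.dairy",
            "sfa.group.red_and_processed_meat",
        ]
        assert 2 <= len(ids) <= 4

    def test_maintain_goal_single_positive_message(self, trees, catalog, sample_profile):
        msgs = resolve_feedback(
            Goal("calcium", 3, "maintain", "green"),
            make_graded("calcium", "recommended"),
            sample_profile,
            trees["calcium"],
            catalog,
        )
        assert len(msgs) == 1 and msgs[0].positive

    def test_mufa_and_pufa_resolve_through_unsaturated_fat_tree(
        self, trees, catalog, sample_profile
    ):
        for nutrient in ("mufa", "pufa"):
            msgs = resolve_feedback(
                goal_for(nutrient, "low"),
                make_graded(nutrient, "low"),
                sample_profile,
                trees["unsaturated_fat"],
                catalog,
            )
            assert [m.message_id for m in msgs] == ["unsaturated_fat.low"]

    def test_wrong_tree_rejected(self, trees, catalog, sample_profile):
        with pytest.raises(InputError):
            resolve_feedback(
                goal_for("iron", "low"),
                make_graded("iron", "low"),
                sample_profile,
                trees["calcium"],
                catalog,
            )

    def test_exhaustive_reachable_conditions_never_raise(
        self, trees, catalog, sample_profile, registry
    ):
        """Every (tree, band, supplement state, contributor pair) resolves."""
        contributor_pairs = list(itertools.combinations(SFA_CANDIDATE_GROUPS, 2)) + [
            ("dairy",)
        ]
        for nutrient in NUTRIENTS:
            tree = trees[tree_key(nutrient)]
            schema_bands = (
                BANDS if registry[nutrient].schema == "adequacy" else BANDS[2:]
            )
            for band in schema_bands:
                for supp in (0.0, 10.0):
                    profile = dataclasses.replace(
                        sample_profile, supplement_intakes={nutrient: supp}
                    )
                    msgs = resolve_feedback(
                        goal_for(nutrient, band),
                        make_graded(nutrient, band),
                        profile,
                        tree,
                        catalog,
                        supplement_counted=registry[nutrient].supplement_counted,
                    )
                    assert len(msgs) >= 1
                    if tree.uses_contributors and band in ("high", "very high"):
                        assert 2 <= len(msgs) <= 4
                    else:
                        assert len(msgs) == 1

    def test_supplement_ignored_for_exempt_nutrients(
        self, trees, catalog, sample_profile, registry
    ):
        """A supplement never changes the advice for the exempt nutrients."""
        for nutrient in SUPPLEMENT_EXEMPT:
            tree = trees[tree_key(nutrient)]
            band = "high" if registry[nutrient].schema == "moderation" else "low"
            with_supp = dataclasses.replace(
                sample_profile, supplement_intakes={nutrient: 99.0}
            )
            without = dataclasses.replace(sample_profile, supplement_intakes={})
            resolve = lambda p: [
                m.message_id
                for m in resolve_feedback(
                    goal_for(nutrient, band),
                    make_graded(nutrient, band),
                    p,
                    tree,
                    catalog,
                    supplement_counted=registry[nutrient].supplement_counted,
                )
            ]
            assert resolve(with_supp) == resolve(without)


class TestCatalogLocales:
    def test_missing_locale_falls_back_to_reference(self, catalog, caplog):
        msg = catalog.lookup("sfa.high", locale="de")
        assert msg.locale == "en"

    def test_unknown_message_raises(self, catalog):
        with pytest.raises(CatalogIntegrityError):
            catalog.lookup("sfa.nonexistent")

    def test_localized_message_preferred(self):
        en = FeedbackMessage("m1", "sfa", "high", "any", None, "en", False, "hello")
        de = FeedbackMessage("m1", "sfa", "high", "any", None, "de", False, "hallo")
        cat = MessageCatalog([en, de])
        assert cat.lookup("m1", "de").text == "hallo"
        assert cat.lookup("m1", "en").text == "hello"


def test_tree_table_round_trip(trees):
    frame = trees_to_frame(trees)
    assert frame_to_trees(frame) == trees


def test_tree_file_round_trip(tmp_path, trees):
    from dietfeedback.trees import load_trees, write_trees

    path = tmp_path / "trees.csv"
    write_trees(trees, path)
    assert load_trees(path) == trees


def test_catalog_file_round_trip(tmp_path, catalog):
    from dietfeedback.trees import load_catalog, write_catalog

    path = tmp_path / "messages.csv"
    write_catalog(catalog, path)
    reloaded = load_catalog(path)
    assert reloaded.message_ids() == catalog.message_ids()
    for mid in catalog.message_ids():
        assert reloaded.lookup(mid) == catalog.lookup(mid)
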