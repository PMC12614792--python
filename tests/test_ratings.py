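"""Rating normalisation, rater exclusion, aggregation and agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matfp.ratings import (aggregate_ratings, attribute_importance,
                           boundary_study_trials, exclude_discordant,
                           fleiss_kappa, rating_study_total, unanimity_counts,
                           zscore_participant)


def make_table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "material_id",
                                       "attribute_id", "response"])


class TestZscoreParticipant:
    def test_symmetric_triple_maps_to_unit_scores(self):
        table = make_table([("p1", f"m{i}", 1, v) for i, v in enumerate([0.0, 50.0, 100.0])])
        out, flagged = zscore_participant(table)
        assert sorted(out["response"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert flagged == []

    def test_single_participant_output_has_zero_mean(self):
        rng = np.random.default_rng(1)
        rows = [("p1", f"m{i}", a, rng.uniform(0, 100))
                for i in range(6) for a in range(1, 17)]
        out, _ = zscore_participant(make_table(rows))
        for a, sub in out.groupby("attribute_id"):
            assert abs(sub["response"].mean()) < 1e-12

    def test_matches_two_pass_standardization_oracle(self):
        rng = np.random.default_rng(2)
        rows = [(f"p{p}", f"m{i}", a, rng.uniform(0, 100))
                for p in range(3) for i in range(5) for a in (1, 2)]
        table = make_table(rows)
        out, _ = zscore_participant(table)
        for (p, a), sub in table.groupby(["participant_id", "attribute_id"]):
            x = sub["response"].to_numpy()
            want = (x - x.mean()) / x.std(ddof=1)
            got = out.loc[sub.index, "response"].to_numpy()
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_every_nonconstant_stratum_standardised(self):
        rng = np.random.default_rng(3)
        rows = [(f"p{p}", f"m{i}", a, rng.uniform(0, 100))
                for p in range(4) for i in range(8) for a in range(1, 5)]
        out, _ = zscore_participant(make_table(rows))
        for _, sub in out.groupby(["participant_id", "attribute_id"]):
            assert abs(sub["response"].mean()) < 1e-10
            assert abs(sub["response"].std(ddof=1) - 1.0) < 1e-10

    def test_constant_stratum_flagged_and_zeroed(self):
        rows = [("p1", f"m{i}", 1, 40.0) for i in range(4)]
        rows += [("p1", f"m{i}", 2, float(10 * i)) for i in range(4)]
        out, flagged = zscore_participant(make_table(rows))
        assert flagged == [("p1", 1)]
        assert (out[out["attribute_id"] == 1]["response"] == 0).all()


class TestExcludeDiscordant:
    def test_negated_rater_excluded(self):
        vals = [10.0, 50.0, 90.0]
        rows = []
        for p in ("p1", "p2"):
            rows += [(p, f"m{i}", 1, v) for i, v in enumerate(vals)]
        rows += [("bad", f"m{i}", 1, v) for i, v in enumerate(reversed(vals))]
        z, flagged = zscore_participant(make_table(rows))
        report = exclude_discordant(z, flagged)
        assert [(e.participant_id, e.attribute_id) for e in report.excluded] == [("bad", 1)]

    def test_identical_raters_none_excluded(self):
        rows = [(p, f"m{i}", 1, float(i * 20))
                for p in ("p1", "p2", "p3") for i in range(4)]
        z, flagged = zscore_participant(make_table(rows))
        assert exclude_discordant(z, flagged).excluded == []

    def test_matches_bruteforce_correlation_loop(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0, 100, size=8)
        rows = []
        for p in range(4):
            noisy = base + rng.normal(0, 5, size=8)
            rows += [(f"p{p}", f"m{i}", 1, float(v)) for i, v in enumerate(noisy)]
        shuffled = rng.permutation(base)
        rows += [("shuf", f"m{i}", 1, float(v)) for i, v in enumerate(shuffled)]
        z, flagged = zscore_participant(make_table(rows))
        report = exclude_discordant(z, flagged)
        # brute-force: correlation of each rater with the all-rater mean
        pivot = z.pivot(index="material_id", columns="participant_id", values="response")
        mean = pivot.mean(axis=1)
        want = {p for p in pivot.columns
                if np.corrcoef(pivot[p], mean)[0, 1] < 0}
        assert {e.participant_id for e in report.excluded} == want

    def test_single_rater_never_excluded(self):
        rows = [("p1", f"m{i}", 1, float(i)) for i in range(5)]
        z, flagged = zscore_participant(make_table(rows))
        assert exclude_discordant(z, flagged).excluded == []


class TestAggregateRatings:
    def test_single_participant_fingerprints_equal_own_zscores(self):
        rng = np.random.default_rng(4)
        rows = [("p1", f"m{i}", a, rng.uniform(0, 100))
                for i in range(5) for a in range(1, 17)]
        table = make_table(rows)
        report = aggregate_ratings(table)
        z, _ = zscore_participant(table)
        for mid in report.fingerprints.ids:
            want = z[z["material_id"] == mid].sort_values("attribute_id")["response"]
            np.testing.assert_allclose(report.fingerprints[mid].values,
                                       want.to_numpy(), atol=1e-12)

    def test_duplicated_participant_changes_nothing(self):
        rng = np.random.default_rng(5)
        vals = {(i, a): rng.uniform(0, 100) for i in range(4) for a in range(1, 17)}
        one = make_table([("p1", f"m{i}", a, v) for (i, a), v in vals.items()])
        two = make_table([(p, f"m{i}", a, v) for p in ("p1", "p2")
                          for (i, a), v in vals.items()])
        r1 = aggregate_ratings(one)
        r2 = aggregate_ratings(two)
        for mid in r1.fingerprints.ids:
            np.testing.assert_allclose(r1.fingerprints[mid].values,
                                       r2.fingerprints[mid].values, atol=1e-12)

    def test_row_order_and_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        rows = [(f"p{p}", f"m{i}", a, rng.uniform(0, 100))
                for p in range(3) for i in range(4) for a in range(1, 17)]
        table = make_table(rows)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabel = table.assign(
            participant_id=table["participant_id"].map({"p0": "zz", "p1": "aa", "p2": "mm"}))
        base = aggregate_ratings(table)
        for variant in (shuffled, relabel):
            got = aggregate_ratings(variant)
            for mid in base.fingerprints.ids:
                np.testing.assert_allclose(got.fingerprints[mid].values,
                                           base.fingerprints[mid].values, atol=1e-12)

    def test_exclusion_is_idempotent_on_surviving_data(self, ratings_50):
        _, table = ratings_50
        z, flagged = zscore_participant(table)
        first = exclude_discordant(z, flagged)
        drop = {(e.participant_id, e.attribute_id) for e in first.excluded}
        keep = [i for i, (p, a) in enumerate(
            zip(z["participant_id"], z["attribute_id"])) if (p, a) not in drop]
        second = exclude_discordant(z.iloc[keep])
        assert second.excluded == []


class TestAttributeImportance:
    def test_toy_enumeration_oracle(self):
        naming = pd.DataFrame({
            "participant_id": ["p1", "p1", "p2", "p2"],
            "trial": [1, 1, 1, 2],
            "term": ["shiny", "rough", "shiny", "soft"],
            "rank": [1, 2, 2, 1],
        })
        clusters = {"shiny": 7, "rough": 2, "soft": 9}
        out = attribute_importance(naming, clusters)
        # 3 distinct (participant, trial) responses
        assert out.loc[7, "ap"] == pytest.approx(2 / 3)
        assert out.loc[7, "ao"] == pytest.approx(1.5)
        assert out.loc[2, "ao"] == pytest.approx(2.0)
        max_ao = 2.0
        assert out.loc[7, "importance"] == pytest.approx(2 / 3 * (max_ao - 1.5))

    def test_largest_mean_rank_and_unmentioned_get_zero_importance(self):
        naming = pd.DataFrame({
            "participant_id": ["p1", "p1"],
            "trial": [1, 1],
            "term": ["shiny", "warm"],
            "rank": [1, 5],
        })
        out = attribute_importance(naming, {"shiny": 7, "warm": 16})
        assert out.loc[16, "importance"] == pytest.approx(0.0)  # max(ao) - ao = 0
        assert out.loc[3, "ap"] == 0.0
        assert out.loc[3, "importance"] == 0.0
        assert np.isnan(out.loc[3, "ao"])

    def test_unmapped_term_rejected(self):
        naming = pd.DataFrame({"participant_id": ["p1"], "trial": [1],
                               "term": ["fuzzy"], "rank": [1]})
        with pytest.raises(ValueError, match="fuzzy"):
            attribute_importance(naming, {})


def assignments_frame(matrix):
    """rows: response index -> list of attribute ids, one per rater."""
    rows = []
    for r, cats in enumerate(matrix):
        for j, a in enumerate(cats):
            rows.append((f"resp{r}", f"rater{j}", a))
    return pd.DataFrame(rows, columns=["response_id", "rater_id", "attribute_id"])


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        df = assignments_frame([[3] * 6, [7] * 6, [11] * 6])
        assert fleiss_kappa(df) == pytest.approx(1.0)

    def test_hand_computed_two_by_two_toy(self):
        # responses: (A,A) and (A,B) with categories A=1, B=2
        df = assignments_frame([[1, 1], [1, 2]])
        # hand computation: P1=1, P2=0, Pbar=1/2; pA=3/4, pB=1/4, Pe=10/16
        want = (0.5 - 10 / 16) / (1 - 10 / 16)
        assert fleiss_kappa(df) == pytest.approx(want)

    def test_agrees_with_statsmodels_on_seeded_tables(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        rng = np.random.default_rng(13)
        matrix = rng.integers(1, 17, size=(40, 6))
        df = assignments_frame(matrix)
        table, _ = aggregate_raters(matrix)
        assert fleiss_kappa(df) == pytest.approx(sm_kappa(table), abs=1e-12)

    def test_unbalanced_rater_counts_rejected(self):
        df = assignments_frame([[1, 1, 1], [2, 2, 2]]).iloc[:-1]
        with pytest.raises(ValueError, match="same number"):
            fleiss_kappa(df)


class TestUnanimityCounts:
    def test_full_agreement_everywhere(self):
        df = assignments_frame([[4] * 6] * 5)
        got = unanimity_counts(df)
        assert got == {"unanimous": 5, "at_least_3": 5, "at_least_2": 5}

    def test_all_distinct_counts_nowhere(self):
        df = assignments_frame([[1, 2, 3, 4, 5, 6]])
        got = unanimity_counts(df)
        assert got == {"unanimous": 0, "at_least_3": 0, "at_least_2": 0}

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(21)
        matrix = rng.integers(1, 17, size=(60, 6))
        got = unanimity_counts(assignments_frame(matrix))
        modal = np.array([np.bincount(row).max() for row in matrix])
        assert got["unanimous"] == int((modal == 6).sum())
        assert got["at_least_3"] == int((modal >= 3).sum())
        assert got["at_least_2"] == int((modal >= 2).sum())


class TestStudyDesignArithmetic:
    def test_rating_study_total(self):
        assert rating_study_total(16, 347, 20) == 111_040

    def test_boundary_study_trials(self):
        assert boundary_study_trials(3, 16, 2) == 96
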