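"""Fingerprint type, similarity metric, retrieval, typicality and profiles."""

import numpy as np
import pandas as pd
import pytest

from matfp.schema import (DEFAULT_SCHEMA, Fingerprint, FingerprintSet,
                          category_profile, fingerprint_similarity,
                          rescale_to_unit, retrieve_top_k, similarity_matrix,
                          typicality)

from conftest import random_unit_fingerprint


def oracle_similarity(a: np.ndarray, b: np.ndarray, alpha: float) -> float:
    """Direct textbook evaluation of the combined correlation + L1 metric."""
    n = len(a)
    am, bm = a - a.mean(), b - b.mean()
    denom = np.sqrt((am @ am) * (bm @ bm))
    r = (am @ bm) / denom if denom > 0 else 0.0
    return alpha * r + (1 - alpha) * (1 - np.abs(a - b).sum() / (2 * n))


class TestSchema:
    def test_sixteen_attributes_with_expected_names(self):
        names = DEFAULT_SCHEMA.names
        assert len(names) == 16
        assert names[0] == "colour vibrancy"
        assert names[6] == "shininess"
        assert names[15] == "warmth"
        assert [a.id for a in DEFAULT_SCHEMA.attributes] == list(range(1, 17))

    def test_cluster_labels_cover_the_five_groups(self):
        clusters = {a.cluster for a in DEFAULT_SCHEMA.attributes}
        assert clusters == {"gloss", "texture_and_pattern", "light_and_colour",
                            "physical", "abstract"}


class TestFingerprintSimilarity:
    def test_identical_nonconstant_pair_scores_one(self, rng):
        fp = random_unit_fingerprint(rng, "a")
        assert fingerprint_similarity(fp, fp, alpha=0.5) == pytest.approx(1.0)

    def test_anti_alternating_pair_scores_minus_half(self):
        v = np.tile([1.0, -1.0], 8)
        a = Fingerprint("a", v)
        b = Fingerprint("b", -v)
        # R = -1 and the absolute-difference term vanishes entirely
        assert fingerprint_similarity(a, b, alpha=0.5) == pytest.approx(-0.5)

    def test_matches_direct_formula_on_100_seeded_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = random_unit_fingerprint(rng, "a")
            b = random_unit_fingerprint(rng, "b")
            alpha = rng.uniform(0, 1)
            got = fingerprint_similarity(a, b, alpha)
            want = oracle_similarity(a.values, b.values, alpha)
            assert got == pytest.approx(want, abs=1e-12)
            assert fingerprint_similarity(b, a, alpha) == pytest.approx(got, abs=1e-12)

    def test_alpha_one_equals_pearson_and_alpha_zero_decreases_with_l1(self, rng):
        a = random_unit_fingerprint(rng, "a")
        b = random_unit_fingerprint(rng, "b")
        am, bm = a.values - a.values.mean(), b.values - b.values.mean()
        r = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert fingerprint_similarity(a, b, alpha=1.0) == pytest.approx(r, abs=1e-12)
        # alpha=0: strictly decreasing in the total absolute difference
        base = fingerprint_similarity(a, b, alpha=0.0)
        c = Fingerprint("c", np.clip(b.values + np.sign(b.values - a.values) * 0.05, -1, 1))
        assert fingerprint_similarity(a, c, alpha=0.0) < base

    def test_constant_vector_warns_and_drops_correlation_term(self):
        a = Fingerprint("a", np.zeros(16))
        b = Fingerprint("b", np.full(16, 0.5))
        with pytest.warns(RuntimeWarning):
            got = fingerprint_similarity(a, b, alpha=0.5)
        assert got == pytest.approx(0.5 * (1 - 16 * 0.5 / 32))

    def test_scale_mismatch_rejected(self, rng):
        a = random_unit_fingerprint(rng, "a")
        z = Fingerprint("z", rng.normal(size=16), scale="zscore")
        with pytest.raises(ValueError, match="scale"):
            fingerprint_similarity(a, z)


class TestSimilarityMatrix:
    def test_identical_members_give_all_ones(self):
        v = np.linspace(-1, 1, 16)
        fset = FingerprintSet([Fingerprint(f"m{i}", v) for i in range(3)])
        m = similarity_matrix(fset, alpha=0.5)
        assert np.allclose(m.values, 1.0)

    def test_singleton_set(self, rng):
        fset = FingerprintSet([random_unit_fingerprint(rng, "only")])
        m = similarity_matrix(fset)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        fps = [random_unit_fingerprint(rng, f"m{i}") for i in range(5)]
        fset = FingerprintSet(fps)
        m = similarity_matrix(fset, alpha=0.3)
        for i in range(5):
            for j in range(5):
                want = oracle_similarity(fps[i].values, fps[j].values, 0.3)
                assert m.values[i, j] == pytest.approx(want, abs=1e-12)
        assert np.allclose(m.values, m.values.T)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix(FingerprintSet([]))


class TestRetrieval:
    def test_exact_match_ranks_first(self, rng):
        target = random_unit_fingerprint(rng, "target")
        others = [random_unit_fingerprint(rng, f"m{i}") for i in range(4)]
        fset = FingerprintSet([Fingerprint("twin", target.values.copy()), *others])
        top = retrieve_top_k(target, fset, k=1)
        assert top[0][0] == "twin"
        assert top[0][1] == pytest.approx(1.0)

    def test_k_larger_than_corpus_returns_everything(self, unit_set):
        query = unit_set["m00"]
        got = retrieve_top_k(query, unit_set, k=99)
        assert len(got) == 9  # all other members, query excluded
        assert "m00" not in {m for m, _ in got}

    def test_ordering_matches_sorted_oracle(self, unit_set):
        query = unit_set["m03"]
        got = retrieve_top_k(query, unit_set, k=5, alpha=0.5)
        sims = {m: oracle_similarity(query.values, unit_set[m].values, 0.5)
                for m in unit_set.ids if m != "m03"}
        want = sorted(sims.items(), key=lambda t: (-t[1], t[0]))[:5]
        assert [m for m, _ in got] == [m for m, _ in want]
        np.testing.assert_allclose([s for _, s in got], [s for _, s in want], atol=1e-12)

    def test_full_retrieval_is_a_permutation_of_other_ids(self, unit_set):
        got = retrieve_top_k(unit_set["m01"], unit_set, k=9)
        assert sorted(m for m, _ in got) == sorted(m for m in unit_set.ids if m != "m01")

    def test_k_below_one_rejected(self, unit_set):
        with pytest.raises(ValueError):
            retrieve_top_k(unit_set["m00"], unit_set, k=0)


class TestTypicality:
    def test_identical_corpus_gives_one(self):
        v = np.linspace(-1, 1, 16)
        fset = FingerprintSet([Fingerprint(f"m{i}", v) for i in range(5)])
        for mid in fset.ids:
            assert typicality(mid, fset) == pytest.approx(1.0)

    def test_eleven_members_average_exactly_one_neighbour(self, rng):
        fps = [random_unit_fingerprint(rng, f"m{i:02d}") for i in range(11)]
        fset = FingerprintSet(fps)
        got = typicality("m00", fset, fraction=0.10)
        best = max(oracle_similarity(fps[0].values, f.values, 0.5) for f in fps[1:])
        assert got == pytest.approx(best, abs=1e-12)

    def test_matches_sort_and_average_oracle(self, rng):
        fps = [random_unit_fingerprint(rng, f"m{i:02d}") for i in range(20)]
        fset = FingerprintSet(fps)
        got = typicality("m05", fset, fraction=0.10)
        sims = sorted((oracle_similarity(fps[5].values, f.values, 0.5)
                       for f in fps if f.material_id != "m05"), reverse=True)
        assert got == pytest.approx(np.mean(sims[:2]), abs=1e-12)  # ceil(0.1*19) = 2

    def test_invariant_to_member_order(self, rng):
        fps = [random_unit_fingerprint(rng, f"m{i:02d}") for i in range(12)]
        a = typicality("m04", FingerprintSet(fps))
        b = typicality("m04", FingerprintSet(list(reversed(fps))))
        assert a == pytest.approx(b, abs=1e-14)


class TestCategoryProfile:
    def test_single_member_category(self, rng):
        fp = random_unit_fingerprint(rng, "solo")
        fset = FingerprintSet([fp], {"solo": "metal"})
        med, se = category_profile(fset, "metal")
        np.testing.assert_allclose(med, fp.values)
        np.testing.assert_allclose(se, 0.0)

    def test_two_members_median_is_midpoint(self, rng):
        a = random_unit_fingerprint(rng, "a")
        b = random_unit_fingerprint(rng, "b")
        fset = FingerprintSet([a, b], {"a": "wood", "b": "wood"})
        med, _ = category_profile(fset, "wood")
        np.testing.assert_allclose(med, (a.values + b.values) / 2)

    def test_matches_columnwise_oracle(self, rng):
        fps = [random_unit_fingerprint(rng, f"m{i}") for i in range(5)]
        fset = FingerprintSet(fps, {f.material_id: "fabric" for f in fps})
        med, se = category_profile(fset, "fabric")
        mat = np.stack([f.values for f in fps])
        np.testing.assert_allclose(med, np.median(mat, axis=0))
        np.testing.assert_allclose(se, mat.std(axis=0, ddof=1) / np.sqrt(5))

    def test_unknown_category_rejected(self, unit_set):
        with pytest.raises(KeyError):
            category_profile(unit_set, "granite")


class TestRescaleToUnit:
    def test_symmetric_triple_maps_to_unit_endpoints(self):
        vals = [-2.0, 0.0, 2.0]
        fps = [Fingerprint(f"m{i}", np.full(16, v), scale="zscore")
               for i, v in enumerate(vals)]
        rescaled, _ = rescale_to_unit(FingerprintSet(fps))
        got = sorted(rescaled[f"m{i}"].values[0] for i in range(3))
        assert got == pytest.approx([-1.0, 0.0, 1.0])

    def test_already_unit_span_is_unchanged(self, rng):
        mat = rng.uniform(-0.9, 0.9, size=(6, 16))
        mat[0] = -1.0
        mat[1] = 1.0
        fps = [Fingerprint(f"m{i}", row, scale="zscore") for i, row in enumerate(mat)]
        rescaled, _ = rescale_to_unit(FingerprintSet(fps))
        for i in range(6):
            np.testing.assert_allclose(rescaled[f"m{i}"].values, mat[i], atol=1e-12)

    def test_each_attribute_spans_exactly_minus_one_to_one(self, rng):
        mat = rng.normal(size=(8, 16)) * rng.uniform(0.5, 3.0, size=16)
        fps = [Fingerprint(f"m{i}", row, scale="zscore") for i, row in enumerate(mat)]
        rescaled, scaler = rescale_to_unit(FingerprintSet(fps))
        out = rescaled.matrix([f"m{i}" for i in range(8)])
        np.testing.assert_allclose(out.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-12)
        # frozen scaler reproduces the same mapping for new fingerprints
        again = scaler.transform(fps[3])
        np.testing.assert_allclose(again.values, out[3], atol=1e-12)

    def test_constant_attribute_rejected_by_name(self):
        mat = np.random.default_rng(0).normal(size=(4, 16))
        mat[:, 6] = 1.5  # shininess constant across the corpus
        fps = [Fingerprint(f"m{i}", row, scale="zscore") for i, row in enumerate(mat)]
        with pytest.raises(ValueError, match="shininess"):
            rescale_to_unit(FingerprintSet(fps))


class TestFingerprintIO:
    def test_csv_round_trip_preserves_values_and_categories(self, unit_set, tmp_path):
        path = tmp_path / "fp.csv"
        unit_set.to_csv(path)
        loaded = FingerprintSet.from_csv(path)
        assert loaded.ids == unit_set.ids
        np.testing.assert_allclose(loaded.matrix(), unit_set.matrix())
        assert loaded.categories == unit_set.categories
        header = path.read_text().splitlines()[0]
        assert header == "material_id,category,scale," + ",".join(
            f"attr{i:02d}" for i in range(1, 17))
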