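"""Tanimoto drug-likeness, OB/DL filtering, and catalog intersection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet.adme import (
    FilterCriteria,
    ReferenceSet,
    catalogs_from_mapping,
    drug_likeness_index,
    filter_compounds,
    intersect_sources,
    tanimoto_similarity,
)
from herbnet.errors import DimensionError, UndefinedSimilarityError, ValidationError
from herbnet.io import CompoundRecord

nonneg_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e3, allow_nan=False), min_size=1, max_size=12
)


def _rec(cid, ob, dl):
    return CompoundRecord(compound_id=cid, chemical_name=cid, ob=ob, dl=dl)


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 2), (2, 1), 4 / 6),
        ],
    )
    def test_hand_computed_values(self, a, b, expected):
        assert tanimoto_similarity(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            tanimoto_similarity((1, 2), (1, 2, 3))

    def test_all_zero_vectors_are_an_error_not_zero(self):
        with pytest.raises(UndefinedSimilarityError):
            tanimoto_similarity((0.0, 0.0), (0.0, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(a=nonneg_vectors, b=nonneg_vectors)
    def test_symmetry_and_range_on_nonnegative_vectors(self, a, b):
        if len(a) != len(b) or (not any(a) and not any(b)):
            return
        s_ab = tanimoto_similarity(a, b)
        s_ba = tanimoto_similarity(b, a)
        assert s_ab == pytest.approx(s_ba)
        assert -1e-12 <= s_ab <= 1 + 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(
        bits_a=st.lists(st.booleans(), min_size=1, max_size=16),
        bits_b=st.lists(st.booleans(), min_size=1, max_size=16),
    )
    def test_binary_vectors_equal_jaccard(self, bits_a, bits_b):
        n = min(len(bits_a), len(bits_b))
        a, b = bits_a[:n], bits_b[:n]
        if not any(a) and not any(b):
            return
        supp_a = {i for i, x in enumerate(a) if x}
        supp_b = {i for i, x in enumerate(b) if x}
        jaccard = len(supp_a & supp_b) / len(supp_a | supp_b)
        assert tanimoto_similarity([float(x) for x in a], [float(x) for x in b]) == pytest.approx(
            jaccard
        )


class TestDrugLikeness:
    def test_equal_to_reference_centroid_scores_one(self):
        ref = ReferenceSet(np.array([[2.0, 2.0], [4.0, 4.0]]))
        assert drug_likeness_index((3, 3), ref) == pytest.approx(1.0)

    def test_orthogonal_to_centroid_scores_zero(self):
        ref = ReferenceSet(np.array([[1.0, 0.0], [1.0, 0.0]]))
        assert drug_likeness_index((0, 1), ref) == pytest.approx(0.0)

    def test_hand_computed_centroid_value(self):
        ref = ReferenceSet(np.array([[2.0, 0.0], [0.0, 2.0]]))
        # centroid (1,1); f((1,0),(1,1)) = 1 / (1 + 2 - 1) = 0.5
        assert drug_likeness_index((1, 0), ref) == pytest.approx(0.5)

    def test_mean_similarity_alternative_differs_from_centroid(self):
        ref = ReferenceSet(np.array([[2.0, 0.0], [0.0, 2.0]]))
        per_mol = np.mean(
            [tanimoto_similarity((1, 0), (2, 0)), tanimoto_similarity((1, 0), (0, 2))]
        )
        assert drug_likeness_index((1, 0), ref, method="mean_similarity") == pytest.approx(
            per_mol
        )

    def test_dimension_mismatch_rejected(self):
        ref = ReferenceSet(np.ones((3, 4)))
        with pytest.raises(DimensionError):
            drug_likeness_index((1, 2), ref)


class TestFilter:
    def test_packaged_table_all_pass(self, table1):
        kept, rejected = filter_compounds(table1, FilterCriteria())
        assert len(kept) == 70 and rejected == []

    def test_boundaries_are_inclusive(self):
        kept, rejected = filter_compounds([_rec("C1", 30.0, 0.18)], FilterCriteria())
        assert len(kept) == 1 and not rejected

    def test_rejection_reasons(self):
        records = [_rec("C1", 29.9, 0.5), _rec("C2", 50, 0.17), _rec("C3", 10, 0.01)]
        kept, rejected = filter_compounds(records, FilterCriteria())
        assert kept == []
        assert [r.reason for r in rejected] == ["low_ob", "low_dl", "both"]

    def test_partition_and_idempotence(self, table1):
        loose = FilterCriteria(ob_min=40, dl_min=0.3)
        kept, rejected = filter_compounds(table1, loose)
        assert len(kept) + len(rejected) == len(table1)
        assert kept + [r.record for r in rejected] != []  # partition covers input
        assert {r.compound_id for r in kept} | {
            r.record.compound_id for r in rejected
        } == {r.compound_id for r in table1}
        kept_again, rejected_again = filter_compounds(kept, loose)
        assert kept_again == kept and rejected_again == []


class TestIntersectSources:
    def test_two_catalogs(self):
        report = intersect_sources(
            catalogs_from_mapping({"A": {"x", "y"}, "B": {"y", "z"}})
        )
        assert report.shared_by_all == 1
        assert report.shared_names == {"y"}

    def test_identical_catalogs_idempotent(self):
        names = {f"m{i}" for i in range(5)}
        report = intersect_sources(catalogs_from_mapping({"A": names, "B": names, "C": names}))
        assert report.shared_by_all == 5

    def test_case_insensitive_canonicalization(self):
        report = intersect_sources(
            catalogs_from_mapping({"A": {"Quercetin"}, "B": {"quercetin"}})
        )
        assert report.shared_by_all == 1

    def test_duplicate_source_name_rejected(self):
        cats = catalogs_from_mapping({"A": {"x"}}) * 2
        with pytest.raises(ValidationError):
            intersect_sources(cats)

    def test_planted_common_core_recovered(self):
        core = {f"core{i}" for i in range(70)}
        sizes = {"db1": 649, "db2": 142, "db3": 455}
        catalogs = {}
        for name, size in sizes.items():
            extra = {f"{name}_only_{i}" for i in range(size - 70)}
            catalogs[name] = core | extra
        report = intersect_sources(catalogs_from_mapping(catalogs))
        assert report.shared_by_all == 70
        assert all(len(c) == s for c, s in zip(catalogs.values(), sizes.values()))

    def test_counts_agree_with_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        universe = [f"n{i}" for i in range(100)]
        for trial in range(20):
            k = int(rng.integers(2, 5))
            cats = {
                f"s{j}": {u for u in universe if rng.random() < 0.4} or {"n0"}
                for j in range(k)
            }
            report = intersect_sources(catalogs_from_mapping(cats))
            # brute force over every name's membership pattern
            by_count = {i: 0 for i in range(1, k + 1)}
            for name in {u for members in cats.values() for u in members}:
                cnt = sum(name in members for members in cats.values())
                by_count[cnt] += 1
            assert report.by_count == by_count
            assert report.shared_by_all == by_count[k]
            for (a, b), size in report.pairwise.items():
                assert size == len(cats[a] & cats[b])
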