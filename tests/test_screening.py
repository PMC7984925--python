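import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmnet.model import CompoundTargetMap
from qmnet.screening import (
    Fingerprint,
    ReferenceLigand,
    intersect_with_disease,
    predict_targets,
    tanimoto,
)


def fp(bits):
    return Fingerprint(np.array(bits, dtype=np.uint8))


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        a = fp([1, 0, 1, 1])
        assert tanimoto(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(fp([1, 1, 0, 0]), fp([0, 0, 1, 1])) == 0.0

    def test_set_arithmetic(self):
        # |a|=3, |b|=4, 2 shared -> 2 / (3 + 4 - 2) = 0.4
        a = fp([1, 1, 1, 0, 0, 0])
        b = fp([1, 1, 0, 1, 1, 0])
        assert tanimoto(a, b) == pytest.approx(0.4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto(fp([1, 0]), fp([1, 0, 0]))

    def test_double_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto(fp([0, 0, 0]), fp([0, 0, 0]))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=64),
        st.lists(st.integers(0, 1), min_size=1, max_size=64),
    )
    def test_symmetric_and_bounded(self, xs, ys):
        n = max(len(xs), len(ys))
        xs = xs + [0] * (n - len(xs))
        ys = ys + [0] * (n - len(ys))
        if sum(xs) + sum(ys) == 0:
            xs[0] = 1
        a, b = fp(xs), fp(ys)
        s = tanimoto(a, b)
        assert s == tanimoto(b, a)
        assert 0.0 <= s <= 1.0
        assert (s == 1.0) == (xs == ys)


class TestPredictTargets:
    def _library(self):
        return [
            ReferenceLigand("l1", fp([1, 1, 0, 0]), frozenset({"AKT1", "TNF"})),
            ReferenceLigand("l2", fp([0, 0, 1, 1]), frozenset({"EGFR"})),
            ReferenceLigand("l3", fp([1, 0, 1, 0]), frozenset({"VEGFA"})),
        ]

    def test_identity_ligand_transfers_its_targets(self):
        out = predict_targets(fp([1, 1, 0, 0]), self._library(), threshold=0.8)
        assert out == {"AKT1", "TNF"}

    def test_nothing_above_threshold_gives_empty_set(self):
        assert predict_targets(fp([0, 1, 1, 0]), self._library(), threshold=0.9) == set()

    def test_union_over_passing_ligands_matches_brute_force(self):
        query = fp([1, 1, 1, 0])
        library = self._library()
        threshold = 0.5
        # independent brute-force scan
        expected = set()
        for lig in library:
            inter = int(np.sum(query.bits & lig.fingerprint.bits))
            union = int(np.sum(query.bits | lig.fingerprint.bits))
            if inter / union > threshold:
                expected |= lig.targets
        got = predict_targets(query, library, threshold)
        assert got == expected
        assert got == {"AKT1", "TNF", "VEGFA"}

    def test_monotone_in_threshold(self, synthetic_study):
        query = next(iter(synthetic_study.query_fingerprints.values()))
        lib = synthetic_study.library
        prev = None
        for thr in (0.0, 0.2, 0.5, 0.8, 0.95):
            cur = predict_targets(query, lib, thr)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_threshold_is_strict(self):
        # a ligand exactly at the threshold must not contribute
        lib = [ReferenceLigand("l", fp([1, 1, 0, 0]), frozenset({"X"}))]
        query = fp([1, 1, 1, 1])  # similarity exactly 0.5
        assert predict_targets(query, lib, threshold=0.5) == set()
        assert predict_targets(query, lib, threshold=0.49) == {"X"}


class TestIntersectWithDisease:
    def test_common_sets_are_subsets_of_both_inputs(self, reference_target_map):
        disease = {"LGALS3", "CA1", "VEGFA", "NOT_A_TARGET"}
        res = intersect_with_disease(reference_target_map, disease)
        for cid, common in res.common_targets.entries.items():
            assert common <= reference_target_map.entries[cid]
            assert common <= disease
        assert res.common_targets.union() <= disease

    def test_active_and_excluded_partition_compounds(self, reference_target_map):
        res = intersect_with_disease(reference_target_map, {"LGALS3"})
        all_ids = set(reference_target_map.entries)
        assert set(res.active_compounds) | set(res.excluded_compounds) == all_ids
        assert set(res.active_compounds) & set(res.excluded_compounds) == set()
        assert res.venn.n_common == 1

    def test_empty_disease_excludes_everything_with_warning(self, reference_target_map):
        with pytest.warns(UserWarning, match="empty disease"):
            res = intersect_with_disease(reference_target_map, set())
        assert res.active_compounds == []
        assert res.venn.n_common == 0

    def test_venn_counts_equal_generator_truth(self, synthetic_study):
        res = intersect_with_disease(
            synthetic_study.predicted_targets, synthetic_study.disease_genes
        )
        truth = synthetic_study.truth
        assert res.venn == truth.expected_venn
        assert res.common_targets.entries == {
            cid: genes for cid, genes in truth.expected_common.items()
        }

    def test_n_common_is_union_size(self):
        tmap = CompoundTargetMap(entries={"a": {"X", "Y"}, "b": {"Y", "Z"}})
        res = intersect_with_disease(tmap, {"X", "Y", "Z"})
        assert res.venn.n_common == 3
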