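import numpy as np
import pytest

from duptrace import duplication as dup
from duptrace.distances import DistanceMatrix
from duptrace.io import DataError, GroupMap
from duptrace.segmentation import Cactus, Segmentation
from duptrace.simulate import SimConfig, simulate_family


def make_cactus(labels, values, columns=(0,)):
    return Cactus(matrix=DistanceMatrix(tuple(labels), np.array(values, float)), columns=tuple(columns))


def make_seg(cacti, labels):
    n_cols = sum(len(c.columns) for c in cacti)
    path = np.concatenate([[k] * len(c.columns) for k, c in enumerate(cacti)])
    cols = tuple(sorted(c for cactus in cacti for c in cactus.columns))
    return Segmentation(
        cacti=cacti,
        path=path,
        analyzed_columns=cols,
        full_path=path,
        switch_penalty=0.1,
        n_iterations=0,
        total_cost=0.0,
        labels=tuple(labels),
    )


class TestWithinSpeciesExtreme:
    def test_two_sequences_single_distance(self):
        labels = ["s1_A", "s1_B"]
        cactus = make_cactus(labels, [[0, 0.7], [0.7, 0]])
        groups = GroupMap(
            species={"s1_A": "s1", "s1_B": "s1"}, group={"s1_A": "g", "s1_B": "g"}
        )
        res = dup.within_species_extreme(cactus, groups, "s1")
        assert res.distance == 0.7
        assert res.pair == ("s1_A", "s1_B")

    def test_identical_sequences_zero(self):
        labels = ["s1_A", "s1_B"]
        cactus = make_cactus(labels, np.zeros((2, 2)))
        groups = GroupMap(
            species={"s1_A": "s1", "s1_B": "s1"}, group={"s1_A": "g", "s1_B": "g"}
        )
        assert dup.within_species_extreme(cactus, groups, "s1").distance == 0.0

    def test_four_sequences_brute_force_max(self):
        rng = np.random.default_rng(3)
        labels = [f"s1_{k}" for k in "wxyz"]
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        cactus = make_cactus(labels, m)
        groups = GroupMap(
            species={l: "s1" for l in labels}, group={l: "g" for l in labels}
        )
        res = dup.within_species_extreme(cactus, groups, "s1")
        expect = max(m[i, j] for i in range(4) for j in range(i + 1, 4))
        assert res.distance == pytest.approx(expect)

    def test_single_sequence_species_rejected(self):
        cactus = make_cactus(["s1_A"], [[0.0]])
        groups = GroupMap(species={"s1_A": "s1"}, group={"s1_A": "g"})
        with pytest.raises(DataError):
            dup.within_species_extreme(cactus, groups, "s1")


class TestDiscriminationScores:
    def two_species_setup(self, d1, d2):
        labels = ["s1_A", "s1_B", "s2_A", "s2_B"]
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = d1
        vals[2, 3] = vals[3, 2] = d2
        groups = GroupMap(
            species={l: l.split("_")[0] for l in labels},
            group={l: "g" for l in labels},
        )
        return make_cactus(labels, vals), groups, labels

    def test_single_cactus_normalizes_to_one(self):
        cactus, groups, labels = self.two_species_setup(0.4, 0.2)
        seg = make_seg([cactus], labels)
        (score,) = dup.discrimination_scores(seg, groups)
        assert score.raw == pytest.approx(0.3)  # mean of 0.4 and 0.2
        assert score.normalized == 1.0
        assert score.n_species_used == 2

    def test_all_zero_raw_gives_zero_normalized(self):
        cactus, groups, labels = self.two_species_setup(0.0, 0.0)
        seg = make_seg([cactus], labels)
        (score,) = dup.discrimination_scores(seg, groups)
        assert score.raw == 0.0 and score.normalized == 0.0

    def test_hand_computed_two_cacti(self):
        c1, groups, labels = self.two_species_setup(1.0, 0.8)
        c2, _, _ = self.two_species_setup(0.2, 0.0)
        c2 = Cactus(matrix=c2.matrix, columns=(1,))
        seg = make_seg([c1, c2], labels)
        s1, s2 = dup.discrimination_scores(seg, groups)
        assert s1.raw == pytest.approx(0.9)
        assert s2.raw == pytest.approx(0.1)
        assert s1.normalized == 1.0
        assert s2.normalized == pytest.approx(0.1 / 0.9)

    def test_no_multicopy_species_rejected(self):
        labels = ["s1_A", "s2_A"]
        cactus = make_cactus(labels, np.zeros((2, 2)))
        groups = GroupMap(
            species={"s1_A": "s1", "s2_A": "s2"}, group={l: "g" for l in labels}
        )
        seg = make_seg([cactus], labels)
        with pytest.raises(DataError):
            dup.discrimination_scores(seg, groups)

    def test_normalization_is_idempotent(self):
        c1, groups, labels = self.two_species_setup(1.0, 0.6)
        c2, _, _ = self.two_species_setup(0.3, 0.1)
        c2 = Cactus(matrix=c2.matrix, columns=(1,))
        seg = make_seg([c1, c2], labels)
        scores = dup.discrimination_scores(seg, groups)
        normalized = [s.normalized for s in scores]
        renorm = [v / max(normalized) for v in normalized]
        assert renorm == pytest.approx(normalized)


def score(idx, normalized):
    return dup.DiscriminationScore(idx, normalized, normalized, 2)


class TestClassifyCacti:
    def test_clear_separation(self):
        labels = dup.classify_cacti([score(0, 1.0), score(1, 0.1)])
        assert labels == ["duplication", "concerted"]

    def test_all_zero_scores_concerted(self):
        labels = dup.classify_cacti([score(0, 0.0), score(1, 0.0)])
        assert labels == ["concerted", "concerted"]

    def test_boundary_is_duplication(self):
        assert dup.classify_cacti([score(0, 0.9)], threshold=0.9) == ["duplication"]

    def test_top_k(self):
        scores = [score(0, 1.0), score(1, 0.95), score(2, 0.2)]
        assert dup.classify_cacti(scores, top_k=1) == [
            "duplication", "concerted", "concerted",
        ]
        assert dup.classify_cacti(scores, top_k=2) == [
            "duplication", "duplication", "concerted",
        ]


class TestDiagnosticSites:
    def seg_with_columns(self):
        labels = ["s1_A", "s1_B", "s2_A", "s2_B"]
        c1 = make_cactus(labels, np.zeros((4, 4)), columns=(2, 6, 8))
        c2 = make_cactus(labels, np.zeros((4, 4)), columns=(0, 1))
        return make_seg([c1, c2], labels)

    def test_no_duplication_label_empty(self):
        seg = self.seg_with_columns()
        assert dup.diagnostic_sites(seg, ["concerted", "concerted"]) == []

    def test_columns_reported_one_based_sorted(self):
        seg = self.seg_with_columns()
        assert dup.diagnostic_sites(seg, ["duplication", "concerted"]) == [3, 7, 9]

    def test_disjoint_from_concerted_columns(self):
        seg = self.seg_with_columns()
        sites = dup.diagnostic_sites(seg, ["duplication", "concerted"])
        concerted = set(seg.cacti[1].columns_1based)
        assert not set(sites) & concerted

    def test_label_count_mismatch(self):
        seg = self.seg_with_columns()
        with pytest.raises(DataError):
            dup.diagnostic_sites(seg, ["duplication"])


class TestDiscoverEndToEnd:
    def test_recovers_diagnostic_block_without_erosion(self, default_family):
        cfg, (aln, groups, sig, truth) = default_family
        result = dup.discover(aln, groups)
        rec, tru = set(result.sites), set(truth.diagnostic_columns)
        precision = len(rec & tru) / len(rec)
        recall = len(rec & tru) / len(tru)
        assert precision >= 0.8
        assert recall >= 0.8
        report = result.report()
        assert set(report["column"]) == rec
        assert (report["normalized_score"] >= 0.9).all()

    def test_sites_subset_of_analyzed_columns(self, default_family):
        cfg, (aln, groups, sig, truth) = default_family
        result = dup.discover(aln, groups)
        analyzed_1based = {c + 1 for c in result.segmentation.analyzed_columns}
        assert set(result.sites) <= analyzed_1based
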