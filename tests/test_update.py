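"""Dereplication, assignment, new-taxon definition, voting, rebuilds, refine."""

import copy

import numpy as np
import pytest

from sbtax.database import SaturationError, build_database, default_manifest
from sbtax.kmers import RANKS, KmerSignature
from sbtax.similarity import ani_from_jaccard, jaccard
from sbtax.taxonomy import Lineage
from sbtax.update import (BatchGenome, UpdateBatch, apply_update, dereplicate,
                          rebuild_branch, refine_references)

K = 15


def sig_with_jaccard(base: np.ndarray, target_j: float, offset: int) -> KmerSignature:
    """A set sharing exactly the right number of elements with ``base``."""
    n = base.size
    inter = int(round(2 * n * target_j / (1 + target_j)))
    foreign = np.arange(2**45 + offset * 10**7, 2**45 + offset * 10**7 + (n - inter),
                        dtype=np.uint64)
    return KmerSignature(K, np.sort(np.concatenate([base[:inter], foreign])))


def ani_target(target_ani: float) -> float:
    """Jaccard similarity that maps to a wanted ANI percent at k=15."""
    import math
    s = math.exp(K * (target_ani / 100.0 - 1.0))  # 2j/(1+j)
    return s / (2.0 - s)


class TestDereplicate:
    def setup_method(self):
        self.base = np.arange(10_000, dtype=np.uint64)
        self.a = BatchGenome("A", KmerSignature(K, self.base))

    def test_exact_duplicate_of_db_genome_dropped(self):
        db_entries = [("ref1", KmerSignature(K, self.base))]
        kept, dropped = dereplicate([self.a], db_entries, threshold=99.0)
        assert kept == []
        assert dropped == [("A", "ref1", 100.0)]

    def test_greedy_chain(self):
        # ANI(A,B) ≈ 99.2, ANI(B,C) ≈ 99.1, ANI(A,C) ≈ 98.5: keep {A, C}
        jab = ani_target(99.2)
        jac = ani_target(98.5)
        b = sig_with_jaccard(self.base, jab, offset=1)
        c = sig_with_jaccard(self.base, jac, offset=2)
        assert ani_from_jaccard(jaccard(self.a.signature, b), K) >= 99.0
        assert ani_from_jaccard(jaccard(self.a.signature, c), K) < 99.0
        batch = [self.a, BatchGenome("B", b), BatchGenome("C", c)]
        kept, dropped = dereplicate(batch, [], threshold=99.0)
        assert [g.genome_id for g in kept] == ["A", "C"]
        assert len(dropped) == 1 and dropped[0][:2] == ("B", "A")

    def test_threshold_100_keeps_distinct(self):
        b = sig_with_jaccard(self.base, 0.9, offset=3)
        kept, dropped = dereplicate(
            [self.a, BatchGenome("B", b)], [], threshold=100.0)
        assert len(kept) == 2 and dropped == []


class TestAssignment:
    def test_near_identical_trio_co_assigned(self, mini_db, mini_scenario):
        # three close mutants of the S4 centroid: the first species hit
        # triggers batch clustering that co-assigns the whole block
        from sbtax.kmers import extract_kmers
        from sbtax.simulate import mutate
        db = mini_db
        anchor = db.clusters["species"]["S4"].centroid_id
        rng = np.random.default_rng(7)
        lut = np.zeros(256, dtype=np.uint8)
        lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
        codes = lut[np.frombuffer(mini_scenario["genomes"][anchor].encode(),
                                  dtype=np.uint8)]
        trio = {}
        for i, rate in enumerate((0.004, 0.005, 0.006)):
            seq = "".join("ACGT"[c] for c in mutate(codes, rate, rng))
            trio[f"q{i}"] = extract_kmers([seq], K)
        batch = UpdateBatch([BatchGenome(g, s) for g, s in sorted(trio.items())],
                            dereplication_threshold=99.9)
        report = apply_update(db, batch)
        assert report.assigned == {"q0": "S4", "q1": "S4", "q2": "S4"}
        assert not any(v for v in report.new_clusters.values())

    def test_conservation_of_batch_genomes(self, mini_db, mini_scenario):
        sigs = mini_scenario["signatures"]
        ids = ["S1_05", "S2_05", "S3_05"]
        batch = UpdateBatch(
            [BatchGenome(g, sigs[g]) for g in ids]
            + [BatchGenome("S1_05_dup", sigs["S1_05"])])  # dereplicates away
        report = apply_update(mini_db, batch)
        n_new_members = sum(n for r in RANKS for _, n in report.new_clusters[r]
                            if r == "species")
        total = (len(report.assigned) + n_new_members + len(report.dereplicated)
                 + len(report.unassigned))
        assert total == 4

    def test_empty_batch_is_noop(self, mini_db):
        before = copy.deepcopy(mini_db.clusters["species"])
        report = apply_update(mini_db, UpdateBatch([]))
        assert report.assigned == {} and report.dereplicated == []
        assert set(mini_db.clusters["species"]) == set(before)


class TestQualityGate:
    def test_fail_tier_excluded_before_dereplication(self, mini_db,
                                                     mini_scenario):
        sigs = mini_scenario["signatures"]
        batch = UpdateBatch(
            [BatchGenome("dirty", sigs["S1_05"], completeness=80,
                         contamination=25),
             BatchGenome("clean", sigs["S2_05"], completeness=80,
                         contamination=2)],
            quality_gate=True)
        report = apply_update(mini_db, batch)
        assert report.excluded_quality == ["dirty"]
        assert "dirty" not in mini_db.records
        assert "clean" in report.assigned or "clean" in mini_db.records

    def test_gate_off_by_default(self, mini_db, mini_scenario):
        sigs = mini_scenario["signatures"]
        report = apply_update(mini_db, UpdateBatch(
            [BatchGenome("dirty", sigs["S3_05"], completeness=80,
                         contamination=25)]))
        assert report.excluded_quality == []
        assert "dirty" in mini_db.records


class TestNewClusters:
    def test_two_tight_blocks_make_exactly_two_species(self, mini_db):
        # 6 genomes queued under genus G1 in two tight ANI blocks
        from sbtax.profile import partial_lineage  # noqa: F401  (context)
        from sbtax.similarity import PairwiseMatrix
        from sbtax.update import define_new_clusters
        db = mini_db
        prefix = db.lineage_of_cluster("genus", "G1")
        ids = [f"q{i}" for i in range(6)]
        values = np.full((6, 6), 80.0)
        values[:3, :3] = 99.0
        values[3:, 3:] = 99.0
        np.fill_diagonal(values, 100.0)
        matrix = PairwiseMatrix(ids, values)
        dummy = KmerSignature(K, np.arange(100, dtype=np.uint64))
        queued = [(BatchGenome(g, dummy), prefix) for g in ids]
        before = db.manifest["msbt_counter"]
        lineages, created = define_new_clusters(queued, db, matrix)
        assert len(created["species"]) == 2
        assert {n for _, n in created["species"]} == {3}
        assert all(r == "species" or not v for r, v in created.items())
        blocks = {}
        for g, lin in lineages.items():
            assert lin.prefix(6) == prefix        # stays under genus G1
            blocks.setdefault(lin["species"], set()).add(g)
        assert sorted(map(sorted, blocks.values())) == [
            ["q0", "q1", "q2"], ["q3", "q4", "q5"]]
        assert db.manifest["msbt_counter"] == before + 2

    def test_unseen_genus_recovered_with_consistent_species(self, mini_scenario):
        # drop genus G3 from the baseline; its strains must come back as new
        # clusters whose species partition matches the planted truth
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        train = [g for g in sorted(sigs) if lineages[g]["genus"] != "G3"]
        db = build_database([(g, sigs[g], lineages[g]) for g in train],
                            default_manifest(K))
        test = [g for g in sorted(sigs) if lineages[g]["genus"] == "G3"]
        report = apply_update(db, UpdateBatch(
            [BatchGenome(g, sigs[g]) for g in test]))
        assert report.assigned == {} and report.unassigned == []
        new_species = report.new_clusters["species"]
        assert sum(n for _, n in new_species) == len(test)
        for label, _ in new_species:
            members = db.clusters["species"][label].genomes
            assert len({lineages[g]["species"] for g in members}) == 1
        # every new species label is unknown and strictly fresh
        assert all(lab.startswith("MSBT") for lab, _ in new_species)

    def test_msbt_labels_strictly_increase_across_updates(self, mini_scenario):
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        train = [g for g in sorted(sigs)
                 if lineages[g]["species"] not in ("S2", "S3")]
        db = build_database([(g, sigs[g], lineages[g]) for g in train],
                            default_manifest(K))
        first = apply_update(db, UpdateBatch(
            [BatchGenome(g, sigs[g]) for g in sorted(sigs)
             if lineages[g]["species"] == "S2"]))
        second = apply_update(db, UpdateBatch(
            [BatchGenome(g, sigs[g]) for g in sorted(sigs)
             if lineages[g]["species"] == "S3"]))
        nums1 = [int(lab[4:]) for lab, _ in first.new_clusters["species"]]
        nums2 = [int(lab[4:]) for lab, _ in second.new_clusters["species"]]
        assert nums1 and nums2
        assert max(nums1) < min(nums2)

    def test_singleton_queued_genome_gets_singleton_species(self, mini_db,
                                                            mini_scenario):
        # heavily diverged strain: outside its species, inside upper ranks
        rng = np.random.default_rng(42)
        from sbtax.kmers import extract_kmers
        from sbtax.simulate import mutate
        lut = np.zeros(256, dtype=np.uint8)
        lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
        codes = lut[np.frombuffer(mini_scenario["genomes"]["S7_01"].encode(),
                                  dtype=np.uint8)]
        seq = "".join("ACGT"[c] for c in mutate(codes, 0.06, rng))
        sig = extract_kmers([seq], K)
        report = apply_update(mini_db, UpdateBatch([BatchGenome("mut", sig)]))
        new_species = report.new_clusters["species"]
        assert len(new_species) == 1 and new_species[0][1] == 1
        assert report.assigned == {}


class TestReferenceIntegration:
    def _db_missing_s2(self, mini_scenario):
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        train = [g for g in sorted(sigs) if lineages[g]["species"] != "S2"]
        return build_database([(g, sigs[g], lineages[g]) for g in train],
                              default_manifest(K))

    def test_unknown_cluster_inherits_reference_taxonomy(self, mini_scenario):
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        db = self._db_missing_s2(mini_scenario)
        mags = [g for g in sorted(sigs) if lineages[g]["species"] == "S2"][:3]
        report = apply_update(db, UpdateBatch(
            [BatchGenome(g, sigs[g]) for g in mags]))
        (msbt_label, _), = report.new_clusters["species"]
        assert msbt_label.startswith("MSBT")
        # a reference with the true lineage lands in the unknown cluster
        ref = [g for g in sorted(sigs) if lineages[g]["species"] == "S2"][3]
        report2 = apply_update(db, UpdateBatch([BatchGenome(
            ref, sigs[ref], genome_type="reference", lineage=lineages[ref])]))
        assert (msbt_label, "S2") in report2.relabeled_clusters
        assert "S2" in db.clusters["species"]
        assert db.clusters["species"]["S2"].is_known

    def test_majority_vote_keeps_dominant_label(self, mini_db, mini_scenario):
        # two references with a minority (wrong) species label join S3:
        # majority of member references still says S3
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        wrong = lineages["S3_01"].with_rank("species", "Imposter")
        mags = [g for g in sorted(sigs) if g.startswith("S3_") and g.endswith("_05")]
        batch = UpdateBatch([
            BatchGenome("odd_ref", sigs[mags[0]], genome_type="reference",
                        lineage=wrong)])
        report = apply_update(mini_db, batch)
        assert report.assigned.get("odd_ref") == "S3"
        assert ("S3", "Imposter") not in report.relabeled_clusters
        assert "S3" in mini_db.clusters["species"]


class TestRebuild:
    def test_rebuild_is_fixed_point(self, mini_db):
        db = mini_db
        before = {
            (rank, label): tree.filter.words.copy()
            for rank in RANKS for label, tree in db.trees[rank].items()
        }
        rebuild_branch(db, ["S1"])
        for (rank, label), words in before.items():
            assert np.array_equal(db.trees[rank][label].filter.words, words)

    def test_untouched_branches_bit_identical_after_update(
            self, mini_db, mini_scenario):
        db = mini_db
        sigs = mini_scenario["signatures"]
        before = {label: tree.filter.words.copy()
                  for label, tree in db.trees["species"].items()}
        report = apply_update(db, UpdateBatch([BatchGenome("q", sigs["S8_05"])]))
        assert report.assigned == {"q": "S8"}
        for label, words in before.items():
            if label != "S8":
                assert np.array_equal(db.trees["species"][label].filter.words,
                                      words)
        assert not np.array_equal(db.trees["species"]["S8"].filter.words,
                                  before["S8"])

    def test_saturation_error_names_node(self, mini_db, mini_scenario):
        db = mini_db
        # shrink the planned size of S6 drastically and rebuild
        db.manifest["plan"]["sizes"]["species"]["S6"] = 64
        with pytest.raises(SaturationError, match="S6"):
            rebuild_branch(db, ["S6"])


class TestRefineReferences:
    def test_planted_minority_mislabel_flagged(self):
        rng = np.random.default_rng(17)
        base = np.unique(rng.integers(0, 2**40, 8000).astype(np.uint64))
        sigs, ids, labels = [], [], {}
        for i in range(6):
            noise = np.arange(2**44 + i * 100, 2**44 + i * 100 + 50, dtype=np.uint64)
            sigs.append(KmerSignature(K, np.sort(np.concatenate([base[:-50], noise]))))
            ids.append(f"g{i}")
            labels[f"g{i}"] = "X" if i < 5 else "Y"
        result = refine_references(ids, sigs, labels, cut=95.0)
        assert result.misclassified == ["g5"]
        assert result.cluster_labels == ["X"]
        assert result.vanished == ["Y"]

    def test_two_clade_species_numbered_by_size(self, mini_scenario):
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        ids = [g for g in sorted(sigs)
               if lineages[g]["species"] in ("S1", "S2", "S4")]
        # S1 (5 genomes) and S2 (5 genomes) share one label; S4 keeps its own
        labels = {g: ("SX" if lineages[g]["species"] in ("S1", "S2") else "S4")
                  for g in ids}
        result = refine_references(ids, [sigs[g] for g in ids], labels, cut=95.0)
        assert result.clades == {"SX": ["SX|c1", "SX|c2"]}
        assert result.misclassified == []
        assert result.vanished == []

    def test_all_correct_and_separated(self, mini_scenario):
        sigs = mini_scenario["signatures"]
        lineages = mini_scenario["lineages"]
        ids = [g for g in sorted(sigs)
               if lineages[g]["species"] in ("S1", "S5", "S9")]
        labels = {g: lineages[g]["species"] for g in ids}
        result = refine_references(ids, [sigs[g] for g in ids], labels)
        assert result.misclassified == []
        assert result.vanished == []
        assert sorted(result.cluster_labels) == ["S1", "S5", "S9"]
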