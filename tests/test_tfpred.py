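"""TF predictor: standardization, featurization, costs, CV metrics, consensus."""

import numpy as np
import pytest

from cmpnomics import (
    CVConfig,
    EmbeddingTable,
    SeqRecord,
    SeqRecordSet,
    class_costs,
    consensus_candidates,
    cross_validate,
    featurize,
    generate_tf_benchmark,
    standardize,
)
from cmpnomics.tfpred import FoldMetrics


def records_of(*seqs, label="TF"):
    return SeqRecordSet(records=[SeqRecord(id=f"s{i}", sequence=s, label=label)
                                 for i, s in enumerate(seqs)])


class TestStandardize:
    def test_exact_length_unchanged(self):
        seq = "ACDEF" * 200  # 1000 residues
        out = standardize(records_of(seq), 1000)
        assert out.records[0].sequence == seq

    def test_truncation_keeps_prefix(self):
        seq = "ACDEF" * 240  # 1200 residues
        out = standardize(records_of(seq), 1000)
        assert out.records[0].sequence == seq[:1000]

    def test_padding_appends_x(self):
        out = standardize(records_of("ACDEFGHIKL"), 1000)
        s = out.records[0].sequence
        assert len(s) == 1000
        assert s.startswith("ACDEFGHIKL")
        assert set(s[10:]) == {"X"}

    def test_labels_and_ids_preserved(self):
        out = standardize(records_of("ACD", "EFG"), 10)
        assert out.ids == ["s0", "s1"]
        assert out.labels == ["TF", "TF"]

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            records_of("ACDZ1")


class TestFeaturize:
    def test_single_letter_composition(self):
        emb = featurize(records_of("AAAA"))
        v = emb.vectors["s0"]
        assert emb.dimension == 420
        assert v[0] > 0  # A composition
        assert np.all(v[1:20] == 0)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_identical_sequences_identical_vectors(self):
        emb = featurize(records_of("MKVLAW" * 10, "MKVLAW" * 10))
        assert np.array_equal(emb.vectors["s0"], emb.vectors["s1"])

    def test_padding_is_feature_neutral(self):
        raw = records_of("MKVLAWHH" * 5)
        padded = standardize(raw, 500)
        assert np.allclose(featurize(raw).vectors["s0"], featurize(padded).vectors["s0"])

    def test_external_table_passthrough_and_coverage(self):
        recs = records_of("ACD", "EFG")
        table = EmbeddingTable(vectors={"s0": np.ones(8), "s1": np.zeros(8)}, dimension=8,
                               source="external_table")
        assert featurize(recs, "external_table", table) is table
        partial = EmbeddingTable(vectors={"s0": np.ones(8)}, dimension=8)
        with pytest.raises(KeyError, match="s1"):
            featurize(recs, "external_table", partial)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            EmbeddingTable(vectors={"a": np.ones(3), "b": np.ones(4)}, dimension=3)

    def test_embedding_tsv_round_trip(self, tmp_path):
        table = EmbeddingTable(vectors={"a": np.array([1.0, 2.5]), "b": np.array([0.0, -1.0])},
                               dimension=2)
        table.to_tsv(tmp_path / "e.tsv")
        back = EmbeddingTable.from_tsv(tmp_path / "e.tsv")
        assert back.dimension == 2
        assert np.allclose(back.vectors["a"], [1.0, 2.5])


class TestClassCosts:
    def test_balanced_labels_equal_costs(self):
        costs = class_costs(["TF"] * 10 + ["NTF"] * 10)
        assert costs["TF"] == costs["NTF"] == 1.0

    def test_benchmark_composition_ratio(self):
        """NTF=2784, TF=954 -> cost(TF)/cost(NTF) = 2784/954 ~ 2.918."""
        costs = class_costs(["NTF"] * 2784 + ["TF"] * 954)
        assert costs["TF"] / costs["NTF"] == pytest.approx(2784 / 954)
        assert costs["TF"] / costs["NTF"] == pytest.approx(2.918, abs=1e-3)

    def test_ninety_ten_gives_nine_to_one(self):
        costs = class_costs(["a"] * 90 + ["b"] * 10)
        assert costs["b"] / costs["a"] == pytest.approx(9.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            class_costs(["TF"] * 5)


class TestFoldMetrics:
    def test_hand_computed_confusion(self):
        m = FoldMetrics(tp=40, fn=10, tn=80, fp=20)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.8)
        assert m.balanced_accuracy == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 * 40 / (2 * 40 + 20 + 10))

    def test_metric_identities_on_random_confusions(self):
        """F1, sensitivity, specificity, balanced accuracy satisfy their formulas."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, size=4))
            m = FoldMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
            sens = tp / (tp + fn) if tp + fn else 0.0
            spec = tn / (tn + fp) if tn + fp else 0.0
            assert m.sensitivity == pytest.approx(sens)
            assert m.specificity == pytest.approx(spec)
            assert m.balanced_accuracy == pytest.approx((sens + spec) / 2)
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
            for value in (m.sensitivity, m.specificity, m.balanced_accuracy, m.f1):
                assert 0.0 <= value <= 1.0


def separable_embeddings(n_tf=30, n_ntf=60, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    records, vectors = [], {}
    for i in range(n_tf):
        rid = f"tf{i}"
        records.append(SeqRecord(id=rid, sequence="ACDEFGHIKL", label="TF"))
        vectors[rid] = rng.normal(gap, 0.1, size=5)
    for i in range(n_ntf):
        rid = f"ntf{i}"
        records.append(SeqRecord(id=rid, sequence="ACDEFGHIKL", label="NTF"))
        vectors[rid] = rng.normal(-gap, 0.1, size=5)
    return SeqRecordSet(records=records), EmbeddingTable(vectors=vectors, dimension=5)


class TestCrossValidate:
    def test_perfectly_separable_gives_perfect_metrics(self):
        recs, emb = separable_embeddings()
        report = cross_validate(recs, emb, CVConfig(folds=5, standard_length=10, seed=1))
        for fold in report.per_fold:
            assert fold.balanced_accuracy == 1.0 and fold.f1 == 1.0
        assert set(report.consensus_candidates()) == {r.id for r in recs.records if r.label == "TF"}

    def test_seed_determinism(self):
        recs, emb = separable_embeddings(seed=3)
        cfg = CVConfig(folds=5, standard_length=10, seed=7)
        r1 = cross_validate(recs, emb, cfg)
        r2 = cross_validate(recs, emb, cfg)
        assert [f.to_dict() for f in r1.per_fold] == [f.to_dict() for f in r2.per_fold]
        assert r1.consensus == r2.consensus

    def test_single_class_rejected(self):
        recs = records_of("ACDEFGHIKL", "ACDEFGHIKM", label="TF")
        with pytest.raises(ValueError, match="single-class"):
            cross_validate(recs, config=CVConfig(folds=2, standard_length=10))

    def test_class_smaller_than_folds_rejected(self):
        records = [SeqRecord(id=f"s{i}", sequence="ACDEFGHIKL", label="TF" if i < 3 else "NTF")
                   for i in range(20)]
        with pytest.raises(ValueError, match="folds"):
            cross_validate(SeqRecordSet(records=records), config=CVConfig(folds=5, standard_length=10))

    def test_report_serialization(self, tmp_path):
        recs, emb = separable_embeddings()
        report = cross_validate(recs, emb, CVConfig(folds=3, standard_length=10, seed=0))
        report.to_json(tmp_path / "cv.json")
        report.per_fold_tsv(tmp_path / "folds.tsv")
        import json

        payload = json.loads((tmp_path / "cv.json").read_text())
        assert len(payload["per_fold"]) == 3
        assert "balanced_accuracy" in payload["means"]
        assert "consensus TF candidates" in report.summary()


class TestConsensus:
    def _report_with(self, fractions):
        recs, emb = separable_embeddings(n_tf=5, n_ntf=10)
        report = cross_validate(recs, emb, CVConfig(folds=5, standard_length=10, seed=0))
        report.consensus = dict(fractions)
        return report

    def test_zero_fraction_always_excluded(self):
        report = self._report_with({"a": 0.0, "b": 1.0})
        assert consensus_candidates(report, 0.01) == ["b"]

    def test_boundary_fraction_included(self):
        report = self._report_with({"a": 0.5})
        assert consensus_candidates(report, 0.5) == ["a"]

    def test_rule_application(self):
        report = self._report_with({"a": 0.6, "b": 0.4})
        assert consensus_candidates(report, 0.5) == ["a"]

    def test_invalid_threshold_rejected(self):
        report = self._report_with({"a": 0.6})
        with pytest.raises(ValueError):
            report.consensus_candidates(0.0)


class TestBenchmarkGenerator:
    def test_composition_and_motif_scan(self):
        seqs = generate_tf_benchmark(n_tf=20, n_ntf=50, length_range=(100, 200),
                                     motif="CKRPLHC", seed=4)
        assert len(seqs) == 70
        for rec in seqs.records:
            if rec.label == "TF":
                assert "CKRPLHC" in rec.sequence  # substring-scan oracle
            else:
                assert "CKRPLHC" not in rec.sequence

    def test_fasta_round_trip(self, tmp_path):
        seqs = generate_tf_benchmark(n_tf=5, n_ntf=8, length_range=(50, 80), seed=1)
        seqs.to_fasta(tmp_path / "b.fasta")
        back = SeqRecordSet.from_fasta(tmp_path / "b.fasta")
        assert back.ids == seqs.ids
        assert back.labels == seqs.labels
        assert [r.sequence for r in back.records] == [r.sequence for r in seqs.records]

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            generate_tf_benchmark(n_tf=2, n_ntf=2, motif="CKXB1")

    def test_single_class_refused_downstream(self):
        seqs = generate_tf_benchmark(n_tf=0, n_ntf=10, length_range=(50, 60), seed=0)
        with pytest.raises(ValueError):
            cross_validate(seqs, config=CVConfig(folds=2, standard_length=60))
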