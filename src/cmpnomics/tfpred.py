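"""Cost-sensitive SVM transcription-factor prediction from protein sequences.

The predictor follows a three-step shape: (1) standardize every sequence to
a fixed length (N-terminal truncation keep, C-terminal X padding);
(2) encode each sequence as a fixed-length vector — either an external
per-sequence embedding table (e.g. from a protein language model) or the
built-in k-mer featurizer; (3) train a support-vector machine whose
misclassification costs are inversely proportional to class frequencies,
under stratified k-fold cross-validation (default 10-fold).

Held-out predictions accumulate per-fold confusion matrices and the
consensus fraction per sequence — the fraction of held-out evaluations in
which the sequence was called a TF.  Sequences at or above the consensus
threshold (default 0.5) are the candidate TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
ALPHABET = AMINO_ACIDS + PAD
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

TF, NTF = "TF", "NTF"


@dataclass(frozen=True)
class SeqRecord:
    id: str
    sequence: str
    label: str | None = None  # TF / NTF / None (unlabeled, prediction only)


@dataclass
class SeqRecordSet:
    """Labelled protein sequences over the 20-letter alphabet plus X."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids")
        for r in self.records:
            if not r.sequence:
                raise ValueError(f"empty sequence for id {r.id!r}")
            bad = set(r.sequence) - set(ALPHABET)
            if bad:
                raise ValueError(f"non-amino-acid symbols {sorted(bad)} in {r.id!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SeqRecordSet":
        """Read FASTA with ``>id|label`` headers (label optional)."""
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if "|" in header:
                rid, label = header.split("|", 1)
            else:
                rid, label = header, None
            records.append(SeqRecord(id=rid, sequence=str(rec.seq).upper(), label=label))
        return cls(records=records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                header = f"{r.id}|{r.label}" if r.label else r.id
                fh.write(f">{header}\n{r.sequence}\n")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and model settings.

    folds : number of stratified CV folds (default 10).
    standard_length : fixed residue length after truncation/padding (default 1000).
    kernel : SVM kernel, "linear" (default) or "rbf".
    cost_mode : "inverse_frequency" (cost-sensitive, default) or "uniform".
    svm_c : SVM regularization constant; the default suits L2-normalized
        embedding vectors, where unit-norm inputs make small C over-regularize.
    consensus_threshold : minimum held-out TF-call fraction for a candidate.
    repeats : independent CV repetitions pooled into the consensus fraction.
    """

    folds: int = 10
    standard_length: int = 1000
    kernel: str = "linear"
    cost_mode: str = "inverse_frequency"
    svm_c: float = 10.0
    seed: int = 0
    consensus_threshold: float = 0.5
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.standard_length < 1:
            raise ValueError("standard_length must be >= 1")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.cost_mode not in ("inverse_frequency", "uniform"):
            raise ValueError(f"unknown cost mode {self.cost_mode!r}")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EmbeddingTable:
    """Per-sequence fixed-length vectors keyed by id."""

    vectors: dict[str, np.ndarray]
    dimension: int
    source: str = "kmer_builtin"

    def __post_init__(self) -> None:
        for rid, v in self.vectors.items():
            if len(v) != self.dimension:
                raise ValueError(
                    f"vector for {rid!r} has dimension {len(v)}, expected {self.dimension}"
                )

    def matrix(self, ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self.vectors]
        if missing:
            raise KeyError(f"ids missing from embedding table: {missing}")
        return np.vstack([self.vectors[i] for i in ids])

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "external_table") -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vectors = {str(i): row.to_numpy(dtype=float) for i, row in df.iterrows()}
        return cls(vectors=vectors, dimension=df.shape[1], source=source)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame.from_dict(
            {i: v for i, v in self.vectors.items()}, orient="index"
        )
        df.columns = [f"v{j+1}" for j in range(self.dimension)]
        df.to_csv(path, sep="\t", index_label="id")


def standardize(records: SeqRecordSet, length: int = 1000) -> SeqRecordSet:
    """Truncate or pad every sequence to exactly ``length`` residues.

    Longer sequences keep their first ``length`` residues (the N-terminus);
    shorter ones are padded at the C-terminus with the neutral symbol X.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    out = []
    for r in records.records:
        if not r.sequence:
            raise ValueError(f"empty sequence for id {r.id!r}")
        seq = r.sequence[:length].ljust(length, PAD)
        out.append(SeqRecord(id=r.id, sequence=seq, label=r.label))
    return SeqRecordSet(records=out)


def _kmer_index(kmer: str, buckets: int = 400) -> int:
    # deterministic hash into a fixed bucket space (21-ary positional code)
    code = 0
    for ch in kmer:
        code = code * 21 + (ALPHABET.index(ch))
    return code % buckets


def _featurize_one(seq: str, buckets: int = 400) -> np.ndarray:
    comp = np.zeros(20)
    for ch in seq:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            comp[idx] += 1.0
    kmers = np.zeros(buckets)
    for i in range(len(seq) - 2):
        kmer = seq[i : i + 3]
        if PAD in kmer:  # padding/unknown symbol breaks k-mers
            continue
        kmers[_kmer_index(kmer, buckets)] += 1.0
    v = np.concatenate([comp, kmers])
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def featurize(
    records: SeqRecordSet,
    backend: str = "kmer_builtin",
    external: EmbeddingTable | None = None,
) -> EmbeddingTable:
    """Encode every sequence as a fixed-length vector.

    ``kmer_builtin`` concatenates the 20-dim amino-acid composition with a
    400-dim hashed 3-mer frequency vector and L2-normalizes; k-mers touching
    the X padding symbol are skipped, so the output is invariant to
    :func:`standardize` padding.  ``external_table`` passes a precomputed
    embedding table through after checking coverage and dimension.
    """
    if backend == "kmer_builtin":
        vectors = {r.id: _featurize_one(r.sequence) for r in records.records}
        return EmbeddingTable(vectors=vectors, dimension=420, source="kmer_builtin")
    if backend == "external_table":
        if external is None:
            raise ValueError("external_table backend needs an embedding table")
        missing = [i for i in records.ids if i not in external.vectors]
        if missing:
            raise KeyError(f"ids missing from external embedding table: {missing}")
        return external
    raise ValueError(f"unknown featurization backend {backend!r}")


def class_costs(labels: Sequence[str]) -> dict[str, float]:
    """Misclassification cost per class, inversely proportional to frequency.

    cost(c) = total / (n_classes * count(c)), so the cost ratio between two
    classes equals the inverse ratio of their frequencies.
    """
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("class costs undefined for single-class data")
    total, n_classes = len(labels), len(counts)
    return {str(c): total / (n_classes * int(k)) for c, k in counts.items()}


@dataclass
class FoldMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "f1": self.f1, "specificity": self.specificity,
            "sensitivity": self.sensitivity, "balanced_accuracy": self.balanced_accuracy,
        }


class TFPredictionModel:
    """Cost-sensitive SVM TF/NTF classifier evaluated by stratified k-fold CV."""

    def __init__(
        self,
        records: SeqRecordSet,
        embeddings: EmbeddingTable | None = None,
        config: CVConfig | None = None,
    ) -> None:
        self.config = config or CVConfig()
        labels = [r.label for r in records.records]
        if any(l is None for l in labels):
            raise ValueError("cross-validation needs labelled records")
        classes = set(labels)
        if len(classes) < 2:
            raise ValueError("degenerate single-class data")
        counts = pd.Series(labels).value_counts()
        if counts.min() < self.config.folds:
            raise ValueError(
                f"smallest class ({counts.min()}) has fewer members than folds ({self.config.folds})"
            )
        self.records = standardize(records, self.config.standard_length)
        self.embeddings = embeddings if embeddings is not None else featurize(self.records)

    def fit(self) -> "CVReport":
        cfg = self.config
        ids = self.records.ids
        y = np.array([1 if r.label == TF else 0 for r in self.records.records])
        X = self.embeddings.matrix(ids)

        if cfg.cost_mode == "inverse_frequency":
            costs = class_costs([r.label for r in self.records.records])
            class_weight = {1: costs[TF], 0: costs[NTF]}
        else:
            class_weight = None

        per_fold: list[FoldMetrics] = []
        tf_calls = np.zeros(len(ids))
        holdouts = np.zeros(len(ids))
        for rep in range(cfg.repeats):
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed + rep)
            for train_idx, test_idx in skf.split(X, y):
                clf = SVC(kernel=cfg.kernel, C=cfg.svm_c, class_weight=class_weight,
                          random_state=cfg.seed)
                clf.fit(X[train_idx], y[train_idx])
                pred = clf.predict(X[test_idx])
                truth = y[test_idx]
                per_fold.append(
                    FoldMetrics(
                        tp=int(np.sum((pred == 1) & (truth == 1))),
                        fp=int(np.sum((pred == 1) & (truth == 0))),
                        tn=int(np.sum((pred == 0) & (truth == 0))),
                        fn=int(np.sum((pred == 0) & (truth == 1))),
                    )
                )
                tf_calls[test_idx] += pred
                holdouts[test_idx] += 1

        consensus = {rid: tf_calls[i] / holdouts[i] for i, rid in enumerate(ids)}
        return CVReport(model=self, per_fold=per_fold, consensus=consensus)


class CVReport:
    """Cross-validation results: per-fold confusion metrics and consensus calls."""

    def __init__(self, model: TFPredictionModel, per_fold: list[FoldMetrics],
                 consensus: dict[str, float]) -> None:
        self.model = model
        self.per_fold = per_fold
        self.consensus = consensus

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.per_fold]))

    @property
    def means(self) -> dict[str, float]:
        return {m: self.mean(m) for m in ("f1", "specificity", "sensitivity", "balanced_accuracy")}

    def consensus_candidates(self, threshold: float | None = None) -> list[str]:
        """Ids whose held-out TF-call fraction is at or above the threshold, sorted."""
        thr = self.model.config.consensus_threshold if threshold is None else threshold
        if not 0 < thr <= 1:
            raise ValueError("threshold must be in (0, 1]")
        return sorted(rid for rid, frac in self.consensus.items() if frac >= thr)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": vars(self.model.config),
            "per_fold": [f.to_dict() for f in self.per_fold],
            "means": self.means,
            "consensus": self.consensus,
            "candidates": self.consensus_candidates(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def per_fold_tsv(self, path: str | Path) -> None:
        pd.DataFrame([f.to_dict() for f in self.per_fold]).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        m = self.means
        cfg = self.model.config
        return "\n".join(
            [
                "Cost-sensitive SVM transcription-factor prediction",
                f"  records: {len(self.model.records)}  folds: {cfg.folds} x {cfg.repeats} repeat(s)"
                f"  kernel: {cfg.kernel}  costs: {cfg.cost_mode}",
                f"  mean F1: {m['f1']:.4f}  specificity: {m['specificity']:.4f}  "
                f"sensitivity: {m['sensitivity']:.4f}  balanced accuracy: {m['balanced_accuracy']:.4f}",
                f"  consensus TF candidates (>= {cfg.consensus_threshold:.0%} of held-out calls): "
                f"{len(self.consensus_candidates())}",
            ]
        )


def cross_validate(
    records: SeqRecordSet,
    embeddings: EmbeddingTable | None = None,
    config: CVConfig | None = None,
) -> CVReport:
    """Functional entry point: stratified CV of the cost-sensitive SVM."""
    return TFPredictionModel(records, embeddings, config).fit()


def consensus_candidates(report: CVReport, threshold: float = 0.5) -> list[str]:
    """Ids called TF in at least ``threshold`` of their held-out evaluations."""
    return report.consensus_candidates(threshold)
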