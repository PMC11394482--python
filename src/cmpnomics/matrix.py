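"""Abundance matrices (proteomic iBAQ intensities, RNA-seq counts) with design metadata.

The container wraps a pandas DataFrame (features in rows, samples in columns)
together with a per-sample design record (genotype, treatment, replicate).
It is the common currency of the differential-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

Modality = Literal["proteomic", "rna"]

NORMALIZATION_METHODS = ("median_center", "library_size", "none")


@dataclass(frozen=True)
class SampleInfo:
    """Design metadata for one sample."""

    genotype: str
    treatment: str
    replicate: int


@dataclass
class AbundanceMatrix:
    """Features x samples abundance matrix with per-sample design metadata.

    Parameters
    ----------
    values : pd.DataFrame
        Feature ids in the index, sample ids in the columns. Intensities
        (non-negative reals) for proteomic data, counts (non-negative
        integers) for RNA-seq.
    design : mapping of sample id -> SampleInfo
        Must cover every column of ``values``.
    modality : {"proteomic", "rna"}
    """

    values: pd.DataFrame
    design: Mapping[str, SampleInfo] = field(default_factory=dict)
    modality: Modality = "proteomic"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.design]
        if self.design and missing:
            raise ValueError(f"samples without design metadata: {missing}")
        if self.modality not in ("proteomic", "rna"):
            raise ValueError(f"unknown modality {self.modality!r}")

    # -- convenience ---------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, genotype: str | None = None, treatment: str | None = None) -> list[str]:
        """Sample ids matching the given genotype and/or treatment."""
        out = []
        for sid in self.values.columns:
            info = self.design[sid]
            if genotype is not None and info.genotype != genotype:
                continue
            if treatment is not None and info.treatment != treatment:
                continue
            out.append(sid)
        return out

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, design_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
        if design_path is not None:
            rows = [
                {
                    "sample_id": sid,
                    "genotype": info.genotype,
                    "treatment": info.treatment,
                    "replicate": info.replicate,
                }
                for sid, info in self.design.items()
            ]
            pd.DataFrame(rows).to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        matrix_path: str | Path,
        design_path: str | Path,
        modality: Modality = "proteomic",
    ) -> "AbundanceMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index.name = None
        design_df = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str})
        design = {
            str(r.sample_id): SampleInfo(str(r.genotype), str(r.treatment), int(r.replicate))
            for r in design_df.itertuples()
        }
        return cls(values=values, design=design, modality=modality)


def normalize(matrix: AbundanceMatrix, method: str = "median_center") -> AbundanceMatrix:
    """Normalize a matrix per sample.

    ``median_center`` divides each sample by 2**(median log2 value) so the
    per-sample median of log2 values becomes 0 (zeros are ignored when taking
    the median).  ``library_size`` rescales each column to the mean column
    sum, the usual counts-per-mean-library normalization.  ``none`` returns
    the input unchanged.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization {method!r}; expected one of {NORMALIZATION_METHODS}")
    if method == "none":
        return matrix

    vals = matrix.values.astype(float)
    if method == "median_center":
        log2 = np.log2(vals.where(vals > 0))
        medians = log2.median(axis=0, skipna=True)
        scaled = vals / np.power(2.0, medians)
    else:  # library_size
        sums = vals.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(f"library_size normalization: all-zero sample column(s) {list(zero.index)}")
        scaled = vals * (sums.mean() / sums)
    return AbundanceMatrix(values=scaled, design=matrix.design, modality=matrix.modality)
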