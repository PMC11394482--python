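"""Differential expression between two sample groups.

The study's statistical rule is deliberately plain: a two-sided two-sample
t-test per feature on log2 values, no multiple-testing correction, and
significance called at p < alpha (default 0.05) with an optional absolute
log2-fold-change floor.  Correction is applied only later, in the
enrichment stage.

Modelled in the statsmodels style: ``DifferentialExpression`` is built from
an :class:`~cmpnomics.matrix.AbundanceMatrix` and two sample groups, and its
``fit`` returns a :class:`DifferentialExpressionResults` carrying the
per-feature table, the up/down/significant sets and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import AbundanceMatrix, normalize


@dataclass(frozen=True)
class DEConfig:
    """Testing rule for differential expression calls.

    alpha : significance level on the raw (uncorrected) p-value.
    test : "welch" (unequal variances, default) or "student".
    log2fc_min : minimum absolute log2 fold change required for a call.
    normalization : applied before testing; see :func:`cmpnomics.matrix.normalize`.
    """

    alpha: float = 0.05
    test: str = "welch"
    log2fc_min: float = 0.0
    normalization: str = "median_center"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("welch", "student"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.log2fc_min < 0:
            raise ValueError("log2fc_min must be non-negative")


class DifferentialExpression:
    """Per-feature two-group comparison on log2-transformed abundances.

    Group B is the numerator of the fold change (log2fc > 0 means higher
    in B).  Counts get a pseudo-count of 1 before log2; proteomic zeros are
    treated as missing for that feature/sample pair.
    """

    def __init__(
        self,
        matrix: AbundanceMatrix,
        group_a: Sequence[str],
        group_b: Sequence[str],
        config: DEConfig | None = None,
    ) -> None:
        self.config = config or DEConfig()
        group_a, group_b = list(group_a), list(group_b)
        if set(group_a) & set(group_b):
            raise ValueError("groups overlap")
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError("each group needs at least 2 samples")
        unknown = [s for s in group_a + group_b if s not in matrix.values.columns]
        if unknown:
            raise ValueError(f"unknown sample ids: {unknown}")
        self.matrix = normalize(matrix, self.config.normalization)
        self.group_a = group_a
        self.group_b = group_b

    def _log2_values(self) -> pd.DataFrame:
        vals = self.matrix.values.astype(float)
        if self.matrix.modality == "rna":
            return np.log2(vals + 1.0)
        # proteomic: zeros are non-detections, masked rather than imputed
        return np.log2(vals.where(vals > 0))

    def fit(self) -> "DifferentialExpressionResults":
        log2 = self._log2_values()
        a = log2[self.group_a].to_numpy()
        b = log2[self.group_b].to_numpy()
        equal_var = self.config.test == "student"
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat, p = stats.ttest_ind(
                b, a, axis=1, equal_var=equal_var, nan_policy="omit"
            )
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        log2fc = mean_b - mean_a

        t_stat = np.asarray(t_stat, dtype=float)
        p = np.asarray(p, dtype=float)
        # zero variance in both groups: identical means -> null (p=1),
        # separated means -> infinitely strong evidence (p=0)
        degenerate = ~np.isfinite(p)
        p[degenerate & (log2fc == 0)] = 1.0
        p[degenerate & (log2fc != 0)] = 0.0
        t_stat[~np.isfinite(t_stat)] = 0.0

        cfg = self.config
        significant = (p < cfg.alpha) & (np.abs(log2fc) >= cfg.log2fc_min)
        table = pd.DataFrame(
            {
                "feature_id": self.matrix.feature_ids,
                "log2fc": log2fc,
                "t_stat": t_stat,
                "p_value": p,
                "direction": np.where(log2fc > 0, "up", "down"),
                "significant": significant,
            }
        )
        return DifferentialExpressionResults(model=self, table=table)


class DifferentialExpressionResults:
    """Fitted per-feature differential expression table with set views."""

    def __init__(self, model: DifferentialExpression, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    def de_sets(self) -> tuple[set[str], set[str], set[str]]:
        """(up, down, all_significant) feature-id sets; up and down partition the significant set."""
        sig = self.table[self.table.significant]
        up = set(sig.loc[sig.direction == "up", "feature_id"])
        down = set(sig.loc[sig.direction == "down", "feature_id"])
        return up, down, up | down

    def volcano_table(self) -> pd.DataFrame:
        """(log2fc, -log10 p) per feature, for external plotting."""
        with np.errstate(divide="ignore"):
            neglog = -np.log10(self.table.p_value.to_numpy())
        return pd.DataFrame(
            {"feature_id": self.table.feature_id, "log2fc": self.table.log2fc, "neg_log10_p": neglog}
        )

    def heatmap_table(self) -> pd.DataFrame:
        """Z-scored group means per feature (two columns: group_a, group_b)."""
        log2 = self.model._log2_values()
        means = pd.DataFrame(
            {
                "group_a": log2[self.model.group_a].mean(axis=1),
                "group_b": log2[self.model.group_b].mean(axis=1),
            }
        )
        centered = means.sub(means.mean(axis=1), axis=0)
        sd = centered.std(axis=1, ddof=0).replace(0.0, 1.0)
        return centered.div(sd, axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        up, down, sig = self.de_sets()
        cfg = self.model.config
        lines = [
            "Differential expression (two-sample t-test on log2 values)",
            f"  test: {cfg.test}, alpha: {cfg.alpha}, |log2FC| >= {cfg.log2fc_min}, "
            f"normalization: {cfg.normalization}, no multiple-testing correction",
            f"  features tested: {len(self.table)}",
            f"  significant: {len(sig)}  (up: {len(up)}, down: {len(down)})",
        ]
        return "\n".join(lines)


def call_de(
    matrix: AbundanceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: DEConfig | None = None,
) -> DifferentialExpressionResults:
    """Functional entry point: fit a two-group comparison and return the results."""
    return DifferentialExpression(matrix, group_a, group_b, config).fit()


def de_sets(results: DifferentialExpressionResults) -> tuple[set[str], set[str], set[str]]:
    """(up, down, all_significant) from a fitted comparison."""
    return results.de_sets()
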