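"""Gene-set over-representation analysis (ORA).

For a query set of DE features against an annotated universe, each term is
tested with the upper-tail hypergeometric test: with N the universe size,
K the term size within the universe, n the number of query features
annotated to at least one term, and k the query hits in the term,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

GeneRatio is k/n — the dot-plot circle size in comparative ORA figures.
P-values are Benjamini-Hochberg adjusted across all tested terms of a
collection (Bonferroni available).  Only enrichment (the upper tail) is
tested.

``OverRepresentation`` follows the Model/Results idiom: construct from
query/universe/collection, ``fit()`` returns :class:`ORAResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (name, category, member ids)."""

    terms: dict[str, tuple[str, str, set[str]]]

    def __post_init__(self) -> None:
        for tid, (_, _, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has no members")

    @classmethod
    def from_gmt(cls, path: str | Path, category: str = "other") -> "GeneSetCollection":
        terms = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tid, desc, members = parts[0], parts[1], set(parts[2:])
            terms[tid] = (desc, category, members)
        return cls(terms=terms)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.terms):
                name, _, members = self.terms[tid]
                fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


def bh_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg step-up adjustment (or Bonferroni), input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {method!r}")
    return list(multipletests(p, method=method)[1])


class OverRepresentation:
    """Hypergeometric enrichment of a query feature set against a collection."""

    def __init__(
        self,
        query: Iterable[str],
        universe: Iterable[str],
        collection: GeneSetCollection,
        adjust: str = "fdr_bh",
    ) -> None:
        self.query = set(query)
        self.universe = set(universe)
        if not self.query <= self.universe:
            raise ValueError("query must be a subset of the universe")
        self.collection = collection
        self.adjust = adjust

    def fit(self) -> "ORAResults":
        if not self.query:
            empty = pd.DataFrame(
                columns=["term_id", "name", "category", "k", "K", "n", "N",
                         "gene_ratio", "gene_ratio_value", "p_hyper", "p_adj"]
            )
            return ORAResults(model=self, table=empty, empty_query=True)
        annotated: set[str] = set()
        term_members: dict[str, set[str]] = {}
        for tid, (_, _, members) in self.collection.terms.items():
            in_universe = members & self.universe
            term_members[tid] = in_universe
            annotated |= in_universe

        N = len(self.universe)
        n = len(self.query & annotated)  # annotated query size
        rows = []
        for tid, members in term_members.items():
            if not members:
                continue
            K = len(members)
            k = len(self.query & members)
            # upper tail P(X >= k)
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
            name, category, _ = self.collection.terms[tid]
            rows.append(
                {
                    "term_id": tid,
                    "name": name,
                    "category": category,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "gene_ratio": f"{Fraction(k, n) if n else Fraction(0)}",
                    "gene_ratio_value": (k / n) if n else 0.0,
                    "p_hyper": min(p, 1.0),
                }
            )
        table = pd.DataFrame(rows)
        if len(table):
            table["p_adj"] = bh_adjust(table["p_hyper"].tolist(), self.adjust)
            table = table.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(drop=True)
        else:
            table["p_adj"] = []
        return ORAResults(model=self, table=table, empty_query=not self.query)


class ORAResults:
    """Term-level enrichment table sorted by adjusted p then term id."""

    def __init__(self, model: OverRepresentation, table: pd.DataFrame, empty_query: bool = False) -> None:
        self.model = model
        self.table = table
        self.empty_query = empty_query  # warning flag: nothing to test

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        if not len(self.table):
            return []
        return self.table.loc[self.table.p_adj < alpha, "term_id"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        cols = ["term_id", "name", "category", "k", "K", "n", "N",
                "gene_ratio", "gene_ratio_value", "p_hyper", "p_adj"]
        self.table.to_csv(path, sep="\t", index=False, columns=cols if len(self.table) else None)

    def summary(self) -> str:
        lines = [
            "Over-representation analysis (upper-tail hypergeometric)",
            f"  universe N = {len(self.model.universe)}, query = {len(self.model.query)}",
            f"  terms tested: {len(self.table)}, adjustment: {self.model.adjust}",
        ]
        if len(self.table):
            top = self.table.head(5)
            lines.append("  top terms (term, k/n, p_adj):")
            for r in top.itertuples():
                lines.append(f"    {r.term_id}  {r.gene_ratio}  {r.p_adj:.3g}")
        return "\n".join(lines)


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    adjust: str = "fdr_bh",
) -> ORAResults:
    """Functional entry point for a single enrichment run."""
    return OverRepresentation(query, universe, collection, adjust).fit()


@dataclass
class DotPlotTable:
    """Long-format comparative ORA table across conditions, with filter flags."""

    rows: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def comparative_dotplot(
    results: Mapping[str, ORAResults],
    exclusion_filters: Mapping[str, set[str]] | None = None,
) -> DotPlotTable:
    """Integrate per-condition ORA results into one dot-plot table.

    Terms found in any exclusion filter (e.g. the dosage-dependent or
    non-mPR pathway filters) are flagged ``excluded`` with the filter name
    as the reason; terms enriched in more than one condition are marked
    ``shared``.
    """
    if not results:
        raise ValueError("no conditions supplied")
    exclusion_filters = exclusion_filters or {}
    term_conditions: dict[str, set[str]] = {}
    for cond, res in results.items():
        for tid in res.table.get("term_id", []):
            term_conditions.setdefault(tid, set()).add(cond)

    rows = []
    for cond, res in results.items():
        for r in res.table.itertuples():
            reason = ""
            for fname, tids in exclusion_filters.items():
                if r.term_id in tids:
                    reason = fname
                    break
            rows.append(
                {
                    "condition": cond,
                    "term_id": r.term_id,
                    "name": r.name,
                    "category": r.category,
                    "gene_ratio": r.gene_ratio,
                    "gene_ratio_value": r.gene_ratio_value,
                    "p_adj": r.p_adj,
                    "excluded": bool(reason),
                    "exclusion_reason": reason,
                    "shared": len(term_conditions[r.term_id]) > 1,
                }
            )
    return DotPlotTable(rows=pd.DataFrame(rows))
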