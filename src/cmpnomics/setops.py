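"""Venn set algebra for DEP/DEG families and the two-step mPR filtration.

Families of 2-3 named feature sets (one per genotype contrast) are
decomposed into exhaustive, pairwise-disjoint Venn regions.  Percentages are
reported against an explicit denominator: published analyses of this kind
mix denominators (total identified features vs filtered totals), so the
denominator is always a required argument, never inferred.

The two-step filtration removes, in order, (1) features responding to CCM1
protein dosage itself and (2) features in the "antagonist" set — responses
attributable to non-mPR receptors (glucocorticoid receptor, nuclear
progesterone receptor) that share the mifepristone ligand.  What survives is
the mPR-specific response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import json

FilterMode = ("subtract", "intersect")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal, as printed tables do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SetFamily:
    """A named family of 2-3 labelled feature-id sets."""

    name: str
    members: dict[str, set[str]]

    def __post_init__(self) -> None:
        if not 2 <= len(self.members) <= 3:
            raise ValueError("a set family holds 2 or 3 sets")
        self.members = {label: set(ids) for label, ids in self.members.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.members)

    def union(self) -> set[str]:
        out: set[str] = set()
        for ids in self.members.values():
            out |= ids
        return out


@dataclass
class VennPartition:
    """Exhaustive region decomposition of a set family.

    ``regions`` maps a region signature (frozenset of labels) to the ids
    belonging to exactly those sets.  ``percentages`` are one-decimal
    round-half-up shares of ``denominator``.
    """

    labels: list[str]
    regions: dict[frozenset, set[str]]
    denominator: int
    percentages: dict[frozenset, float] = field(default_factory=dict)

    def count(self, *labels: str) -> int:
        return len(self.regions[frozenset(labels)])

    def percentage(self, *labels: str) -> float:
        return self.percentages[frozenset(labels)]

    def region_order(self) -> list[frozenset]:
        """Stable ordering: singles (input label order), then pairs, then the triple."""
        order: list[frozenset] = []
        for k in range(1, len(self.labels) + 1):
            for combo in combinations(self.labels, k):
                order.append(frozenset(combo))
        return order

    def to_frame_rows(self) -> list[dict]:
        rows = []
        for sig in self.region_order():
            rows.append(
                {
                    "region": "&".join(sorted(sig, key=self.labels.index)),
                    "count": len(self.regions[sig]),
                    "percentage": self.percentages[sig],
                }
            )
        return rows

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tcount\tpercentage\n")
            for row in self.to_frame_rows():
                fh.write(f"{row['region']}\t{row['count']}\t{row['percentage']}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "denominator": self.denominator,
            "regions": [
                dict(row, members=sorted(self.regions[sig]))
                for sig, row in zip(self.region_order(), self.to_frame_rows())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class FilterSpec:
    """The two filtration layers.

    layer1 : features whose expression tracks CCM1 dosage itself.
    layer2 : features in the non-mPR ("antagonist") response set, derived
        from mifepristone-treated cells expressing GR/nPR.
    id_normalization : "exact" or "case_insensitive_symbol" — the antagonist
        set comes from a different species/cell line, so case-insensitive
        gene-symbol matching is the default.
    """

    layer1: set[str]
    layer2: set[str]
    id_normalization: str = "case_insensitive_symbol"

    def __post_init__(self) -> None:
        if self.id_normalization not in ("exact", "case_insensitive_symbol"):
            raise ValueError(f"unknown id normalization {self.id_normalization!r}")

    def normalize_id(self, feature_id: str) -> str:
        if self.id_normalization == "case_insensitive_symbol":
            return feature_id.upper()
        return feature_id


def venn_partition(family: SetFamily, denominator: int) -> VennPartition:
    """Decompose a 2/3-set family into exhaustive disjoint Venn regions.

    ``denominator`` is the count percentages are taken against; it must be
    at least the union size (a smaller denominator would make the printed
    percentage convention ill-defined).
    """
    union = family.union()
    if denominator < len(union):
        raise ValueError(
            f"denominator {denominator} smaller than union size {len(union)}"
        )
    labels = family.labels
    regions: dict[frozenset, set[str]] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(family.members[l] for l in combo))
            outside = set().union(*(family.members[l] for l in labels if l not in combo))
            regions[frozenset(combo)] = inside - outside
    percentages = {
        sig: round_half_up(100.0 * len(ids) / denominator, 1) for sig, ids in regions.items()
    }
    return VennPartition(labels=labels, regions=regions, denominator=denominator, percentages=percentages)


def apply_filter(family: SetFamily, filter_set: Iterable[str], mode: str = "subtract",
                 id_normalization: str = "exact") -> SetFamily:
    """Subtract a filter set from (or intersect it with) every set of a family."""
    if mode not in FilterMode:
        raise ValueError(f"unknown filter mode {mode!r}")
    spec = FilterSpec(layer1=set(), layer2=set(), id_normalization=id_normalization)
    norm_filter = {spec.normalize_id(x) for x in filter_set}
    members = {}
    for label, ids in family.members.items():
        if mode == "subtract":
            members[label] = {x for x in ids if spec.normalize_id(x) not in norm_filter}
        else:
            members[label] = {x for x in ids if spec.normalize_id(x) in norm_filter}
    return SetFamily(name=family.name, members=members)


@dataclass
class FiltrationReport:
    """Per-layer removal bookkeeping from :func:`two_step_filtration`."""

    removed_layer1: dict[str, int]
    removed_layer2: dict[str, int]
    surviving: dict[str, int]
    surviving_union: int

    def to_dict(self) -> dict:
        return {
            "removed_layer1": self.removed_layer1,
            "removed_layer2": self.removed_layer2,
            "surviving": self.surviving,
            "surviving_union": self.surviving_union,
        }


def two_step_filtration(prg_response: SetFamily, spec: FilterSpec) -> tuple[SetFamily, FiltrationReport]:
    """Remove dosage-dependent (layer 1) then non-mPR antagonist (layer 2) features.

    Returns the surviving mPR-specific family and a report of per-layer
    removal counts.  Because both layers act by set difference, applying
    them in either order gives the same final family.
    """
    after1 = apply_filter(prg_response, spec.layer1, "subtract", spec.id_normalization)
    after2 = apply_filter(after1, spec.layer2, "subtract", spec.id_normalization)
    report = FiltrationReport(
        removed_layer1={l: len(prg_response.members[l]) - len(after1.members[l]) for l in prg_response.labels},
        removed_layer2={l: len(after1.members[l]) - len(after2.members[l]) for l in after1.labels},
        surviving={l: len(after2.members[l]) for l in after2.labels},
        surviving_union=len(after2.union()),
    )
    return after2, report


# -- plain-text serialization -----------------------------------------------

def read_feature_set(path: str | Path) -> set[str]:
    """One id per line."""
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_feature_set(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


def read_set_family(path: str | Path, name: str = "family") -> SetFamily:
    """Two-column TSV: set_label <TAB> feature id."""
    members: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        label, fid = line.split("\t")
        members.setdefault(label, set()).add(fid)
    return SetFamily(name=name, members=members)


def write_set_family(family: SetFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in family.labels:
            for fid in sorted(family.members[label]):
                fh.write(f"{label}\t{fid}\n")
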