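"""Bundled worked examples: published Venn region counts from the emulated study.

The CCM1/progesterone study this package re-implements prints, for each of
its Venn analyses, every exclusive region count together with the
percentage denominator.  Those printed tables are inputs here: they let the
set-algebra stage be exercised (and its percentage arithmetic checked)
without the study's unreleased raw data.  Region keys are frozensets of
set labels; e.g. ``frozenset({"WT", "KO"})`` is the exclusive WT-and-KO
(not KI96) region.

Four analyses are bundled:

* ``DEP_GENOTYPE`` — proteins differential between CCM1 genotype pairs
  (labels are the three pairwise contrasts), denominator 1059 (all
  identified proteins).
* ``DEP_PRG`` — proteins responding to progesterone action per genotype,
  denominator 1059.
* ``DEP_PRG_FILTERED`` / ``DEG_PRG_FILTERED`` — the same responses after
  the antagonist filtration, denominators 876 and 6424.
* ``DEP_MPR_SPECIFIC`` / ``DEG_MPR_SPECIFIC`` — surviving mPR-specific
  features after the full two-step filtration, denominators 18 and 103.
"""

from __future__ import annotations

from dataclasses import dataclass

from .setops import FilterSpec, SetFamily


@dataclass(frozen=True)
class VennExample:
    """Printed exclusive region counts, the percentage denominator, and the printed percentages."""

    name: str
    labels: tuple[str, ...]
    region_counts: dict[frozenset, int]
    denominator: int
    printed_percentages: dict[frozenset, float]


def _regions3(labels, singles, pairs, triple):
    a, b, c = labels
    return {
        frozenset({a}): singles[0],
        frozenset({b}): singles[1],
        frozenset({c}): singles[2],
        frozenset({a, b}): pairs[0],
        frozenset({a, c}): pairs[1],
        frozenset({b, c}): pairs[2],
        frozenset({a, b, c}): triple,
    }


_PAIR_LABELS = ("WTvsKI96", "KOvsWT", "KI96vsWT")

DEP_GENOTYPE = VennExample(
    name="DEP_genotype_pairs",
    labels=_PAIR_LABELS,
    region_counts=_regions3(_PAIR_LABELS, (205, 120, 194), (113, 173, 186), 68),
    denominator=1059,
    printed_percentages=_regions3(_PAIR_LABELS, (19.4, 11.3, 18.3), (10.7, 16.3, 17.6), 6.4),
)

_GENO_LABELS = ("WT", "KO", "KI96")

DEP_PRG = VennExample(
    name="DEP_prg_response",
    labels=_GENO_LABELS,
    region_counts=_regions3(_GENO_LABELS, (218, 212, 115), (48, 27, 29), 12),
    denominator=1059,
    printed_percentages=_regions3(_GENO_LABELS, (20.6, 20.0, 10.9), (4.5, 2.5, 2.7), 1.1),
)

DEP_PRG_FILTERED = VennExample(
    name="DEP_prg_filtered",
    labels=_GENO_LABELS,
    region_counts=_regions3(_GENO_LABELS, (262, 224, 151), (79, 66, 42), 52),
    denominator=876,
    printed_percentages=_regions3(_GENO_LABELS, (29.9, 25.6, 17.2), (9.0, 7.5, 4.8), 5.9),
)

_DEG_LABELS = ("KO", "KI96")

DEG_PRG_FILTERED = VennExample(
    name="DEG_prg_filtered",
    labels=_DEG_LABELS,
    region_counts={
        frozenset({"KO"}): 1230,
        frozenset({"KI96"}): 3242,
        frozenset({"KO", "KI96"}): 1952,
    },
    denominator=6424,
    printed_percentages={
        frozenset({"KO"}): 19.1,
        frozenset({"KI96"}): 50.5,
        frozenset({"KO", "KI96"}): 30.4,
    },
)

DEP_MPR_SPECIFIC = VennExample(
    name="DEP_mpr_specific",
    labels=_GENO_LABELS,
    region_counts=_regions3(_GENO_LABELS, (7, 2, 2), (3, 1, 3), 0),
    denominator=18,
    printed_percentages=_regions3(_GENO_LABELS, (38.9, 11.1, 11.1), (16.7, 5.6, 16.7), 0.0),
)

DEG_MPR_SPECIFIC = VennExample(
    name="DEG_mpr_specific",
    labels=_DEG_LABELS,
    region_counts={
        frozenset({"KO"}): 20,
        frozenset({"KI96"}): 57,
        frozenset({"KO", "KI96"}): 26,
    },
    denominator=103,
    printed_percentages={
        frozenset({"KO"}): 19.4,
        frozenset({"KI96"}): 55.3,
        frozenset({"KO", "KI96"}): 25.2,
    },
)

ALL_EXAMPLES = (
    DEP_GENOTYPE,
    DEP_PRG,
    DEP_PRG_FILTERED,
    DEG_PRG_FILTERED,
    DEP_MPR_SPECIFIC,
    DEG_MPR_SPECIFIC,
)


def family_from_regions(example: VennExample) -> SetFamily:
    """Materialize a set family with synthetic ids realizing the printed region counts.

    Ids are deterministic (``<example>_<region>_<i>``), so the resulting
    family's exclusive Venn regions reproduce the printed counts exactly.
    """
    members: dict[str, set[str]] = {label: set() for label in example.labels}
    for sig, count in example.region_counts.items():
        tag = "+".join(sorted(sig))
        ids = {f"{example.name}:{tag}:{i}" for i in range(count)}
        for label in sig:
            members[label] |= ids
    return SetFamily(name=example.name, members=members)


def filtration_fixture() -> tuple[SetFamily, FilterSpec, VennExample]:
    """A filtration worked example built from the printed tables.

    Starts from the antagonist-filtered progesterone-response DEP family
    (876 proteins across three genotypes) and builds a two-layer filter
    spec that removes everything except the printed mPR-specific survivors
    (18 proteins, with the published region structure).  Within each Venn
    region the removed ids are split between layer 1 (dosage-dependent)
    and layer 2 (antagonist) — the published tables constrain only the
    total removed, not the split.
    """
    before = family_from_regions(DEP_PRG_FILTERED)
    survivors_by_region = DEP_MPR_SPECIFIC.region_counts
    layer1: set[str] = set()
    layer2: set[str] = set()
    for sig, count in DEP_PRG_FILTERED.region_counts.items():
        tag = "+".join(sorted(sig))
        keep = survivors_by_region.get(sig, 0)
        removed = [f"{DEP_PRG_FILTERED.name}:{tag}:{i}" for i in range(keep, count)]
        half = len(removed) // 2
        layer1 |= set(removed[:half])
        layer2 |= set(removed[half:])
    spec = FilterSpec(layer1=layer1, layer2=layer2, id_normalization="exact")
    return before, spec, DEP_MPR_SPECIFIC
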