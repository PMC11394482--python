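"""Synthetic multi-omics data with planted, recoverable structure.

The study design being emulated: three mouse-embryonic-fibroblast lines
with distinct CCM1 genotypes (wild type, knockout, knockin/96), each
treated with vehicle or with combined progesterone + mifepristone
("PRG action"), three biological replicates per cell.  The generators
produce every input the downstream pipeline consumes:

* a proteomic intensity matrix (log-normal, iBAQ-like) and an RNA-seq
  count matrix (negative binomial) with planted genotype and treatment
  effects of a known log2 magnitude;
* flat gene-set collections (GMT) with terms deliberately enriched for
  the planted differentially expressed features;
* an imbalanced TF/NTF protein-sequence benchmark (default composition
  2784 non-TFs / 954 TFs) whose TF class carries a planted sequence motif;
* an "antagonist" filter set covering a configurable fraction of the
  planted non-mPR treatment effects.

Every generator is deterministic given its seed, and each returns (or is
paired with) a GroundTruth object so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .matrix import AbundanceMatrix, SampleInfo
from .tfpred import AMINO_ACIDS, SeqRecord, SeqRecordSet, TF, NTF

DEFAULT_MOTIF = "CKRPLHC"  # arbitrary 7-mer; a synthetic stand-in, not a real DNA-binding domain


@dataclass(frozen=True)
class ExperimentConfig:
    """Design and effect-size knobs for the synthetic omics experiment.

    The defaults mirror the emulated study: genotypes (WT, KO, KI96),
    treatments (VEH, PRG_MIF), three biological replicates per
    genotype-treatment cell.  ``effect_log2fc`` is the planted shift in
    log2 units; ``frac_genotype_de`` / ``frac_treatment_de`` are the
    fractions of features shifted per genotype contrast / per-genotype
    treatment response.  ``frac_non_mpr`` splits each genotype's planted
    treatment responders into non-mPR ("antagonist") and mPR-specific
    subsets, which only matters to the antagonist-filter generator.
    """

    n_features_protein: int = 1000
    n_features_rna: int = 2000
    genotypes: tuple[str, ...] = ("WT", "KO", "KI96")
    treatments: tuple[str, ...] = ("VEH", "PRG_MIF")
    replicates: int = 3
    effect_log2fc: float = 2.0
    frac_genotype_de: float = 0.1
    frac_treatment_de: float = 0.1
    nb_dispersion: float = 0.2
    noise_sd_log2: float = 0.5
    frac_non_mpr: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features_protein <= 0 or self.n_features_rna <= 0:
            raise ValueError("feature counts must be positive")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per cell")
        for frac in (self.frac_genotype_de, self.frac_treatment_de,
                     self.frac_non_mpr, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise SD must be positive")
        if len(set(self.genotypes)) != len(self.genotypes) or len(set(self.treatments)) != len(self.treatments):
            raise ValueError("genotype/treatment labels must be unique")


@dataclass
class GroundTruth:
    """Which features were planted where, for exact recovery scoring.

    ``genotype_de_features`` maps each non-reference genotype to the ids
    shifted in that genotype (the CCM1-dosage contrast vs the first
    genotype).  ``treatment_de_features`` maps each genotype to the ids
    shifted under the treated condition in that genotype.  ``effect_signs``
    records the planted sign per (context, feature).  The treatment
    responders are partitioned into non-mPR and mPR-specific subsets.
    """

    genotype_de_features: dict[str, set[str]] = field(default_factory=dict)
    treatment_de_features: dict[str, set[str]] = field(default_factory=dict)
    tf_ids: set[str] = field(default_factory=set)
    effect_signs: dict[tuple[str, str], int] = field(default_factory=dict)
    non_mpr_features: set[str] = field(default_factory=set)
    mpr_specific_features: set[str] = field(default_factory=set)

    def all_genotype_de(self) -> set[str]:
        out: set[str] = set()
        for ids in self.genotype_de_features.values():
            out |= ids
        return out

    def all_treatment_de(self) -> set[str]:
        out: set[str] = set()
        for ids in self.treatment_de_features.values():
            out |= ids
        return out


def _make_design(config: ExperimentConfig, prefix: str) -> dict[str, SampleInfo]:
    design: dict[str, SampleInfo] = {}
    for g in config.genotypes:
        for t in config.treatments:
            for r in range(1, config.replicates + 1):
                design[f"{prefix}_{g}_{t}_r{r}"] = SampleInfo(genotype=g, treatment=t, replicate=r)
    return design


def _plant_effects(
    rng: np.random.Generator,
    config: ExperimentConfig,
    feature_ids: list[str],
    truth: GroundTruth,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Choose planted feature sets and signs; fill the GroundTruth in place."""
    n = len(feature_ids)
    n_gde = round(config.frac_genotype_de * n)
    n_tde = round(config.frac_treatment_de * n)
    reference = config.genotypes[0]
    treated = config.treatments[-1]

    genotype_sets: dict[str, set[str]] = {}
    for g in config.genotypes[1:]:
        chosen = set(rng.choice(feature_ids, size=n_gde, replace=False)) if n_gde else set()
        genotype_sets[g] = chosen
        truth.genotype_de_features.setdefault(g, set()).update(chosen)
        for fid in sorted(chosen):  # sorted: sign draws must not depend on set hash order
            truth.effect_signs[(f"genotype:{g}", fid)] = int(rng.choice([-1, 1]))

    treatment_sets: dict[str, set[str]] = {}
    for g in config.genotypes:
        chosen = set(rng.choice(feature_ids, size=n_tde, replace=False)) if n_tde else set()
        treatment_sets[g] = chosen
        truth.treatment_de_features.setdefault(g, set()).update(chosen)
        for fid in sorted(chosen):  # sorted: sign draws must not depend on set hash order
            truth.effect_signs[(f"treatment:{g}:{treated}", fid)] = int(rng.choice([-1, 1]))
        # partition this genotype's responders into non-mPR vs mPR-specific
        ordered = sorted(chosen)
        n_non = round(config.frac_non_mpr * len(ordered))
        non = set(rng.choice(ordered, size=n_non, replace=False)) if n_non else set()
        truth.non_mpr_features |= non
        truth.mpr_specific_features |= set(ordered) - non
    # a feature planted as non-mPR in one genotype and mPR in another counts as non-mPR
    truth.mpr_specific_features -= truth.non_mpr_features
    return genotype_sets, treatment_sets


def _effect_matrix(
    config: ExperimentConfig,
    feature_ids: list[str],
    design: dict[str, SampleInfo],
    genotype_sets: dict[str, set[str]],
    treatment_sets: dict[str, set[str]],
    truth: GroundTruth,
) -> np.ndarray:
    """Planted log2 shifts per feature x sample."""
    idx = {fid: i for i, fid in enumerate(feature_ids)}
    shift = np.zeros((len(feature_ids), len(design)))
    treated = config.treatments[-1]
    for j, (sid, info) in enumerate(design.items()):
        for fid in genotype_sets.get(info.genotype, ()):
            sign = truth.effect_signs[(f"genotype:{info.genotype}", fid)]
            shift[idx[fid], j] += sign * config.effect_log2fc
        if info.treatment == treated:
            for fid in treatment_sets.get(info.genotype, ()):
                sign = truth.effect_signs[(f"treatment:{info.genotype}:{treated}", fid)]
                shift[idx[fid], j] += sign * config.effect_log2fc
    return shift


def generate_omics(config: ExperimentConfig) -> tuple[AbundanceMatrix, AbundanceMatrix, GroundTruth]:
    """Generate the proteomic intensity and RNA count matrices plus ground truth.

    Proteomic values are log-normal on the log2 scale: per-feature baseline
    log2 intensity ~ Uniform(18, 30) (iBAQ-like dynamic range) plus
    Normal(0, noise_sd_log2) replicate noise plus the planted shifts.
    RNA values are negative-binomial counts with per-feature log-normal
    means and a common dispersion; planted shifts multiply the mean by
    2**(signed effect).
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # --- proteomics ---------------------------------------------------
    prot_ids = [f"P{i:05d}" for i in range(config.n_features_protein)]
    prot_design = _make_design(config, "prot")
    geno_sets, treat_sets = _plant_effects(rng, config, prot_ids, truth)
    baseline = rng.uniform(18.0, 30.0, size=(config.n_features_protein, 1))
    noise = rng.normal(0.0, config.noise_sd_log2, size=(config.n_features_protein, len(prot_design)))
    shifts = _effect_matrix(config, prot_ids, prot_design, geno_sets, treat_sets, truth)
    log2_intensity = baseline + noise + shifts
    intensities = np.power(2.0, log2_intensity)
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities[mask] = 0.0  # missing-at-random non-detections
    proteomic = AbundanceMatrix(
        values=pd.DataFrame(intensities, index=prot_ids, columns=list(prot_design)),
        design=prot_design,
        modality="proteomic",
    )

    # --- RNA-seq ------------------------------------------------------
    rna_ids = [f"G{i:05d}" for i in range(config.n_features_rna)]
    rna_design = _make_design(config, "rna")
    rna_geno, rna_treat = _plant_effects(rng, config, rna_ids, truth)
    mean_log2 = rng.uniform(3.0, 12.0, size=(config.n_features_rna, 1))
    rna_shifts = _effect_matrix(config, rna_ids, rna_design, rna_geno, rna_treat, truth)
    mu = np.power(2.0, mean_log2 + rna_shifts)
    # NB with common dispersion a: var = mu + a*mu^2; gamma-Poisson mixture
    a = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / a, scale=a * mu)
    counts = rng.poisson(lam)
    rna = AbundanceMatrix(
        values=pd.DataFrame(counts, index=rna_ids, columns=list(rna_design)),
        design=rna_design,
        modality="rna",
    )
    return proteomic, rna, truth


def generate_gene_sets(
    n_terms: int,
    sizes: tuple[int, int],
    universe: list[str],
    planted_terms: int,
    ground_truth: GroundTruth,
    seed: int = 0,
    overlap_fraction: float = 0.6,
    category: str = "GO",
) -> GeneSetCollection:
    """Flat gene-set collection with ``planted_terms`` enriched for planted DE features.

    Planted terms draw ``overlap_fraction`` of their members from the
    ground-truth treatment-DE features (falling back to genotype-DE ids if
    none overlap the universe) and the rest from the background; the other
    terms are uniform draws from the universe.
    """
    if planted_terms > n_terms:
        raise ValueError("planted_terms cannot exceed n_terms")
    lo, hi = sizes
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("term size range must fit inside the universe")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    de_pool = sorted((ground_truth.all_treatment_de() | ground_truth.all_genotype_de()) & set(universe))
    background = sorted(set(universe) - set(de_pool))

    terms: dict[str, tuple[str, str, set[str]]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if i < planted_terms and de_pool:
            n_de = min(round(overlap_fraction * size), len(de_pool))
            members = set(rng.choice(de_pool, size=n_de, replace=False))
            rest = min(size - n_de, len(background))
            if rest > 0:
                members |= set(rng.choice(background, size=rest, replace=False))
            name = f"planted term {i}"
        else:
            members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
            name = f"background term {i}"
        terms[f"T{i:04d}"] = (name, category, members)
    return GeneSetCollection(terms=terms)


def generate_tf_benchmark(
    n_tf: int = 954,
    n_ntf: int = 2784,
    length_range: tuple[int, int] = (200, 1200),
    motif: str = DEFAULT_MOTIF,
    motif_copies: int = 3,
    seed: int = 0,
) -> SeqRecordSet:
    """Imbalanced TF/NTF benchmark with a planted motif in every TF sequence.

    TF records carry ``motif_copies`` non-overlapping copies of ``motif``
    at random positions (a short repeated motif standing in for the much
    longer DNA-binding domains of real TFs, so the class signal is clearly
    detectable); NTF records are motif-free random background over the
    20-letter alphabet.  The default composition (954 TF / 2784 NTF, 3738
    records total) matches the benchmark regime the predictor is meant for.
    """
    bad = set(motif) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"motif contains non-amino-acid symbols: {sorted(bad)}")
    lo, hi = length_range
    if len(motif) >= lo:
        raise ValueError("motif must be shorter than the minimum sequence length")
    if motif_copies < 1:
        raise ValueError("motif_copies must be >= 1")
    if motif_copies * len(motif) > lo:
        raise ValueError("motif copies must fit inside the minimum sequence length")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    def random_seq(length: int) -> str:
        return "".join(rng.choice(aa, size=length))

    records: list[SeqRecord] = []
    m = len(motif)
    for i in range(n_tf):
        length = int(rng.integers(lo, hi + 1))
        seq = random_seq(length)
        # non-overlapping slots: pick copy starts on a motif-length grid
        slots = rng.choice(length // m, size=motif_copies, replace=False)
        for slot in slots:
            pos = int(slot) * m
            seq = seq[:pos] + motif + seq[pos + m:]
        records.append(SeqRecord(id=f"TF{i:05d}", sequence=seq, label=TF))
    for i in range(n_ntf):
        length = int(rng.integers(lo, hi + 1))
        seq = random_seq(length)
        while motif in seq:  # keep the background genuinely motif-free
            seq = random_seq(length)
        records.append(SeqRecord(id=f"NTF{i:05d}", sequence=seq, label=NTF))
    return SeqRecordSet(records=records)


def generate_antagonist_filter(
    ground_truth: GroundTruth,
    coverage: float = 1.0,
    seed: int = 0,
    n_background: int = 50,
    background_pool: list[str] | None = None,
) -> set[str]:
    """Antagonist (non-mPR) filter set: covered planted non-mPR ids plus background.

    Covers ``coverage`` of the ground-truth non-mPR planted features and
    adds ``n_background`` ids drawn from ``background_pool`` (never from
    the designated mPR-specific planted features, which the filter must
    leave untouched).
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    non_mpr = sorted(ground_truth.non_mpr_features)
    n_cover = round(coverage * len(non_mpr))
    chosen = set(rng.choice(non_mpr, size=n_cover, replace=False)) if n_cover else set()
    if background_pool:
        pool = sorted(set(background_pool)
                      - ground_truth.mpr_specific_features
                      - ground_truth.non_mpr_features)
        n_bg = min(n_background, len(pool))
        if n_bg:
            chosen |= set(rng.choice(pool, size=n_bg, replace=False))
    return chosen


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    import json

    payload = {
        "genotype_de_features": {g: sorted(s) for g, s in truth.genotype_de_features.items()},
        "treatment_de_features": {g: sorted(s) for g, s in truth.treatment_de_features.items()},
        "tf_ids": sorted(truth.tf_ids),
        "effect_signs": {f"{ctx}|{fid}": sign for (ctx, fid), sign in sorted(truth.effect_signs.items())},
        "non_mpr_features": sorted(truth.non_mpr_features),
        "mpr_specific_features": sorted(truth.mpr_specific_features),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
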