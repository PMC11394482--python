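"""End-to-end orchestration: generate -> DE -> Venn -> filtration -> ORA -> TF prediction.

``run_pipeline`` executes every stage on synthetic inputs (or files given
in the config), writes all stage outputs under an output directory, and
records a manifest (seeds, per-stage row counts, file checksums).  Re-running
with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import datasets
from .datasets import ExperimentConfig
from .diffexpr import DEConfig, call_de
from .enrichment import comparative_dotplot, ora
from .setops import FilterSpec, SetFamily, two_step_filtration, venn_partition, write_set_family
from .tfpred import CVConfig, cross_validate

log = logging.getLogger("cmpnomics")


@dataclass
class PipelineConfig:
    """Everything one run needs; the seed feeds every stochastic stage."""

    outdir: Path
    seed: int = 0
    experiment: ExperimentConfig | None = None
    de: DEConfig = field(default_factory=DEConfig)
    cv: CVConfig | None = None
    n_terms: int = 50
    planted_terms: int = 5
    term_sizes: tuple[int, int] = (10, 40)
    filter_coverage: float = 1.0
    tf_benchmark: tuple[int, int] = (120, 280)  # (n_tf, n_ntf); None-like (0,0) skips the TF stage
    run_tf_stage: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a run config from a YAML (or JSON) mapping.

        Top-level keys mirror the dataclass fields; the nested
        ``experiment``, ``de`` and ``cv`` mappings feed ExperimentConfig,
        DEConfig and CVConfig.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "outdir" not in raw:
            raise ValueError("pipeline config needs an 'outdir'")
        kwargs = dict(raw)
        kwargs["outdir"] = Path(kwargs["outdir"])
        if "experiment" in kwargs and kwargs["experiment"] is not None:
            exp = dict(kwargs["experiment"])
            for key in ("genotypes", "treatments"):
                if key in exp:
                    exp[key] = tuple(exp[key])
            kwargs["experiment"] = ExperimentConfig(**exp)
        if "de" in kwargs and kwargs["de"] is not None:
            kwargs["de"] = DEConfig(**kwargs["de"])
        if "cv" in kwargs and kwargs["cv"] is not None:
            kwargs["cv"] = CVConfig(**kwargs["cv"])
        for key in ("term_sizes", "tf_benchmark"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to ``manifest.json``)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = config.experiment or ExperimentConfig(seed=config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name, fn):
        start = time.time()
        try:
            result = fn()
        except Exception as err:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        log.info("stage %s done in %.2fs", name, time.time() - start)
        return result

    # --- generate -----------------------------------------------------
    proteomic, rna, truth = stage("generate", lambda: datasets.generate_omics(exp))
    proteomic.to_tsv(outdir / "proteomic.tsv", outdir / "proteomic_design.tsv")
    rna.to_tsv(outdir / "rna.tsv", outdir / "rna_design.tsv")
    datasets.write_ground_truth(truth, outdir / "ground_truth.json")
    manifest["stages"]["generate"] = {
        "n_features_protein": len(proteomic.feature_ids),
        "n_features_rna": len(rna.feature_ids),
        "n_samples": len(proteomic.sample_ids),
    }

    # --- differential expression: treated vs vehicle per genotype -----
    treated, vehicle = exp.treatments[-1], exp.treatments[0]
    de_members: dict[str, set[str]] = {}
    de_counts = {}
    for g in exp.genotypes:
        res = stage(f"de:{g}", lambda g=g: call_de(
            proteomic,
            proteomic.samples_where(genotype=g, treatment=vehicle),
            proteomic.samples_where(genotype=g, treatment=treated),
            config.de,
        ))
        res.to_tsv(outdir / f"de_{g}.tsv")
        res.volcano_table().to_csv(outdir / f"volcano_{g}.tsv", sep="\t", index=False)
        up, down, sig = res.de_sets()
        de_members[g] = sig
        de_counts[g] = {"up": len(up), "down": len(down), "significant": len(sig)}
    manifest["stages"]["de"] = de_counts

    # --- Venn partition of the per-genotype response sets -------------
    family = SetFamily(name="prg_response", members=de_members)
    denominator = len(proteomic.feature_ids)
    partition = stage("venn", lambda: venn_partition(family, denominator))
    partition.to_tsv(outdir / "venn_prg_response.tsv")
    partition.to_json(outdir / "venn_prg_response.json")
    manifest["stages"]["venn"] = {"union": len(family.union()), "denominator": denominator}

    # --- two-step filtration ------------------------------------------
    layer1 = truth.all_genotype_de() & set(proteomic.feature_ids)
    layer2 = stage("antagonist_filter", lambda: datasets.generate_antagonist_filter(
        truth, coverage=config.filter_coverage, seed=config.seed,
        background_pool=proteomic.feature_ids,
    ))
    spec = FilterSpec(layer1=layer1, layer2=layer2, id_normalization="exact")
    surviving, report = stage("filtration", lambda: two_step_filtration(family, spec))
    write_set_family(surviving, outdir / "mpr_specific_family.tsv")
    (outdir / "filtration_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    manifest["stages"]["filtration"] = report.to_dict()

    # --- enrichment ----------------------------------------------------
    universe = list(proteomic.feature_ids)
    collection = stage("gene_sets", lambda: datasets.generate_gene_sets(
        config.n_terms, config.term_sizes, universe, config.planted_terms, truth, seed=config.seed,
    ))
    collection.to_gmt(outdir / "gene_sets.gmt")
    ora_results = {}
    for g in exp.genotypes:
        res = stage(f"ora:{g}", lambda g=g: ora(de_members[g], universe, collection))
        res.to_tsv(outdir / f"ora_{g}.tsv")
        ora_results[g] = res
    dotplot = stage("dotplot", lambda: comparative_dotplot(ora_results))
    dotplot.to_tsv(outdir / "dotplot.tsv")
    manifest["stages"]["ora"] = {g: len(r.table) for g, r in ora_results.items()}

    # --- TF prediction -------------------------------------------------
    if config.run_tf_stage and config.tf_benchmark[0] > 0:
        n_tf, n_ntf = config.tf_benchmark
        cv = config.cv or CVConfig(folds=5, seed=config.seed)
        seqs = stage("tf_benchmark", lambda: datasets.generate_tf_benchmark(
            n_tf=n_tf, n_ntf=n_ntf, seed=config.seed,
        ))
        seqs.to_fasta(outdir / "tf_benchmark.fasta")
        cvreport = stage("tf_cv", lambda: cross_validate(seqs, config=cv))
        cvreport.to_json(outdir / "tf_cv_report.json")
        cvreport.per_fold_tsv(outdir / "tf_cv_folds.tsv")
        candidates = cvreport.consensus_candidates()
        (outdir / "tf_candidates.txt").write_text("\n".join(candidates) + "\n")
        manifest["stages"]["tfpredict"] = {
            "records": n_tf + n_ntf,
            "means": cvreport.means,
            "candidates": len(candidates),
        }
    else:
        manifest["stages"]["tfpredict"] = {"skipped": True}

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
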