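"""File-based orchestration of the full analysis.

Stages (validate -> stats -> usage -> cluster -> pairs -> dnds -> classify ->
specific -> enrich) each read and write plain TSV/FASTA files in the output
directory, so any stage can be rerun or replaced by an external tool.  A run
manifest records the configuration, input checksums, per-stage row counts and
seeds; reruns with an identical configuration produce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import codon_usage, enrichment, homology, selection, seqio, specificity

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "validate",
    "stats",
    "usage",
    "cluster",
    "pairs",
    "dnds",
    "classify",
    "specific",
    "enrich",
]


@dataclass
class PipelineConfig:
    focal_fasta: str
    outdir: str
    comparator_fastas: dict[str, str] = field(default_factory=dict)
    annotation_tsv: Optional[str] = None
    go_map_tsv: Optional[str] = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    min_coverage: float = 0.6
    min_identity: float = 0.75
    ultra_threshold: float = 0.001
    neutral_epsilon: float = 0.05
    min_term_size: int = 5
    min_codons: int = 30
    k_min: int = 2
    k_max: int = 8
    n_init: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_config(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        paths = [self.focal_fasta, *self.comparator_fastas.values()]
        if "specific" in self.stages or "enrich" in self.stages:
            if self.annotation_tsv is None and "specific" in self.stages:
                raise ValueError("stage 'specific' requires annotation_tsv")
            if self.go_map_tsv is None and "enrich" in self.stages:
                raise ValueError("stage 'enrich' requires go_map_tsv")
        if self.annotation_tsv:
            paths.append(self.annotation_tsv)
        if self.go_map_tsv:
            paths.append(self.go_map_tsv)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not (0 <= self.min_coverage <= 1 and 0 <= self.min_identity <= 1):
            raise ValueError("coverage/identity thresholds must lie in [0, 1]")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    df.to_csv(tmp, sep="\t", index=False)
    tmp.replace(path)


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    config.validate_config()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {**config.__dict__},
        "inputs": {},
        "stages": {},
        "seed": config.seed,
    }
    for name, p in [
        ("focal_fasta", config.focal_fasta),
        *[(f"comparator:{k}", v) for k, v in config.comparator_fastas.items()],
        ("annotation_tsv", config.annotation_tsv),
        ("go_map_tsv", config.go_map_tsv),
    ]:
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    stages = [s for s in ALL_STAGES if s in config.stages]
    state: dict = {}

    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s started", stage)
        n_rows = _STAGE_FUNCS[stage](config, outdir, state)
        # timings go to the log only, keeping the manifest byte-reproducible
        manifest["stages"][stage] = {"rows": n_rows}
        logger.info(
            "stage %s done (%s rows, %.3fs)", stage, n_rows, time.perf_counter() - t0
        )

    tmp = outdir / "run_manifest.json.partial"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.replace(outdir / "run_manifest.json")
    return manifest


# --- stage implementations -------------------------------------------------


def _load_validated(config: PipelineConfig, state: dict) -> None:
    if "focal" in state:
        return
    focal = seqio.validate_cds(
        seqio.read_fasta(config.focal_fasta, species="focal"),
        min_codons=config.min_codons,
    )
    state["focal"] = focal
    state["comparators"] = {}
    for name, path in config.comparator_fastas.items():
        state["comparators"][name] = seqio.validate_cds(
            seqio.read_fasta(path, species=name), min_codons=config.min_codons
        )


def _stage_validate(config: PipelineConfig, outdir: Path, state: dict) -> int:
    _load_validated(config, state)
    seqio.write_validation_report(state["focal"], outdir / "validation_focal.tsv")
    seqio.write_fasta(state["focal"].valid_only(), outdir / "validated_focal.fasta")
    for name, cset in state["comparators"].items():
        seqio.write_validation_report(cset, outdir / f"validation_{name}.tsv")
    return len(state["focal"])


def _stage_stats(config: PipelineConfig, outdir: Path, state: dict) -> int:
    _load_validated(config, state)
    stats = seqio.assembly_stats(state["focal"])
    seqio.write_assembly_stats(stats, outdir / "assembly_stats.tsv")
    return 1


def _stage_usage(config: PipelineConfig, outdir: Path, state: dict) -> int:
    _load_validated(config, state)
    profiles = codon_usage.profile_set(state["focal"])
    _atomic_write_df(profiles, outdir / "codon_usage.tsv")
    matrix = codon_usage.rscu_matrix(state["focal"])
    matrix.to_csv(outdir / "rscu_matrix.tsv", sep="\t", index_label="gene_id")
    codon_usage.histogram_export(
        profiles[["enc_ratio", "gc3_gc12_ratio"]], outdir / "usage_histograms.tsv"
    )
    state["profiles"] = profiles
    state["rscu_matrix"] = matrix
    return len(profiles)


def _stage_cluster(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "rscu_matrix" not in state:
        state["rscu_matrix"] = pd.read_csv(
            outdir / "rscu_matrix.tsv", sep="\t", index_col="gene_id"
        )
    prepared = cluster_mod.prepare_matrix(state["rscu_matrix"])
    result = cluster_mod.kmeans_scan(
        prepared,
        k_range=range(config.k_min, config.k_max + 1),
        n_init=config.n_init,
        seed=config.seed,
    )
    cluster_mod.write_cluster_outputs(result, outdir)
    state["clustering"] = result
    return len(result.labels)


def _stage_pairs(config: PipelineConfig, outdir: Path, state: dict) -> int:
    _load_validated(config, state)
    paralogs = homology.find_paralog_pairs(
        state["focal"], config.min_coverage, config.min_identity
    )
    homology.write_pairs(paralogs, outdir / "paralog_pairs.tsv")
    state["paralogs"] = paralogs
    state["orthologs"] = {}
    n = paralogs.n_pairs
    for name, cset in state["comparators"].items():
        orth = homology.find_ortholog_pairs(
            state["focal"], cset, config.min_coverage, config.min_identity
        )
        homology.write_pairs(orth, outdir / f"ortholog_pairs_{name}.tsv")
        state["orthologs"][name] = orth
        n += orth.n_pairs
    return n


def _stage_dnds(config: PipelineConfig, outdir: Path, state: dict) -> int:
    frames = []
    if "paralogs" in state:
        frames.append(selection.estimate_pairset(state["paralogs"], "paralog"))
    for name, orth in state.get("orthologs", {}).items():
        frames.append(selection.estimate_pairset(orth, f"ortholog:{name}"))
    if not frames:
        raise RuntimeError("stage dnds requires stage pairs in the same run")
    nonempty = [f for f in frames if len(f)]
    estimates = pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]
    _atomic_write_df(estimates, outdir / "dnds_estimates.tsv")
    codon_usage.histogram_export(
        estimates[["dn", "ds", "omega"]], outdir / "dnds_histograms.tsv"
    )
    state["estimates"] = estimates
    return len(estimates)


def _stage_classify(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "estimates" not in state:
        state["estimates"] = pd.read_csv(outdir / "dnds_estimates.tsv", sep="\t")
    classified = selection.classify(
        state["estimates"], config.ultra_threshold, config.neutral_epsilon
    )
    _atomic_write_df(classified, outdir / "dnds_classified.tsv")
    state["classified"] = classified
    return len(classified)


def _stage_specific(config: PipelineConfig, outdir: Path, state: dict) -> int:
    _load_validated(config, state)
    annotations = specificity.read_annotations(config.annotation_tsv)
    ortholog_evidence: dict[str, pd.DataFrame] = {}
    for name, orth in state.get("orthologs", {}).items():
        ortholog_evidence[name] = orth.to_frame()
    # orthogroup columns in the annotation table also count as comparator hits
    for col in annotations.columns:
        if col.startswith("og_"):
            present = annotations.loc[
                annotations[col].notna() & (annotations[col].astype(str) != ""),
                "gene_id",
            ]
            ortholog_evidence[col] = pd.DataFrame({"id_a": present})
    calls = specificity.call_specific(
        annotations,
        ortholog_evidence,
        gene_ids=state["focal"].ids,
        paralog_pairs=state.get("paralogs"),
    )
    specificity.write_specificity(calls, outdir / "specificity.tsv")
    specificity.write_venn(specificity.venn_counts(annotations), outdir / "venn.tsv")
    state["specificity"] = calls
    return int(calls["is_specific"].sum())


def _stage_enrich(config: PipelineConfig, outdir: Path, state: dict) -> int:
    go_map = specificity.read_go_map(config.go_map_tsv)
    background = set(go_map["gene_id"])
    study_sets: dict[str, set[str]] = {}
    if "classified" in state:
        ultra = selection.gene_set_by_class(state["classified"], "ultra_conserved")
        positive = selection.gene_set_by_class(state["classified"], "positive")
        if ultra:
            study_sets["ultra_conserved"] = ultra & background
        if positive:
            study_sets["positive"] = positive & background
    if "specificity" in state:
        spec = set(
            state["specificity"].loc[state["specificity"]["is_specific"], "gene_id"]
        )
        if spec:
            study_sets["species_specific"] = spec & background
    n = 0
    for name, study in study_sets.items():
        if not study:
            logger.warning("study set %s has no annotated genes; skipped", name)
            continue
        result = enrichment.enrich(
            study, background, go_map, min_term_size=config.min_term_size
        )
        _atomic_write_df(result, outdir / f"enrichment_{name}.tsv")
        n += len(result)
    if not study_sets:
        logger.warning("no study sets available for enrichment")
    return n


_STAGE_FUNCS = {
    "validate": _stage_validate,
    "stats": _stage_stats,
    "usage": _stage_usage,
    "cluster": _stage_cluster,
    "pairs": _stage_pairs,
    "dnds": _stage_dnds,
    "classify": _stage_classify,
    "specific": _stage_specific,
    "enrich": _stage_enrich,
}
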