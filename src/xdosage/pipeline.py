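"""End-to-end orchestration: data (real or simulated) -> gene subgroups ->
RXE/RGE -> compensation calls and boxplot summaries -> bootstrap DE ->
group statistics -> report and run manifest.

Every run is driven by a :class:`PipelineConfig` and a seed; identical
config + seed reproduce byte-identical numeric outputs.  The manifest records
the config, seed, package version and a SHA-256 digest of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    ExpressionMatrix,
    GeneAnnotation,
    ValidationError,
    read_expression_matrix,
    read_gene_map,
    read_par_list,
)
from .bootstrap_de import BootstrapConfig, bootstrap_de, degs_to_frame, filter_x_linked
from .dosage_metrics import (
    SUBGROUP_NAMES,
    SubgroupSpec,
    relative_expression,
    results_to_frame,
    rge_to_frame,
    summarize_group,
    tissue_mean_rxe,
)
from .group_stats import (
    anova_expressed_counts,
    compare_rxe_by_diet,
    compare_rxe_by_sex,
    comparisons_to_frame,
    count_expressed_x_genes,
    expressed_x_count_table,
)
from .synthetic_data import (
    SyntheticConfig,
    config_from_dict,
    config_to_dict,
    generate_annotation,
    generate_expression,
)

logger = logging.getLogger("xdosage")


@dataclass
class PipelineConfig:
    """Inputs, stage selection and output location for one run.

    Either ``synthetic`` is set (simulation mode) or the three real-data
    paths are given (``par_list_path`` optional).  ``seed`` overrides the
    synthetic config's seed and seeds the bootstrap.
    """

    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    gene_map_path: str | None = None
    par_list_path: str | None = None
    subgroups: list[str] = field(default_factory=lambda: list(SUBGROUP_NAMES))
    expressed_threshold: float = 1.0
    rxe_method: str = "log_of_mean"
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    de_group_column: str = "treatment"
    de_comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("Con", "Over"), ("Con", "Res")]
    )
    de_per_tissue: bool = True
    out_dir: str = "xdosage_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = set(self.subgroups) - set(SUBGROUP_NAMES)
        if bad:
            raise ValidationError(f"unknown subgroups: {sorted(bad)}")
        if self.synthetic is None:
            missing = [
                name
                for name, value in [
                    ("expression_path", self.expression_path),
                    ("metadata_path", self.metadata_path),
                    ("gene_map_path", self.gene_map_path),
                ]
                if value is None
            ]
            if missing:
                raise ValidationError(
                    f"real-data mode requires {missing} (or a synthetic block)"
                )


def config_from_yaml(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("synthetic") is not None:
        d["synthetic"] = config_from_dict(d["synthetic"])
    if d.get("bootstrap") is not None:
        d["bootstrap"] = BootstrapConfig(**d["bootstrap"])
    if d.get("de_comparisons") is not None:
        d["de_comparisons"] = [tuple(pair) for pair in d["de_comparisons"]]
    return PipelineConfig(**d)


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
    return handler

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig) -> tuple[ExpressionMatrix, GeneAnnotation]:
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        annotation = generate_annotation(syn)
        matrix = generate_expression(annotation, syn)
        logger.info(
            "simulated %d genes x %d samples (u=%.3g)",
            len(annotation), len(matrix.sample_ids), syn.upregulation_factor_u,
        )
        return matrix, annotation
    annotation = read_gene_map(config.gene_map_path)
    if config.par_list_path:
        annotation = read_par_list(config.par_list_path, annotation)
    matrix = read_expression_matrix(config.expression_path, config.metadata_path)
    return matrix, annotation


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, config.log_level)
    outputs: dict[str, Path] = {}
    try:
        stage = "load"
        matrix, annotation = _load_inputs(config)

        stage = "relative_expression"
        boxplots: dict[str, dict] = {}
        results_by_subgroup = {}
        for name in config.subgroups:
            spec = SubgroupSpec(name=name, expressed_threshold=config.expressed_threshold)
            results = relative_expression(
                matrix, annotation, spec, method=config.rxe_method
            )
            results_by_subgroup[name] = results
            rxe_path = out / f"rxe_{name}.tsv"
            results_to_frame(results).to_csv(rxe_path, sep="\t", index=False)
            outputs[f"rxe_{name}"] = rxe_path
            rge_path = out / f"rge_{name}.tsv"
            rge_to_frame(results).to_csv(rge_path, sep="\t", index=False)
            outputs[f"rge_{name}"] = rge_path
            # per-sample boxplot of the autosomal RGE spread, the band the
            # X chromosome is judged against
            boxplots[name] = {
                r.sample_id: dataclasses.asdict(
                    summarize_group(list(r.rge_by_chromosome.items()))
                )
                for r in results
                if len(r.rge_by_chromosome) >= 2
            }
            boxplots[name]["tissue_mean_rxe"] = tissue_mean_rxe(results)
        box_path = out / "boxplots.json"
        box_path.write_text(json.dumps(boxplots, indent=1, sort_keys=True))
        outputs["boxplots"] = box_path

        stage = "bootstrap_de"
        de_frames, x_frames = [], []
        tissues = (
            sorted(matrix.samples["tissue"].unique()) if config.de_per_tissue else [None]
        )
        for ref, alt in config.de_comparisons:
            for tissue in tissues:
                sub = matrix
                if tissue is not None:
                    ids = matrix.samples.index[matrix.samples["tissue"] == tissue]
                    sub = matrix.subset_samples(list(ids))
                levels = set(sub.samples[config.de_group_column])
                if not {ref, alt} <= levels:
                    logger.warning(
                        "skipping DE %s vs %s in %s: level(s) absent",
                        ref, alt, tissue or "all",
                    )
                    continue
                boot = dataclasses.replace(config.bootstrap, seed=config.seed)
                degs = bootstrap_de(
                    sub, config.de_group_column, ref, alt, boot
                )
                label = f"{ref}_vs_{alt}"
                de_frames.append(
                    degs_to_frame(degs, comparison=label, tissue=tissue or "all")
                )
                x_degs = filter_x_linked(degs, annotation)
                x_frames.append(
                    degs_to_frame(x_degs, comparison=label, tissue=tissue or "all")
                )
        if de_frames:
            de_path = out / "degs.tsv"
            pd.concat(de_frames, ignore_index=True).to_csv(de_path, sep="\t", index=False)
            outputs["degs"] = de_path
            x_path = out / "x_degs.tsv"
            pd.concat(x_frames, ignore_index=True).to_csv(x_path, sep="\t", index=False)
            outputs["x_degs"] = x_path

        stage = "group_stats"
        comparisons = []
        stats_subgroup = "EXPRESSED" if "EXPRESSED" in results_by_subgroup else config.subgroups[0]
        results = results_by_subgroup[stats_subgroup]
        for tissue in sorted({r.tissue for r in results}):
            in_tissue = [r for r in results if r.tissue == tissue]
            sexes = {r.sex for r in in_tissue} - {"unknown"}
            if len(sexes) == 2 and all(
                sum(r.sex == s for r in in_tissue) >= 2 for s in sexes
            ):
                comparisons.append(
                    (f"rxe_sex_{tissue}", compare_rxe_by_sex(in_tissue))
                )
            for ref, alt in config.de_comparisons:
                if {ref, alt} <= {r.treatment for r in in_tissue}:
                    comparisons.append(
                        (
                            f"rxe_diet_{tissue}_{ref}_vs_{alt}",
                            compare_rxe_by_diet(in_tissue, ref, alt),
                        )
                    )
        counts = count_expressed_x_genes(matrix, annotation, config.expressed_threshold)
        meta = matrix.samples
        for tissue in sorted(meta["tissue"].unique()):
            by_trt = {
                trt: [
                    counts[s]
                    for s in meta.index[
                        (meta["tissue"] == tissue) & (meta["treatment"] == trt)
                    ]
                ]
                for trt in sorted(meta.loc[meta["tissue"] == tissue, "treatment"].unique())
            }
            by_trt = {k: v for k, v in by_trt.items() if len(v) >= 2}
            if len(by_trt) >= 2:
                comparisons.append(
                    (f"x_gene_counts_{tissue}", anova_expressed_counts(by_trt))
                )
        stats_path = out / "group_stats.tsv"
        comparisons_to_frame(comparisons).to_csv(stats_path, sep="\t", index=False)
        outputs["group_stats"] = stats_path
        counts_path = out / "expressed_x_counts.tsv"
        expressed_x_count_table(matrix, annotation, config.expressed_threshold).to_csv(
            counts_path, sep="\t", index=False
        )
        outputs["expressed_x_counts"] = counts_path
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        logger.removeHandler(handler)
        handler.close()
        raise
    stage = "manifest"
    manifest = {
        "package": "xdosage",
        "version": __version__,
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return manifest


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = config_to_dict(config.synthetic)
    d["de_comparisons"] = [list(pair) for pair in config.de_comparisons]
    return d


def collect_report(run_dir: str | Path) -> dict:
    """Bundle a run's outputs into one JSON-serializable report."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    report = {"manifest": manifest, "tables": {}}
    for name, entry in manifest["outputs"].items():
        path = Path(entry["path"])
        if path.suffix == ".tsv":
            report["tables"][name] = pd.read_csv(path, sep="\t").to_dict("records")
        elif path.suffix == ".json":
            report["tables"][name] = json.loads(path.read_text())
    return report
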