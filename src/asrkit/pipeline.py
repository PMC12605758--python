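"""End-to-end analysis pipeline: annotations -> ASR -> bias model -> ASR*.

A :class:`RunConfig` (loadable from a small YAML file) drives the full
workflow: compute ASR from annotation files (or simulate a species
panel), join with annotation metadata, build the Spearman matrix, run
LASSO selection, fit the quartic expectation, derive sigma_min and the
normalized ASR* values, and write every artifact plus a machine-readable
summary and the resolved configuration next to the outputs. A stage
failure aborts with the stage name; artifacts written so far are kept
and listed in a MANIFEST.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gff_model, stats_pipeline
from .metadata_report import METRIC_NAMES, SpeciesTable, read_species_table
from .stats_pipeline import SUPPORT_FRACTION_COL
from .synthetic_data import SpeciesSimParams, simulate_species_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_LASSO_PREDICTORS"]

# The reduced, low-collinearity predictor set used for LASSO selection.
DEFAULT_LASSO_PREDICTORS = [
    "contig_n50",
    "scaffold_n50",
    "n_proteins_hsapiens",
    "n_transcripts_hsapiens",
    "n_rnaseq_reads",
    "cds_fully_supported_pct",
    "cds_from_model_pct",
    "cds_known_pct",
]

STAGE_EXIT_CODES = {
    "compute-asr": 10,
    "join": 11,
    "correlate": 12,
    "lasso": 13,
    "normalize": 14,
    "evaluate": 15,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass(slots=True)
class RunConfig:
    """Resolved configuration for one pipeline run.

    Defaults mirror the analysis conventions: degree-4 polynomial,
    80/20 train/test split, 10-fold cross-validation. Either
    ``species_table`` points at an existing table (TSV), or
    ``simulate`` is true and a panel is generated with ``seed``.
    """

    out_prefix: str = "asrkit_run"
    gff_files: list[str] = field(default_factory=list)
    species_table: str | None = None
    simulate: bool = False
    n_species: int = 670
    seed: int = 0
    degree: int = 4
    split_fraction: float = 0.8
    folds: int = 10
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_LASSO_PREDICTORS))
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dict.

    Artifacts are written under ``config.out_prefix``; the resolved
    config and a MANIFEST of written files accompany them.
    """
    logging.basicConfig(level=config.log_level)
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    summary: dict = {"seed": config.seed}

    def _write_manifest(complete: bool) -> None:
        manifest = {"complete": complete, "artifacts": written}
        p = prefix.with_name(prefix.name + ".MANIFEST.json")
        p.write_text(json.dumps(manifest, indent=2) + "\n")

    cfg_path = prefix.with_name(prefix.name + ".config.yaml")
    cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    written.append(str(cfg_path))

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                _write_manifest(complete=False)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return deco

    # --- compute-asr ------------------------------------------------------
    @stage("compute-asr")
    def asr_values() -> dict[str, float]:
        out: dict[str, float] = {}
        for path in config.gff_files:
            aset = gff_model.parse_gff3(path)
            res = gff_model.genome_asr(aset)
            name = Path(path).stem
            out[name] = res.genome_asr
            tsv = prefix.with_name(prefix.name + f".{name}.per_gene.tsv")
            gff_model.write_per_gene_tsv(res, aset, tsv)
            js = prefix.with_name(prefix.name + f".{name}.genome.json")
            gff_model.write_genome_summary(res, js)
            written.extend([str(tsv), str(js)])
        return out

    summary["genome_asr"] = asr_values

    # --- join -------------------------------------------------------------
    @stage("join")
    def table() -> SpeciesTable | None:
        if config.species_table:
            return read_species_table(config.species_table)
        if config.simulate:
            return simulate_species_table(
                SpeciesSimParams(n_species=config.n_species, seed=config.seed)
            )
        if config.gff_files:
            return None  # annotation-only run: stats stages skipped
        raise ValueError("no input: set gff_files, species_table or simulate: true")

    if table is None:
        summary["stats"] = "skipped (no species table)"
        sp = prefix.with_name(prefix.name + ".summary.json")
        sp.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(str(sp))
        _write_manifest(complete=True)
        return summary

    tbl_path = prefix.with_name(prefix.name + ".species_table.tsv")
    table.write_tsv(tbl_path)
    written.append(str(tbl_path))
    summary["n_species"] = len(table)

    # --- correlate --------------------------------------------------------
    @stage("correlate")
    def corr():
        variables = ["asr", *[m for m in METRIC_NAMES]]
        cm = stats_pipeline.spearman_matrix(table, variables)
        written.extend(str(p) for p in cm.write_tsv(prefix))
        return cm

    summary["rho_asr_support_pct"] = float(
        corr.rho.loc["asr", SUPPORT_FRACTION_COL]
    )

    # --- lasso ------------------------------------------------------------
    @stage("lasso")
    def lasso():
        fit = stats_pipeline.lasso_select(
            table,
            predictors=config.predictors,
            split_fraction=config.split_fraction,
            folds=config.folds,
            seed=config.seed,
        )
        p = prefix.with_name(prefix.name + ".lasso.json")
        fit.to_json(p)
        written.append(str(p))
        return fit

    summary["lasso_selected"] = lasso.selected
    summary["lasso_test_r2"] = lasso.test_r2

    # --- normalize --------------------------------------------------------
    @stage("normalize")
    def norm():
        df = table.complete_frame(["asr", SUPPORT_FRACTION_COL])
        fit = stats_pipeline.fit_polynomial(
            df[SUPPORT_FRACTION_COL].to_numpy(float) / 100.0,
            df["asr"].to_numpy(float),
            degree=config.degree,
        )
        model = stats_pipeline.build_normalization(fit, table)
        p = prefix.with_name(prefix.name + ".normalization.json")
        model.to_json(p)
        written.append(str(p))
        star = stats_pipeline.normalize_table(model, table)
        sp = prefix.with_name(prefix.name + ".asr_star.tsv")
        star.to_csv(sp, sep="\t", index=False)
        written.append(str(sp))
        return model

    summary["beta_raw_basis"] = norm.fit.beta.tolist()
    summary["beta_scaled_basis"] = norm.fit.scaled_coef.tolist()
    summary["sigma_min"] = norm.sigma_min
    summary["fit_r2"] = norm.fit.r2

    # --- evaluate ---------------------------------------------------------
    @stage("evaluate")
    def report():
        return stats_pipeline.evaluate_normalization(norm, table)

    summary["evaluation"] = report

    sp = prefix.with_name(prefix.name + ".summary.json")
    sp.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(str(sp))
    _write_manifest(complete=True)
    return summary
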