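"""Pipeline orchestration: scoring -> filtering -> DE -> clustering ->
network -> enrichment -> validation, with a declarative YAML config, stage
logging and a report bundle (stage TSVs + JSON summary + log)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clinical, enrichment, validation
from .de import DEConfig, ExactTestDE
from .expression import (
    CountMatrix,
    ExpressionFilterConfig,
    cluster_samples,
    cpm,
    filter_expressed,
    log_cpm10,
    log_fpkm,
)
from .network import CoexpressionNetwork, NetworkConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "demo_table1"]


class ConfigError(Exception):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Malformed or missing input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    clinical_csv: str = ""
    counts_tsv: str = ""
    lengths_tsv: Optional[str] = None
    annotation_tsv: Optional[str] = None
    mapping_tsv: Optional[str] = None
    ki67_fields_csv: Optional[str] = None
    caf_fields_csv: Optional[str] = None
    outdir: str = "mctomics_run"
    seed: int = 0
    min_cpm: float = 1.0
    min_samples: int = 4
    de_alpha: float = 0.05
    de_min_abs_logfc: float = 2.0
    beta: float = 11.0
    n_top_genes: int = 6000
    min_module_size: int = 30
    trait_p_threshold: float = 0.1
    enrich_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name, path in [("clinical_csv", self.clinical_csv), ("counts_tsv", self.counts_tsv)]:
            if not path:
                raise ConfigError(f"{name} is required")
            if not Path(path).exists():
                raise DataError(f"input file not found: {path}")
        for name in ("lengths_tsv", "annotation_tsv", "mapping_tsv",
                     "ki67_fields_csv", "caf_fields_csv"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise DataError(f"input file not found: {p}")
        if not 0 < self.de_alpha < 1 or not 0 < self.enrich_alpha < 1:
            raise ConfigError("alpha levels must lie in (0, 1)")

    def content_hash(self) -> str:
        # outdir is excluded: the hash identifies inputs and parameters,
        # not where the report lands
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except (ConfigError, DataError):
                raise
            except Exception as exc:
                raise DataError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the JSON-able run summary.

    Outputs are written under ``config.outdir``: per-stage TSVs, a
    ``summary.json`` stamped with the config hash and seed, and a run log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("mctomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"config_hash": config.content_hash(), "seed": config.seed}
    try:
        # 1. clinical scoring -------------------------------------------------
        records = _stage("score")(clinical.read_clinical_csv)(config.clinical_csv)
        score_table, cohort = clinical.score_cohort(records)
        clinical.write_score_table(score_table, outdir / "malignancy_scores.tsv")
        risk = score_table.set_index("sample_id")["risk"]
        scores = score_table.set_index("sample_id")["total"].astype(float)
        summary["risk_group_sizes"] = {
            "high": cohort.n_high_risk, "low": cohort.n_low_risk
        }

        # 2. expression matrix ------------------------------------------------
        matrix = _stage("expression")(CountMatrix.from_tsv)(
            config.counts_tsv, config.lengths_tsv
        )
        missing = set(matrix.sample_ids) ^ set(risk.index)
        if missing:
            raise DataError(
                f"clinical table and count matrix disagree on samples: {sorted(missing)}"
            )
        cpm_mat = cpm(matrix)
        kept = filter_expressed(
            cpm_mat, ExpressionFilterConfig(config.min_cpm, config.min_samples)
        )
        summary["n_genes_total"] = int(matrix.counts.shape[0])
        summary["n_genes_expressed"] = len(kept)
        filtered = matrix.subset_genes(kept)

        # 3. differential expression ------------------------------------------
        de_res = _stage("de")(
            lambda: ExactTestDE(
                filtered,
                risk.loc[filtered.sample_ids].to_numpy(),
                baseline="low",
                config=DEConfig(config.de_alpha, config.de_min_abs_logfc),
            ).fit()
        )()
        de_res.to_tsv(outdir / "differential_expression.tsv")
        summary["de"] = {
            "n_up": de_res.n_up,
            "n_down": de_res.n_down,
            "dispersion": de_res.dispersion,
        }

        # 4. heatmap-view sample clustering on the DE genes -------------------
        if de_res.de_genes and len(de_res.de_genes) >= 1:
            sub = filtered.subset_genes(de_res.de_genes)
            try:
                expr_view = log_fpkm(sub)
            except ValueError:
                logger.warning("no gene lengths available; using log10(CPM + 1)")
                expr_view = log_cpm10(cpm(matrix).loc[de_res.de_genes])
            tree = cluster_samples(expr_view)
            (outdir / "sample_dendrogram.nwk").write_text(tree.to_newick() + "\n")
            two = tree.cut(2)
            agree = _partition_agreement(two, risk)
            summary["de_cluster_vs_risk_agreement"] = agree

        # 5. co-expression network --------------------------------------------
        log_expr = log_cpm10(cpm_mat.loc[kept])
        net = _stage("network")(
            lambda: CoexpressionNetwork(
                log_expr,
                NetworkConfig(
                    beta=config.beta,
                    n_top_genes=config.n_top_genes,
                    min_module_size=config.min_module_size,
                    trait_p_threshold=config.trait_p_threshold,
                ),
            ).fit()
        )()
        net.partition.labels.to_csv(outdir / "modules.tsv", sep="\t", index_label="gene")
        net.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        mt = net.trait_correlation(scores)
        mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        sig_modules = list(mt.loc[mt["significant"], "module"])
        summary["network"] = {
            "n_modules": net.n_modules,
            "significant_modules": sig_modules,
        }

        # 6. enrichment --------------------------------------------------------
        if config.annotation_tsv:
            annot = enrichment.read_annotation_tsv(config.annotation_tsv)
            background = list(kept)
            targets = {"de_genes": de_res.de_genes}
            for m in sig_modules:
                targets[f"module_{m}"] = net.partition.genes(m)
            if config.mapping_tsv:
                mapping = enrichment.read_mapping_tsv(config.mapping_tsv)
                background, _ = enrichment.map_orthologues(background, mapping)
                targets = {
                    k: enrichment.map_orthologues(v, mapping)[0] for k, v in targets.items()
                }
            enr_summary = {}
            for name, target in targets.items():
                if not target:
                    continue
                table = _stage(f"enrich:{name}")(enrichment.enrich)(
                    set(target) & set(background), background, annot,
                    alpha=config.enrich_alpha,
                )
                table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
                enr_summary[name] = int(table["significant"].sum()) if len(table) else 0
            summary["enrichment_significant_terms"] = enr_summary

        # 7. validation --------------------------------------------------------
        val = {}
        if config.ki67_fields_csv:
            fields = validation.read_field_counts_csv(config.ki67_fields_csv)
            idx = validation.sample_indices(fields, mode="ki67").set_index("sample")
            groups = [
                idx.loc[risk.index[risk == g], "ki67_index"].to_numpy()
                for g in ("high", "low")
            ]
            res = validation.mann_whitney(groups[0], groups[1])
            val["ki67"] = {"U": res.U, "p": res.p, "method": res.method}
            idx.to_csv(outdir / "ki67_indices.tsv", sep="\t")
        if config.caf_fields_csv:
            fields = validation.read_field_counts_csv(config.caf_fields_csv)
            idx = validation.sample_indices(fields, mode="caf").set_index("sample")
            groups = [
                idx.loc[risk.index[risk == g], "caf_score"].to_numpy()
                for g in ("high", "low")
            ]
            res = validation.mann_whitney(groups[0], groups[1])
            val["caf"] = {"U": res.U, "p": res.p, "method": res.method}
            idx.to_csv(outdir / "caf_scores.tsv", sep="\t")
        if val:
            summary["validation"] = val

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonify)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _partition_agreement(clusters: pd.Series, risk: pd.Series) -> float:
    """Best-label-matching agreement between a 2-cut and the risk dichotomy."""
    risk = risk.loc[clusters.index]
    a = (clusters == clusters.iloc[0]).to_numpy()
    b = (risk == "high").to_numpy()
    agree = max((a == b).mean(), (a != b).mean())
    return float(agree)


def demo_table1(clinical_csv=None) -> tuple[pd.DataFrame, clinical.CohortSummary]:
    """Score a cohort CSV shaped like the bundled 15-dog example.

    With no argument, uses the packaged example cohort; returns the
    per-sample score table (sub-scores, total, risk) and the cohort summary.
    """
    if clinical_csv is None:
        records = clinical.load_example_cohort()
    else:
        records = clinical.read_clinical_csv(clinical_csv)
    return clinical.score_cohort(records)
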