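"""End-to-end orchestration: counts in, every stage's table out.

Stage order mirrors the analysis: completeness filter and normalisation,
PCA group check, DE/PIF table, gene-set skew, extreme-PIF target
selection, RIF scoring, and panel clustering. Each stage's output is
written as plain text under the output directory and a manifest records
parameters and per-stage row counts so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cluster as pcl
from . import de as pde
from . import io as pio
from . import mito as pmito
from . import normalize as pnorm
from . import rif as prif
from .matrices import ValidationError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are kept on disk."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts: str
    groups: str
    out_dir: str
    regulator_set: str | None = None
    mito_set: str | None = None
    pseudocount: float = 1.0
    extreme_fraction: float = 0.05
    panel_k: int = 20
    z_threshold: float = 1.96
    distance: str = "pearson"
    linkage: str = "average"
    rpm_before_filter: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("counts", "groups", "out_dir"):
            if key not in raw:
                raise ValidationError(f"config missing required key {key!r}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")
        if not 0 < self.extreme_fraction < 1:
            raise ValidationError("extreme_fraction must be in (0, 1)")
        if self.panel_k <= 0:
            raise ValidationError("panel_k must be positive")
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")
        if self.distance not in pcl.DISTANCES:
            raise ValidationError(f"distance must be one of {pcl.DISTANCES}")
        if self.linkage not in pcl.LINKAGES:
            raise ValidationError(f"linkage must be one of {pcl.LINKAGES}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing intermediates; returns the result bundle.

    A stage failure raises with the stage name; earlier outputs are kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "parameters": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        rec = stage("read")
        cm = pio.read_counts(config.counts, config.groups)
        rec["n_genes"] = len(cm.gene_ids)
        rec["n_samples"] = len(cm.sample_ids)

        rec = stage("normalize")
        em = pnorm.normalize_counts(
            cm,
            pseudocount=config.pseudocount,
            rpm_before_filter=config.rpm_before_filter,
        )
        pio.write_expression(em, out / "normalized.tsv")
        rec["n_complete_genes"] = len(em.gene_ids)
        rec["provenance"] = em.provenance
        bundle["expression"] = em

        rec = stage("pca_check")
        pca = pnorm.pca_group_check(em)
        pio.write_table(pca.coordinates.set_index("sample"), out / "pca.tsv")
        rec["n_misclassified"] = pca.n_misclassified
        rec["separated"] = pca.separated
        bundle["pca"] = pca

        rec = stage("de")
        det = pde.compute_de(em)
        pio.write_table(det, out / "de_table.tsv")
        rec["n_genes"] = len(det)
        bundle["de_table"] = det

        if config.mito_set:
            rec = stage("mito_skew")
            mito_ids = pio.read_gene_set(config.mito_set)
            skew = pmito.skew_analysis(det, mito_ids)
            pio.write_table(skew.to_frame(), out / "mito_skew.tsv", index=False)
            rec.update(n_up=skew.n_up, n_down=skew.n_down, p_value=skew.p_value)
            bundle["mito_skew"] = skew

        rec = stage("extreme_pif")
        up, down = pde.select_extreme_pif(det, config.extreme_fraction)
        pio.write_gene_set(up, out / "targets_up.txt")
        pio.write_gene_set(down, out / "targets_down.txt")
        rec["n_up"] = len(up)
        rec["n_down"] = len(down)
        bundle["targets"] = (up, down)

        if config.regulator_set:
            rec = stage("rif")
            reg_ids = pio.read_gene_set(config.regulator_set)
            regulators = sorted(reg_ids & set(em.gene_ids))
            dropped = len(reg_ids) - len(regulators)
            if dropped:
                logger.warning(
                    "%d regulators absent from the filtered matrix; skipped",
                    dropped,
                )
            rec["n_regulators_dropped"] = dropped
            rift = prif.rif_analysis(
                em, det, regulators, up + down, threshold=config.z_threshold
            )
            pio.write_table(rift, out / "rif_table.tsv")
            rec["n_regulators"] = len(rift)
            rec["n_outliers"] = int(rift["outlier"].sum())
            bundle["rif_table"] = rift

        rec = stage("panel_clustering")
        panel = pde.select_panel(det, config.panel_k)
        pio.write_gene_set(panel, out / "panel.txt")
        normed = pcl.row_normalize(em.values.loc[panel])
        report = pcl.cluster_samples(
            normed, em.groups, distance=config.distance, linkage_method=config.linkage
        )
        (out / "cluster_report.json").write_text(report.to_json())
        (out / "dendrogram.nwk").write_text(report.linkage_tree + "\n")
        rec["purity"] = report.purity
        rec["dispersion"] = report.dispersion
        bundle["cluster"] = report
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(failed, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle
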