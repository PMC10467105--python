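"""End-to-end pipeline orchestration with a YAML config and a run manifest.

The run executes signature construction, then the two parallel analyses
(connectivity and regulon enrichment), then validation when annotations are
supplied.  No stage mutates its inputs; everything is written under the
configured output directory, and a JSON manifest records versions, seeds,
input digests and row counts.  Reruns of the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import sigconn
from sigconn import diff_expr, io, master_regulator, validation
from sigconn.connectivity import connect_all
from sigconn.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    counts: str
    meta: str
    output_dir: str
    reference_matrix: str | None = None
    reference_meta: str | None = None
    pcl_gmt: str | None = None
    regulons: str | None = None
    tf_disease: str | None = None
    annotations: str | None = None  # TSV: query id -> true PCL
    perturbagens: list[str] = field(default_factory=list)  # empty -> all treated
    alpha: float = 0.05
    fdr: float = 0.05
    min_tfs: int = 2
    q: float = 67.0
    n_perms: int = 100
    seed: int = 0
    mra_direction: str = "both"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("counts", "meta", "output_dir") if k not in raw]
        if missing:
            raise ConfigError(f"config missing required keys: {missing}")
        return cls(**raw)

    def validate(self) -> None:
        path_fields = [
            "counts", "meta", "reference_matrix", "reference_meta",
            "pcl_gmt", "regulons", "tf_disease", "annotations",
        ]
        for name in path_fields:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if (self.reference_matrix is None) != (self.reference_meta is None):
            raise ConfigError("reference_matrix and reference_meta must be given together")
        if self.regulons is not None and self.tf_disease is None:
            raise ConfigError("mra requested (regulons given) but tf_disease path missing")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index=False, index_label=None) -> dict:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FORMAT)
    return {"path": path.name, "rows": int(df.shape[0]), "sha256": _sha256(path)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    manifest: dict = {
        "sigconn_version": sigconn.__version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for name in ("counts", "meta", "reference_matrix", "reference_meta",
                 "pcl_gmt", "regulons", "tf_disease", "annotations"):
        value = getattr(config, name)
        if value is not None:
            manifest["inputs"][name] = {"path": str(value), "sha256": _sha256(value)}

    def stage(name):
        logger.info("stage %s: start", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        cm = io.load_count_matrix(config.counts, config.meta)
        controls = cm.control_samples()
        perturbagens = config.perturbagens or sorted(
            set(cm.sample_meta.loc[cm.samples]
                .loc[lambda m: ~m["is_control"].astype(bool), "perturbagen"])
        )

        stage("signature")
        signatures, tables = [], {}
        for pert in perturbagens:
            treated = cm.samples_for(pert)
            sig, table = diff_expr.build_signature(
                cm, treated, controls, alpha=config.alpha, query_id=pert
            )
            signatures.append(sig)
            tables[pert] = table
            tsv, js = io.write_signature(sig, table, out_dir / f"signature_{pert}.tsv")
            manifest["outputs"][f"signature_{pert}"] = {
                "path": tsv.name, "rows": len(sig), "sha256": _sha256(tsv),
            }
            manifest["outputs"][f"signature_{pert}_json"] = {
                "path": js.name, "rows": len(sig), "sha256": _sha256(js),
            }

        table = None
        if config.reference_matrix is not None:
            stage("connect")
            db = io.load_reference_db(
                config.reference_matrix, config.reference_meta, config.pcl_gmt
            )
            table, pcl_scores, sparsity = connect_all(signatures, db, q=config.q)
            tau_wide = table.scores.pivot(index="query", columns="reference", values="tau")
            manifest["outputs"]["tau_matrix"] = _write(
                tau_wide, out_dir / "tau_matrix.tsv", index=True, index_label="query"
            )
            manifest["outputs"]["pcl_scores"] = _write(pcl_scores, out_dir / "pcl_scores.tsv")
            manifest["outputs"]["sparsity"] = _write(sparsity, out_dir / "sparsity.tsv")

        if config.regulons is not None:
            stage("mra")
            regulons = io.load_regulons(config.regulons)
            tf_disease = io.load_tf_disease_map(config.tf_disease)
            enr_frames, disease_frames = [], []
            for pert in perturbagens:
                treated = cm.samples_for(pert)
                z = master_regulator.gene_zscores(cm, treated, controls)
                null = master_regulator.permutation_null(
                    cm, treated, controls, n_perms=config.n_perms, seed=config.seed
                )
                enr = master_regulator.regulon_enrichment(z, regulons, null)
                enr.insert(0, "perturbagen", pert)
                enr_frames.append(enr)
                dis = master_regulator.map_to_diseases(
                    enr, tf_disease, fdr_threshold=config.fdr,
                    min_tfs=config.min_tfs, direction=config.mra_direction,
                )
                dis.insert(0, "perturbagen", pert)
                disease_frames.append(dis)
            manifest["outputs"]["regulon_enrichment"] = _write(
                pd.concat(enr_frames, ignore_index=True),
                out_dir / "regulon_enrichment.tsv",
            )
            manifest["outputs"]["disease_associations"] = _write(
                pd.concat(disease_frames, ignore_index=True),
                out_dir / "disease_associations.tsv",
            )

        if config.annotations is not None and table is not None:
            stage("validate")
            ann_df = pd.read_csv(config.annotations, sep="\t", comment="#", dtype=str)
            annotations = dict(zip(ann_df.iloc[:, 0], ann_df.iloc[:, 1]))
            manifest["outputs"]["within_pcl"] = _write(
                validation.within_pcl_test(table, annotations, db),
                out_dir / "within_pcl.tsv",
            )
            manifest["outputs"]["rank_percentiles"] = _write(
                validation.rank_percentiles(table, db, annotations, group_by="cell_line"),
                out_dir / "rank_percentiles_by_cell_line.tsv",
            )
    except (DataError, ConfigError) as e:
        stage_name = manifest["stages"][-1] if manifest["stages"] else "init"
        raise type(e)(f"stage {stage_name!r} failed: {e}") from e

    manifest["elapsed_s"] = round(time.monotonic() - t0, 3)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        payload = {k: v for k, v in manifest.items() if k != "elapsed_s"}
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished in %.1fs", manifest["elapsed_s"])
    return manifest
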