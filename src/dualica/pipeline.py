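"""End-to-end pipeline orchestration with file artifacts.

Thin layer over :class:`dualica.DualICA`: reads the input matrix, runs the
estimator, and writes every intermediate as a labeled text file plus a
manifest recording version, seed and configuration hash, so a run is fully
reproducible and inspectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import read_lfc_matrix, write_lfc_matrix
from .enrichment import enrich_all, enrichment_to_frame, read_gmt
from .estimator import DualICA
from .exceptions import ConfigError
from .extraction import SignedCluster
from .modules import modules_to_frame
from .plotting import plot_association_heatmap, plot_module_heatmap, plot_scree

__all__ = ["RunConfig", "run_pipeline", "clusters_to_frame", "write_clusters_gmt"]

logger = logging.getLogger("dualica")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_path: str
    output_dir: str
    delimiter: str = "\t"
    clip_bound: float = 6.0
    clip_first: bool = False
    scree_grid: list[int] | None = None
    sensitivity: float = 1.0
    alpha_extract: float = 0.05
    alpha_assoc: float = 0.05
    z_min: float = 2.0
    seed: int = 0
    n_condition_ics: int | None = None  # fixed k overrides the scree
    n_gene_ics: int | None = None  # fixed l overrides the scree
    gmt_path: str | None = None
    min_set_size: int = 10
    max_iter: int = 500

    def __post_init__(self) -> None:
        for name in ("alpha_extract", "alpha_assoc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.clip_bound <= 0:
            raise ConfigError(
                f"clip_bound must be positive, got {self.clip_bound}"
            )
        if self.z_min < 0:
            raise ConfigError(f"z_min must be >= 0, got {self.z_min}")
        if self.sensitivity <= 0:
            raise ConfigError(
                f"sensitivity must be positive, got {self.sensitivity}"
            )
        for name in ("n_condition_ics", "n_gene_ics"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def clusters_to_frame(clusters: list[SignedCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for member, coef, orphan in zip(
            c.member_ids, c.member_coefficients, c.orphan_flags
        ):
            rows.append(
                {
                    "axis": c.axis,
                    "ic_index": c.source_ic,
                    "sign": c.sign,
                    "cluster": c.label,
                    "member_id": member,
                    "coefficient": coef,
                    "orphan_flag": orphan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "axis", "ic_index", "sign", "cluster",
            "member_id", "coefficient", "orphan_flag",
        ],
    )


def write_clusters_gmt(clusters: list[SignedCluster], path) -> None:
    """Export gene clusters as a GMT file for external enrichment tools."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in clusters:
            if c.axis != "gene" or not len(c):
                continue
            fh.write(
                "\t".join([c.label, f"dualica cluster {c.label}"] + c.member_ids)
                + "\n"
            )


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts.

    Returns a dict of artifact paths plus the fitted estimator under
    ``"estimator"``. Any stage failure is re-raised annotated with the
    stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict = {"estimator": None}
    stage = "setup"
    try:
        stage = "read input"
        _stage(stage)
        M = read_lfc_matrix(config.input_path, delimiter=config.delimiter)

        stage = "fit"
        _stage(stage)
        est = DualICA(
            n_condition_ics=(
                "auto" if config.n_condition_ics is None else config.n_condition_ics
            ),
            n_gene_ics="auto" if config.n_gene_ics is None else config.n_gene_ics,
            scree_grid=config.scree_grid,
            clip_bound=config.clip_bound,
            clip_first=config.clip_first,
            alpha_extract=config.alpha_extract,
            alpha_assoc=config.alpha_assoc,
            z_min=config.z_min,
            sensitivity=config.sensitivity,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
        est.fit(M)
        artifacts["estimator"] = est

        stage = "write artifacts"
        _stage(stage)
        sep = config.delimiter
        write_lfc_matrix(est.preprocessed_, out / "preprocessed.tsv", sep)
        artifacts["preprocessed"] = out / "preprocessed.tsv"

        for axis, scree, chosen in (
            ("condition", est.scree_condition_, est.n_condition_ics_),
            ("gene", est.scree_gene_, est.n_gene_ics_),
        ):
            if scree is None:
                continue
            path = out / f"scree_{axis}.tsv"
            scree.to_frame(chosen).to_csv(path, sep=sep, index=False)
            plot_scree(scree, chosen, out / f"scree_{axis}.png")
            artifacts[f"scree_{axis}"] = path

        cd, gd = est.condition_decomposition_, est.gene_decomposition_
        ics_k = [f"IC{i}" for i in range(cd.n_components)]
        ics_l = [f"IC{i}" for i in range(gd.n_components)]
        pd.DataFrame(cd.signal, index=cd.row_ids, columns=ics_k).to_csv(
            out / "G_signal.tsv", sep=sep
        )
        pd.DataFrame(cd.mixing, index=ics_k, columns=cd.col_ids).to_csv(
            out / "A_mixing.tsv", sep=sep
        )
        pd.DataFrame(gd.signal, index=gd.row_ids, columns=ics_l).to_csv(
            out / "C_signal.tsv", sep=sep
        )
        pd.DataFrame(gd.mixing, index=ics_l, columns=gd.col_ids).to_csv(
            out / "B_mixing.tsv", sep=sep
        )

        clusters = est.gene_clusters_ + est.condition_clusters_
        clusters_to_frame(clusters).to_csv(
            out / "clusters.tsv", sep=sep, index=False
        )
        write_clusters_gmt(est.gene_clusters_, out / "gene_clusters.gmt")
        artifacts["clusters"] = out / "clusters.tsv"

        est.association_.to_frame().to_csv(
            out / "associations.tsv", sep=sep, index=False
        )
        plot_association_heatmap(est.association_, out / "associations.png")
        artifacts["associations"] = out / "associations.tsv"

        modules_to_frame(est.modules_).to_csv(
            out / "modules.tsv", sep=sep, index=False
        )
        with open(out / "modules.json", "w", encoding="utf-8") as fh:
            json.dump(
                [dataclasses.asdict(m) for m in est.modules_], fh, indent=2
            )
        if est.modules_:
            plot_module_heatmap(
                est.raw_, est.modules_, out / "modules_heatmap.png"
            )
        artifacts["modules"] = out / "modules.tsv"

        if config.gmt_path:
            stage = "enrichment"
            _stage(stage)
            collection = read_gmt(config.gmt_path, universe=M.gene_ids)
            records = enrich_all(
                est.gene_clusters_, collection,
                min_set_size=config.min_set_size, alpha=config.alpha_assoc,
            )
            enrichment_to_frame(records).to_csv(
                out / "enrichment.tsv", sep=sep, index=False
            )
            artifacts["enrichment"] = out / "enrichment.tsv"

        stage = "manifest"
        cfg = config.to_dict()
        manifest = {
            "dualica_version": __version__,
            "seed": config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "n_condition_ics": est.n_condition_ics_,
            "n_gene_ics": est.n_gene_ics_,
            "n_gene_clusters": len(est.gene_clusters_),
            "n_condition_clusters": len(est.condition_clusters_),
            "n_significant_pairs": len(est.significant_pairs_),
            "n_modules": len(est.modules_),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        artifacts["manifest"] = out / "manifest.json"
        return artifacts
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise type(exc)(f"[stage: {stage}] {exc}").with_traceback(
            exc.__traceback__
        ) from None
    finally:
        logger.removeHandler(handler)
        handler.close()
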