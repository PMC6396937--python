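"""End-to-end orchestration: load -> transform -> decompose -> ternarize
-> mine -> filter -> featurize -> select/stratify.

Every stage writes its artifact into a run directory and the manifest
records stage outputs with SHA-256 checksums, so a rerun with the same
config and seed is byte-reproducible and verifiable.
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
from .decomposition import (
    RANK_METHODS,
    component_thresholds,
    compute_svd,
    estimate_robust_rank,
    projection_matrix,
    ternary_map,
)
from .features import feature_matrix, select_features, subnetwork_eigensystem
from .matrix import (
    ExpressionMatrix,
    Transform,
    filter_genes_by_expression_ratio,
    load_labels,
    load_matrix,
    log_tpm_transform,
    save_matrix,
)
from .mining import build_subnetwork, enumerate_closed_rules, filter_subnetworks

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("coac")


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults.

    The constants mirror the method's published operating points: the
    F-threshold p-value cutoff alpha in [0.01, 0.05] (default 0.05), the
    F-score feature-selection threshold 2.4, the expressed-cell ratio
    gene filter 0.03, top/bottom stratification size 32, and the 10 uM
    IC50 resistance cutoff.
    """

    # input
    input_path: str | None = None
    orientation: str = "cells_by_genes"
    labels_path: str | None = None
    # transform
    apply_log: bool = True
    rescale_tpm: bool = False
    gene_min_expression_ratio: float = 0.03
    # decomposition
    k: int = 30
    alpha: float = 0.05
    strict_alpha_bounds: bool = True
    center: bool = False
    rank_method: str = "permutation"
    n_perm: int = 10
    seed: int = 0
    energy_fraction: float = 0.9
    # mining
    min_genes: int = 2
    min_components: int = 1
    edge_threshold: float = 0.5
    min_avg_corr: float = 0.5
    min_avg_comp_ratio: float = 0.5
    top_fraction: float | None = None
    # features
    feature_v: int | str = "auto"
    f_score_threshold: float = 2.4
    f_score_mode: str = "anova"
    stratify_k: int = 32
    ic50_cutoff: float = 10.0

    def validate(self) -> None:
        if self.strict_alpha_bounds and not 0.01 <= self.alpha <= 0.05:
            raise ValueError(
                f"alpha={self.alpha} outside [0.01, 0.05] under strict bounds"
            )
        if self.rank_method not in RANK_METHODS:
            raise ValueError(f"rank_method must be one of {RANK_METHODS}")
        if not 0 <= self.gene_min_expression_ratio <= 1:
            raise ValueError("gene_min_expression_ratio must be in [0, 1]")
        if self.top_fraction is not None and not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_tree(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    matrix: ExpressionMatrix | None = None,
    labels: dict[str, str] | None = None,
) -> dict:
    """Execute all stages, write artifacts under ``out_dir``, return the
    manifest (also written as ``manifest.json``).

    ``matrix`` may be passed directly (e.g. straight from the synthetic
    generator) instead of ``config.input_path``.  Any stage failure aborts
    with the stage name; artifacts of completed stages remain on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "load"
    try:
        if matrix is None:
            if config.input_path is None:
                raise ValueError("no input: set config.input_path or pass matrix=")
            matrix = load_matrix(config.input_path, orientation=config.orientation)
        if labels is None and config.labels_path:
            labels = load_labels(config.labels_path)
        d_in = out / "input"
        save_matrix(matrix, d_in)
        manifest["stages"]["load"] = {"dir": "input", "files": _checksum_tree(d_in)}
        log.info("load: %d cells x %d genes", matrix.n_cells, matrix.n_genes)

        stage = "transform"
        if config.gene_min_expression_ratio > 0:
            matrix = filter_genes_by_expression_ratio(
                matrix, config.gene_min_expression_ratio
            )
        if config.apply_log and matrix.transform is Transform.RAW:
            matrix = log_tpm_transform(matrix, rescale_tpm=config.rescale_tpm)
        d_tr = out / "transformed"
        save_matrix(matrix, d_tr)
        manifest["stages"]["transform"] = {
            "dir": "transformed",
            "n_genes": matrix.n_genes,
            "files": _checksum_tree(d_tr),
        }

        stage = "decompose"
        k = min(config.k, min(matrix.values.shape))
        decomp = compute_svd(matrix, k=k, center=config.center, seed=config.seed)
        decomp.rank_r = estimate_robust_rank(
            decomp,
            matrix,
            method=config.rank_method,
            n_perm=config.n_perm,
            seed=config.seed,
            energy_fraction=config.energy_fraction,
        )
        d_dec = out / "decomposition"
        d_dec.mkdir(exist_ok=True)
        np.savetxt(d_dec / "U.tsv", decomp.U, fmt="%.12g", delimiter="\t")
        np.savetxt(d_dec / "sigma.tsv", decomp.sigma, fmt="%.12g")
        np.savetxt(d_dec / "V.tsv", decomp.V, fmt="%.12g", delimiter="\t")
        (d_dec / "rank.json").write_text(
            json.dumps({"k": k, "rank_r": decomp.rank_r}) + "\n"
        )
        manifest["stages"]["decompose"] = {
            "dir": "decomposition",
            "rank_r": decomp.rank_r,
            "files": _checksum_tree(d_dec),
        }
        log.info("decompose: k=%d rank_r=%d", k, decomp.rank_r)

        stage = "ternarize"
        proj = projection_matrix(decomp, matrix)
        thr = component_thresholds(
            proj, alpha=config.alpha, strict_alpha_bounds=config.strict_alpha_bounds
        )
        ternary = ternary_map(proj, thr)
        d_ter = out / "ternary"
        d_ter.mkdir(exist_ok=True)
        import scipy.io
        import scipy.sparse as sp

        scipy.io.mmwrite(d_ter / "ternary.mtx", sp.coo_matrix(ternary.M))
        manifest["stages"]["ternarize"] = {
            "dir": "ternary",
            "nonzero": int(abs(ternary.M).sum()),
            "files": _checksum_tree(d_ter),
        }

        stage = "mine"
        rules = enumerate_closed_rules(
            ternary, min_genes=config.min_genes, min_components=config.min_components
        )
        d_mine = out / "rules"
        d_mine.mkdir(exist_ok=True)
        with open(d_mine / "rules.jsonl", "w") as fh:
            for r in rules:
                fh.write(
                    json.dumps(
                        {"genes": list(r.genes), "components": list(r.components)}
                    )
                    + "\n"
                )
        manifest["stages"]["mine"] = {
            "dir": "rules",
            "n_rules": len(rules),
            "files": _checksum_tree(d_mine),
        }
        log.info("mine: %d closed rules", len(rules))

        stage = "filter"
        subs = [
            build_subnetwork(r, decomp, matrix, edge_threshold=config.edge_threshold)
            for r in rules
        ]
        subs = [s for s in subs if len(s.giant_genes) >= config.min_genes]
        kept = filter_subnetworks(
            subs,
            min_avg_corr=config.min_avg_corr,
            min_avg_comp_ratio=config.min_avg_comp_ratio,
            top_fraction=config.top_fraction,
        )
        d_sub = out / "subnetworks"
        d_sub.mkdir(exist_ok=True)
        with open(d_sub / "subnetworks.jsonl", "w") as fh:
            for i, s in enumerate(kept):
                fh.write(
                    json.dumps(
                        {
                            "id": f"subnetwork_{i}",
                            "genes": list(s.giant_genes),
                            "components": list(s.rule.components),
                            "avg_correlation": round(s.avg_correlation, 10),
                            "avg_component_ratio": round(s.avg_component_ratio, 10),
                        }
                    )
                    + "\n"
                )
        for i, s in enumerate(kept):
            with open(d_sub / f"subnetwork_{i}.edges.tsv", "w") as fh:
                for u, v, w in s.edges:
                    fh.write(f"{u}\t{v}\t{w:.10g}\n")
        manifest["stages"]["filter"] = {
            "dir": "subnetworks",
            "n_subnetworks": len(kept),
            "files": _checksum_tree(d_sub),
        }
        log.info("filter: %d of %d subnetworks kept", len(kept), len(subs))

        stage = "featurize"
        d_feat = out / "features"
        d_feat.mkdir(exist_ok=True)
        if kept:
            eigensystems = [
                subnetwork_eigensystem(
                    s, matrix, v=config.feature_v, name=f"subnetwork_{i}"
                )
                for i, s in enumerate(kept)
            ]
            fm = feature_matrix(matrix, eigensystems)
            fm.to_csv(d_feat / "features.tsv", sep="\t", float_format="%.10g")
            if labels:
                scores = select_features(
                    fm,
                    labels,
                    threshold=config.f_score_threshold,
                    mode=config.f_score_mode,
                )
                pd.DataFrame(
                    [(s.feature, s.f_score, s.kept) for s in scores],
                    columns=["feature", "f_score", "kept"],
                ).to_csv(
                    d_feat / "feature_scores.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )
        else:
            (d_feat / "features.tsv").write_text("")
        manifest["stages"]["featurize"] = {
            "dir": "features",
            "n_features": len(kept),
            "files": _checksum_tree(d_feat),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_json(out / "config.json")
    manifest["config_sha256"] = _sha256(out / "config.json")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
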