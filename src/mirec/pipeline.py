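"""End-to-end orchestration: cohort -> normalization -> screens -> models.

A run is driven by a single :class:`RunConfig` (loadable from YAML/JSON)
holding either input file paths or a simulation config, the screen and
selection parameters, and one global seed.  Stage seeds are fanned out
from the global seed by stable hashing of stage names, so any stage can be
reproduced in isolation and a rerun with the same config yields
byte-identical artifacts.  Every artifact is listed with its SHA-256
checksum in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import (
    DEFAULT_MODEL_TARGETS,
    SfsConfig,
    build_subtype_models,
    fit_linear_scorer,
    roc_curve_points,
)
from .cohort import (
    ContrastError,
    MirnaExpressionMatrix,
    annotation_levels,
    make_contrast,
    normalize_ct,
    read_annotations,
    read_ct_matrix,
    write_annotations,
    write_ct_matrix,
    write_expression_matrix,
)
from .screen import ScreenResult, direction_counts, fc_filter, run_screen
from .simulate import SyntheticCohortConfig, generate_cohort

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "render_top_table", "stage_seed"]

logger = logging.getLogger(__name__)

DEFAULT_SCREEN_TARGETS: tuple[tuple[str, str], ...] = tuple(
    [("histology", lvl) for lvl in annotation_levels("histology")]
    + [("molecular", lvl) for lvl in annotation_levels("molecular")]
    + [("ctnnb1", "mutated")]
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input."""


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: input source, parameters, output directory."""

    outdir: str
    seed: int = 0
    ct_path: str | None = None
    annotations_path: str | None = None
    simulate: SyntheticCohortConfig | None = None
    screen_targets: tuple[tuple[str, str], ...] = DEFAULT_SCREEN_TARGETS
    model_targets: tuple[tuple[str, str], ...] | None = None
    alpha: float = 0.05
    n_permutations: int = 1000
    fc_threshold: float = 0.5
    detection_limit: float = 38.0
    max_missing_frac: float = 0.2
    spike_in_prefix: str = "SPIKE_"
    sfs: SfsConfig = field(default_factory=SfsConfig)

    def __post_init__(self) -> None:
        have_paths = self.ct_path is not None or self.annotations_path is not None
        if have_paths and self.simulate is not None:
            raise ValueError("config must give either input paths or a simulation, not both")
        if not have_paths and self.simulate is None:
            raise ValueError("config must give input paths or a simulation")
        if have_paths and (self.ct_path is None or self.annotations_path is None):
            raise ValueError("both ct_path and annotations_path are required")
        object.__setattr__(
            self, "screen_targets", tuple((v, l) for v, l in self.screen_targets)
        )
        if self.model_targets is not None:
            object.__setattr__(
                self, "model_targets", tuple((v, l) for v, l in self.model_targets)
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None and not isinstance(
            d["simulate"], SyntheticCohortConfig
        ):
            d["simulate"] = SyntheticCohortConfig.from_dict(d["simulate"])
        if "sfs" in d and not isinstance(d["sfs"], SfsConfig):
            d["sfs"] = SfsConfig(**d["sfs"])
        for key in ("screen_targets", "model_targets"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(t) for t in d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def echo(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "ct_path": self.ct_path,
            "annotations_path": self.annotations_path,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "screen_targets": [list(t) for t in self.screen_targets],
            "model_targets": [list(t) for t in self.model_targets]
            if self.model_targets
            else None,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "fc_threshold": self.fc_threshold,
            "detection_limit": self.detection_limit,
            "max_missing_frac": self.max_missing_frac,
            "spike_in_prefix": self.spike_in_prefix,
            "sfs": self.sfs.__dict__.copy(),
        }
        return d


def render_top_table(screen: ScreenResult, fc_threshold: float | None = None) -> pd.DataFrame:
    """Filtered top table: increased block then decreased, by |log2 FC| desc.

    Only fold-change-filter survivors appear; fold changes are rounded to
    two decimals for display.
    """
    threshold = screen.fc_threshold if fc_threshold is None else fc_threshold
    kept = fc_filter(list(screen.records), threshold)
    rows = []
    for direction in ("increased", "decreased"):
        block = [r for r in kept if r.direction == direction]
        block.sort(key=lambda r: (-abs(np.log2(r.fold_change)), r.mirna_id))
        rows.extend(
            {
                "direction": r.direction,
                "mirna_id": r.mirna_id,
                "fold_change": round(r.fold_change, 2),
                "perm_p": r.perm_p,
            }
            for r in block
        )
    return pd.DataFrame(rows, columns=["direction", "mirna_id", "fold_change", "perm_p"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, detail: str):
    class _StageContext:
        def __enter__(self):
            logger.info("stage %s: %s", name, detail)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed on {detail}: {exc}") from exc
            return False

    return _StageContext()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def record(path: Path) -> Path:
        artifacts.append(path)
        return path

    (outdir / "run_config.json").write_text(
        json.dumps(config.echo(), indent=2, sort_keys=True) + "\n"
    )
    record(outdir / "run_config.json")

    # ------------------------------------------------------------------ cohort
    if config.simulate is not None:
        sim = replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        with _stage("simulate", f"seed={sim.seed}"):
            raw, ann, truth = generate_cohort(sim)
            write_ct_matrix(raw, record(outdir / "ct_matrix.tsv"))
            write_annotations(ann, record(outdir / "annotations.tsv"))
            pd.DataFrame([e.__dict__ for e in truth]).to_csv(
                record(outdir / "planted_effects.tsv"), sep="\t", index=False
            )
    else:
        with _stage("load", f"{config.ct_path}, {config.annotations_path}"):
            raw = read_ct_matrix(config.ct_path, config.spike_in_prefix)
            ann = read_annotations(config.annotations_path)

    # --------------------------------------------------------------- normalize
    with _stage("normalize", f"{len(raw.assay_ids)} assays x {len(raw.sample_ids)} samples"):
        expr = normalize_ct(raw, config.detection_limit, config.max_missing_frac)
        write_expression_matrix(expr, record(outdir / "expression.tsv"))

    # ------------------------------------------------------------------ screens
    screens: dict[tuple[str, str], ScreenResult] = {}
    summary_rows = []
    screen_dir = outdir / "screens"
    screen_dir.mkdir(exist_ok=True)
    for variable, level in config.screen_targets:
        tag = f"{variable}_{level}"
        with _stage("screen", f"{variable}={level}"):
            contrast = make_contrast(ann, variable, level)
            result = run_screen(
                expr,
                contrast,
                alpha=config.alpha,
                B=config.n_permutations,
                fc_threshold=config.fc_threshold,
                seed=stage_seed(config.seed, f"screen:{variable}={level}"),
            )
            screens[(variable, level)] = result
            result.write_tsv(record(screen_dir / f"screen_{tag}.tsv"))
            record(screen_dir / f"screen_{tag}.params.json")
            render_top_table(result).to_csv(
                record(screen_dir / f"top_table_{tag}.tsv"),
                sep="\t", index=False, float_format="%.10g",
            )
            n_up, n_down = direction_counts(result.significant())
            summary_rows.append(
                {
                    "contrast": result.contrast_name,
                    "n_tested": len(result.records),
                    "n_significant": n_up + n_down,
                    "n_increased": n_up,
                    "n_decreased": n_down,
                    "n_fc_filtered": len(fc_filter(list(result.records), config.fc_threshold)),
                }
            )
    pd.DataFrame(summary_rows).to_csv(
        record(outdir / "direction_counts.tsv"), sep="\t", index=False
    )

    # ------------------------------------------------------------------- models
    model_dir = outdir / "models"
    model_dir.mkdir(exist_ok=True)
    model_targets = (
        config.model_targets if config.model_targets is not None else DEFAULT_MODEL_TARGETS
    )
    sfs = replace(config.sfs, seed=stage_seed(config.seed, "models"))
    for variable, level in model_targets:
        tag = f"{variable}_{level}"
        with _stage("model", f"{variable}={level}"):
            candidates = _model_candidates(expr, screens.get((variable, level)), sfs)
            models = build_subtype_models(
                expr, ann, targets=[(variable, level)], config=sfs, candidates=candidates
            )
            if not models:
                raise ContrastError(f"no valid contrast for {variable}={level}")
            model = models[0]
            (model_dir / f"model_{tag}.json").write_text(
                json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n"
            )
            record(model_dir / f"model_{tag}.json")
            contrast = make_contrast(ann, variable, level)
            scorer = fit_linear_scorer(
                expr, contrast, model.selected_mirnas, sfs.regularization
            )
            ids = list(contrast.positive_ids) + list(contrast.negative_ids)
            scores = scorer.score(expr, ids)
            labels = [1] * contrast.n_positive + [0] * contrast.n_negative
            roc_curve_points(scores, labels).to_csv(
                record(model_dir / f"roc_{tag}.tsv"),
                sep="\t", index=False, float_format="%.10g",
            )

    # ----------------------------------------------------------------- manifest
    manifest = {
        "seed": config.seed,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _model_candidates(
    expr: MirnaExpressionMatrix, screen: ScreenResult | None, sfs: SfsConfig
) -> list[str]:
    """Screen-significant miRNAs, falling back to the full panel when few."""
    if screen is None:
        return list(expr.mirna_ids)
    sig = [r.mirna_id for r in screen.significant()]
    if len(sig) < 2 * sfs.max_features:
        return list(expr.mirna_ids)
    return sig
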