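"""End-to-end orchestration: configuration, staged runs, manifests.

A run is fully determined by a :class:`RunConfig` (seed included); the
single seed deterministically derives per-stage substreams so stages can
be rerun independently.  Stage order: ``simulate`` → ``activity`` →
{``plsda``, ``symreg``} → ``fe`` → ``analyze``; each stage writes its
outputs under the run directory and registers them in a manifest keyed by
a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import healing, io, plsda, symreg
from .activity import FEATURE_NAMES, daily_metrics, weekly_features
from .geometry import GeometrySpec
from .synthetic import (
    CohortConfig,
    simulate_cohort,
    simulate_feature_cohort,
)

logger = logging.getLogger("rehabmech")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "activity", "plsda", "symreg", "fe", "analyze")
_STAGE_DEPS = {
    "simulate": (),
    "activity": ("simulate",),
    "plsda": ("activity",),
    "symreg": (),
    "fe": ("simulate",),
    "analyze": ("fe",),
}


@dataclass
class RunConfig:
    """Validated run settings with defaults for every stage."""

    seed: int
    out_dir: str = "runs/default"
    n_days: int = 21
    gap_seconds: int = 6
    week_range: tuple[int, int] = (1, 3)
    n_components: int = 2
    k_folds: int = 4
    n_boot: int = 500
    gp_runs: int = 10
    gp_population: int = 300
    gp_generations: int = 60
    gp_max_fitness: float = 0.2
    gp_cohort_size: int = 60
    fe_voxel_size: float = 0.5
    fe_bone_grid: int = 10

    def cohort_config(self, seed: int) -> CohortConfig:
        return CohortConfig(seed=seed, n_days=self.n_days)

    def geometry_spec(self) -> GeometrySpec:
        return GeometrySpec(
            voxel_size=self.fe_voxel_size, bone_grid=self.fe_bone_grid
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_FIELD_TYPES = {
    "seed": int,
    "out_dir": str,
    "n_days": int,
    "gap_seconds": int,
    "week_range": (list, tuple),
    "n_components": int,
    "k_folds": int,
    "n_boot": int,
    "gp_runs": int,
    "gp_population": int,
    "gp_generations": int,
    "gp_max_fitness": (int, float),
    "gp_cohort_size": int,
    "fe_voxel_size": (int, float),
    "fe_bone_grid": int,
}
_POSITIVE = {
    "n_days", "gap_seconds", "n_components", "k_folds", "n_boot",
    "gp_runs", "gp_population", "gp_generations", "gp_cohort_size",
    "fe_voxel_size", "fe_bone_grid",
}


def validate_config(source: str | Path | dict) -> tuple[RunConfig | None,
                                                        list[str]]:
    """Schema-check a config mapping (or YAML/JSON file).

    Returns ``(config, errors)``; all problems are collected in one pass
    rather than failing fast.  Unknown keys produce warnings in the error
    list prefixed ``warning:``; a missing seed or type violation is an
    error and yields ``config=None``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
    else:
        data = dict(source)
    errors: list[str] = []
    clean: dict = {}
    for key, value in data.items():
        if key not in _FIELD_TYPES:
            errors.append(f"warning: unknown key {key!r} ignored")
            continue
        expected = _FIELD_TYPES[key]
        if not isinstance(value, expected) or isinstance(value, bool):
            errors.append(
                f"{key}: expected {expected}, got {type(value).__name__}"
            )
            continue
        if key in _POSITIVE and not (value > 0):
            errors.append(f"{key}: must be positive, got {value!r}")
            continue
        if key == "k_folds" and value < 2:
            errors.append(f"k_folds: must be >= 2, got {value!r}")
            continue
        clean[key] = tuple(value) if key == "week_range" else value
    if "seed" not in clean:
        errors.append("seed: mandatory and must be an integer")
    fatal = [e for e in errors if not e.startswith("warning:")]
    if fatal:
        return None, errors
    return RunConfig(**clean), errors


def _stage_seed(config: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(
    config: RunConfig, stages: list[str] | None = None
) -> dict:
    """Execute the requested stages in dependency order.

    Returns (and writes) the run manifest.  Requesting a stage whose
    upstream outputs are absent raises a dependency error naming the
    missing artifact.
    """
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    ordered = [s for s in STAGES if s in requested]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text())
        if manifest_path.exists()
        else {"outputs": {}}
    )
    manifest.update(
        config_hash=config.config_hash(), seed=config.seed,
        version=_package_version(),
    )
    outputs: dict[str, list[str]] = manifest["outputs"]

    def require(stage: str, artifact: Path, produced_by: str) -> None:
        if not artifact.exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires {artifact} (run "
                f"{produced_by!r} first)"
            )

    state: dict = {}
    for stage in ordered:
        seed = _stage_seed(config, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        if stage == "simulate":
            bundle = simulate_cohort(config.cohort_config(seed))
            state["bundle"] = bundle
            files = []
            for s in bundle.subjects:
                p = out / f"telemetry_{s.subject_id}.csv"
                io.write_telemetry_csv(s.telemetry, p)
                files.append(str(p))
            table = bundle.outcome_table()
            table.to_csv(out / "outcomes.csv", index=False)
            files.append(str(out / "outcomes.csv"))
            logger.info(
                "simulate: %d subjects, %d designed unions",
                len(bundle.subjects), int(table["union"].sum()),
            )
            outputs["simulate"] = files
        elif stage == "activity":
            require(stage, out / "outcomes.csv", "simulate")
            rows = []
            for p in sorted(out.glob("telemetry_*.csv")):
                days = io.read_telemetry_csv(p)
                feats = [
                    daily_metrics(d, gap_seconds=config.gap_seconds)
                    for d in days
                ]
                wk = weekly_features(feats, weeks=config.week_range)
                row = {"subject_id": days[0].subject_id}
                row.update(
                    {n: getattr(wk, n) for n in FEATURE_NAMES}
                )
                rows.append(row)
            feat = pd.DataFrame(rows)
            feat.to_csv(out / "features.csv", index=False)
            logger.info("activity: %d subjects featurized", len(feat))
            outputs["activity"] = [str(out / "features.csv")]
        elif stage == "plsda":
            require(stage, out / "features.csv", "activity")
            require(stage, out / "outcomes.csv", "simulate")
            feat = pd.read_csv(out / "features.csv")
            outc = pd.read_csv(out / "outcomes.csv")
            merged = feat.merge(
                outc[["subject_id", "union"]], on="subject_id"
            )
            X = merged[list(FEATURE_NAMES)].to_numpy()
            y = merged["union"].to_numpy()
            model = plsda.fit_plsda(
                X, y, n_components=config.n_components,
                feature_names=list(FEATURE_NAMES),
            )
            cis = plsda.bootstrap_loadings(
                X, y, n_boot=config.n_boot, seed=seed,
                n_components=config.n_components,
                feature_names=list(FEATURE_NAMES),
            )
            acc = plsda.cv_accuracy(
                X, y, k_folds=config.k_folds, seed=seed,
                n_components=config.n_components,
            )
            report = {
                "r_squared": model.r_squared,
                "pct_variance": model.pct_variance,
                "loadings": {
                    name: model.x_loadings[j].tolist()
                    for j, name in enumerate(model.feature_names)
                },
                "cv_accuracy": acc,
                "loading_ci": cis,
                "n_degenerate_resamples": cis.n_redrawn,
            }
            io.write_json(report, out / "plsda_report.json")
            logger.info("plsda: R^2=%.3f CV accuracy=%.3f",
                        model.r_squared, acc)
            outputs["plsda"] = [str(out / "plsda_report.json")]
        elif stage == "symreg":
            cohort = simulate_feature_cohort(
                n_subjects=config.gp_cohort_size, seed=seed
            )
            X = cohort[list(FEATURE_NAMES)].to_numpy()
            y = cohort["bone_volume"].to_numpy()
            gp_cfg = symreg.GPConfig(
                n_runs=config.gp_runs,
                population=config.gp_population,
                generations=config.gp_generations,
                seed=seed,
            )
            archive = symreg.evolve(X, y, gp_cfg)
            robust = symreg.robust_filter(archive.models, X, y, seed=seed)
            knee = symreg.select_knee_relative(
                robust, max_fitness=config.gp_max_fitness
            )
            logger.info(
                "symreg: %d archived models, %d at the knee",
                len(archive), len(knee),
            )
            presence = symreg.variable_presence(
                knee or archive.models,
                n_features=len(FEATURE_NAMES),
                feature_names=FEATURE_NAMES,
            )
            pd.DataFrame(
                sorted(presence.items()), columns=["feature", "presence"]
            ).to_csv(out / "variable_presence.csv", index=False)
            arch = [
                {
                    "expression": m.key,
                    "fitness": m.fitness,
                    "complexity": m.complexity,
                    "variables": sorted(
                        FEATURE_NAMES[v] for v in m.variables_used
                    ),
                    "run": m.run_index,
                }
                for m in sorted(
                    archive.models,
                    key=lambda m: (m.fitness, m.complexity, m.key),
                )
            ]
            io.write_json(
                {"models": arch, "n_knee": len(knee)},
                out / "symreg_archive.json",
            )
            if knee:
                ens = symreg.ModelEnsemble(knee[:24])
                d_idx = FEATURE_NAMES.index("distance")
                r_idx = FEATURE_NAMES.index("rest")
                gx = np.linspace(X[:, d_idx].min(), X[:, d_idx].max(), 21)
                gy = np.linspace(X[:, r_idx].min(), X[:, r_idx].max(), 11)
                surf = symreg.response_surface(
                    ens, d_idx, r_idx, gx, gy, X
                )
                rows = []
                for i, xv in enumerate(gx):
                    for j, yv in enumerate(gy):
                        rows.append(
                            {
                                "distance": xv,
                                "rest": yv,
                                "center": surf["center"][i, j],
                                "spread": surf["spread"][i, j],
                                "supported": bool(surf["supported"][i, j]),
                            }
                        )
                pd.DataFrame(rows).to_csv(
                    out / "response_surface.csv", index=False
                )
            outputs["symreg"] = [
                str(out / "variable_presence.csv"),
                str(out / "symreg_archive.json"),
                str(out / "response_surface.csv"),
            ]
        elif stage == "fe":
            if "bundle" not in state:
                require(stage, out / "outcomes.csv", "simulate")
                state["bundle"] = simulate_cohort(
                    config.cohort_config(_stage_seed(config, "simulate"))
                )
            records = healing.analyze_cohort(
                state["bundle"], spec=config.geometry_spec()
            )
            state["records"] = records
            rows = []
            for r in records:
                for wk in (2, 4):
                    for mask, s in r.strain[wk].items():
                        rows.append(
                            {
                                "subject_id": r.subject_id,
                                "week": wk,
                                "mask": mask,
                                "compressive_mean": s.compressive_mean,
                                "compressive_sd": s.compressive_sd,
                                "shear_mean": s.shear_mean,
                                "shear_sd": s.shear_sd,
                                "volume_mm3": s.volume,
                                "n_elements": s.n_elements,
                            }
                        )
            pd.DataFrame(rows).to_csv(
                out / "strain_summaries.csv", index=False
            )
            logger.info("fe: %d subjects solved", len(records))
            outputs["fe"] = [str(out / "strain_summaries.csv")]
        elif stage == "analyze":
            if "records" not in state:
                raise FileNotFoundError(
                    "stage 'analyze' requires in-memory FE records; run "
                    "'fe' in the same invocation"
                )
            report = healing.cohort_report(state["records"])
            report["subjects"].to_csv(
                out / "cohort_subjects.csv", index=False
            )
            io.write_json(
                {
                    k: v
                    for k, v in report.items()
                    if k not in ("subjects", "bridging_rates")
                },
                out / "cohort_report.json",
            )
            report["bridging_rates"].to_csv(
                out / "bridging_rates.csv", index=False
            )
            logger.info(
                "analyze: concordance %.2f, bridging rate %.2f",
                report["fold_change_concordance"],
                report["overall_bridging_rate"],
            )
            outputs["analyze"] = [
                str(out / "cohort_subjects.csv"),
                str(out / "cohort_report.json"),
                str(out / "bridging_rates.csv"),
            ]
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__
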