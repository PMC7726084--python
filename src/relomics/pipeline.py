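"""End-to-end study orchestration.

Two composite runs mirror the study design:

* :func:`run_phantom_study` — simulate the repeated-acquisition liver
  phantom, extract the feature panel per insert per acquisition, and
  screen features for CCC robustness;
* :func:`run_outcome_study` — take a lesion cohort table (real or
  simulated) and produce the univariate screen, the single-feature /
  dose-only / combined nested-CV models for both endpoints, the final
  model coefficients, KM stratification and calibration summaries.

A :class:`RunManifest` records config, seed and output hashes so runs
can be reproduced and compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortGenConfig, SyntheticCohort, generate_cohort
from .features import FEATURE_NAMES, extract_all
from .modeling import ModelingConfig, univariate_screen
from .outcome import LesionProgressionModel, LesionResponseModel
from .phantom import PhantomSeries, PhantomSpec, generate_phantom_series
from .robustness import RobustnessReport, long_format_table, robustness_screen

__all__ = [
    "RunManifest",
    "phantom_feature_table",
    "run_phantom_study",
    "run_outcome_study",
]


@dataclass
class RunManifest:
    """Reproducibility record for a pipeline run."""

    stage: str
    seed: int
    config: dict
    outputs: dict = field(default_factory=dict)   # path -> sha256
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def record_output(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()
    }


def phantom_feature_table(
    series: PhantomSeries,
    ng: int = 32,
    target_mm: float = 0.97,
    feature_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Extract features for every insert under every acquisition.

    Returns the long-format table
    ``(lesion_id, repeat_id, condition_id, feature, value)`` consumed by
    the robustness screen.
    """
    rows = []
    for (cond, rep), img in series.images.items():
        for insert_name, mask in series.masks.items():
            feats = extract_all(
                img, mask, ng=ng, target_mm=target_mm, feature_subset=feature_subset
            )
            rows.append(
                {"lesion_id": insert_name, "repeat_id": rep, "condition_id": cond,
                 **feats}
            )
    return long_format_table(pd.DataFrame(rows))


def run_phantom_study(
    spec: PhantomSpec | None = None,
    threshold: float = 0.85,
    ng: int = 32,
    target_mm: float = 0.97,
    mode: str = "pooled",
    feature_subset: list[str] | None = None,
) -> tuple[RobustnessReport, pd.DataFrame]:
    """Phantom simulation -> feature extraction -> CCC robustness screen."""
    spec = spec or PhantomSpec()
    series = generate_phantom_series(spec)
    table = phantom_feature_table(series, ng=ng, target_mm=target_mm,
                                  feature_subset=feature_subset)
    report = robustness_screen(table, threshold=threshold, mode=mode)
    return report, table


def _three_model_block(data: pd.DataFrame, endpoint: str, combined_features: list[str],
                       dose_col: str, config: ModelingConfig):
    """Fit the radiomics-only, dose-only and combined models for one
    endpoint and collect their nested-CV summaries."""
    if endpoint == "OR":
        cls = LesionResponseModel
    else:
        cls = LesionProgressionModel

    combined = cls(data, features=combined_features,
                   config=replace(config, endpoint=endpoint)).fit()
    top_radiomics = next(
        (f for f in combined.ranking.index if f != dose_col), combined_features[0]
    )
    single = cls(data, features=[top_radiomics],
                 config=replace(config, endpoint=endpoint)).fit()
    dose_only = cls(data, features=[dose_col],
                    config=replace(config, endpoint=endpoint)).fit()

    rows = []
    for label, res in (
        (f"radiomics ({top_radiomics})", single),
        ("dose", dose_only),
        (f"combined", combined),
    ):
        for g, r in res.cv_performance.summary.iterrows():
            rows.append(
                {"model": label, "subgroup": g, "mean": r["mean"],
                 "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"],
                 "n_folds": int(r["n_folds"])}
            )
    table = pd.DataFrame(rows)
    return {
        "performance": table,
        "combined": combined,
        "radiomics_only": single,
        "dose_only": dose_only,
        "top_radiomics_feature": top_radiomics,
    }


def run_outcome_study(
    data: pd.DataFrame | SyntheticCohort | None = None,
    features: list[str] | None = None,
    dose_col: str = "dose",
    config: ModelingConfig | None = None,
    cohort_config: CohortGenConfig | None = None,
    endpoints: tuple[str, ...] = ("OR", "progression"),
) -> dict:
    """Univariate screen plus the three-model nested-CV comparison for
    each requested endpoint.

    ``data`` may be a cohort DataFrame (columns: features + ``dose``,
    ``OR``, ``time``, ``event``, optional ``subgroup``) or a
    :class:`SyntheticCohort`; when omitted, a cohort is simulated from
    ``cohort_config`` (defaults to the study-like conditions).
    """
    if data is None:
        cohort = generate_cohort(cohort_config or CohortGenConfig())
        data = cohort.data
    elif isinstance(data, SyntheticCohort):
        data = data.data
    config = config or ModelingConfig()

    if features is None:
        reserved = {"lesion_id", "subgroup", "OR", "time", "event", "dose_Gy"}
        features = [
            c for c in data.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(data[c])
        ]
    if dose_col not in features:
        features = features + [dose_col]

    bundle: dict = {
        "univariate": univariate_screen(data, features),
        "features": features,
    }
    for ep in endpoints:
        block = _three_model_block(data, ep, features, dose_col, config)
        if ep == "progression":
            block["km"] = block["combined"].km_stratification()
        else:
            block["calibration"] = {
                "combined": block["combined"].calibration(),
                "dose": block["dose_only"].calibration(),
                "radiomics": block["radiomics_only"].calibration(),
            }
        bundle[ep] = block
    return bundle


def save_outcome_bundle(bundle: dict, outdir: str | Path, seed: int,
                        config: ModelingConfig) -> RunManifest:
    """Write the Table-3-style CSV reports and final-model JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("outcome_study", seed, _config_dict(config))
    uni_path = outdir / "univariate.csv"
    bundle["univariate"].to_csv(uni_path)
    manifest.record_output(uni_path)
    for ep in ("OR", "progression"):
        if ep not in bundle:
            continue
        block = bundle[ep]
        perf_path = outdir / f"cv_performance_{ep}.csv"
        block["performance"].to_csv(perf_path, index=False)
        manifest.record_output(perf_path)
        res = block["combined"]
        res.ranking.to_csv(outdir / f"ranking_{ep}.csv")
        res.order_curve.table.to_csv(outdir / f"order_curve_{ep}.csv")
        final = {
            "endpoint": ep,
            "features": res.selected_features,
            "coefficients": dict(zip(res.model.features, map(float, res.model.coef))),
            "intercept": float(res.model.intercept),
            "standardization": {
                "mean": dict(zip(res.model.features, map(float, res.model.mean))),
                "sd": dict(zip(res.model.features, map(float, res.model.sd))),
            },
        }
        fm_path = outdir / f"final_model_{ep}.json"
        fm_path.write_text(json.dumps(final, indent=2))
        for p in (outdir / f"ranking_{ep}.csv", outdir / f"order_curve_{ep}.csv", fm_path):
            manifest.record_output(p)
    manifest.save(outdir / "manifest.json")
    return manifest
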