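"""End-to-end orchestration: simulate -> extract -> benchmark -> CNN -> report.

`run_all` chains the stages on a phantom cohort, writes every
intermediate artifact (feature tables raw and harmonized, benchmark
report, CNN scores) beside a resolved copy of the configuration, and
is deterministic given the seeds in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from lipomics import cnn as cnn_mod
from lipomics.combat import harmonize
from lipomics.evaluate import DEFAULT_GRIDS, FAST_GRIDS, auc_mann_whitney, make_cv_plan, run_benchmark
from lipomics.features import ExtractionConfig, extract_cohort
from lipomics.phantom import PhantomSpec, generate_case, generate_cohort, study_spec, small_spec
from lipomics.preprocessing import crop_and_resize_slices, zscore_normalize

log = logging.getLogger("lipomics")

PRESETS = {"study": study_spec, "small": small_spec}

_KNOWN_KEYS = {
    "preset", "spec_overrides", "seed", "cv_k", "threshold", "fast_grids",
    "run_cnn", "cnn_epochs", "out_dir", "target_spacing", "interp",
}


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    preset: str = "small"
    spec_overrides: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    cv_k: int = 5
    threshold: float = 0.5
    fast_grids: bool = True
    run_cnn: bool = True
    cnn_epochs: int = 15
    out_dir: str = "lipomics_run"
    target_spacing: float = 1.0
    interp: str = "nearest"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]
        return d


def build_slice_dataset(spec: PhantomSpec, out_size: int = 224, max_slices_per_case: int = 8):
    """Z-scored 2D lesion crops for every case of a phantom spec.

    Returns ``(images, case_ids, labels)`` with one row per slice.  At
    most ``max_slices_per_case`` central lesion slices are kept per case
    (the peripheral slices show little lesion area).
    """
    imgs, cids, labs = [], [], []
    for i in range(spec.n_cases):
        v, _, label = generate_case(spec, i)
        crops, zidx = crop_and_resize_slices(v, out_size=out_size)
        if max_slices_per_case and len(crops) > max_slices_per_case:
            mid = len(crops) // 2
            half = max_slices_per_case // 2
            sel = slice(mid - half, mid - half + max_slices_per_case)
            crops = crops[sel]
        for c in crops:
            if c.std() == 0:
                continue
            imgs.append(zscore_normalize(c).astype(np.float32))
            cids.append(f"case_{i:04d}")
            labs.append(label)
    return np.stack(imgs), np.asarray(cids), np.asarray(labs, dtype=int)


def run_all(config: RunConfig) -> dict:
    """Run the full two-arm comparison on a phantom cohort."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.resolved(), indent=1))
    completed = []
    manifest_path = out / "MANIFEST.json"

    def _checkpoint(stage: str):
        completed.append(stage)
        manifest_path.write_text(json.dumps({"completed_stages": completed}, indent=1))

    try:
        spec = PRESETS[config.preset](seed=config.seed, **config.spec_overrides)
        cohort_dir = out / "cohort"
        log.info("simulating cohort (%d cases)", spec.n_cases)
        manifest = generate_cohort(spec, cohort_dir, overwrite=True)
        _checkpoint("simulate")

        log.info("extracting radiomic features")
        ecfg = ExtractionConfig(target_spacing=config.target_spacing, interp=config.interp)
        feats = extract_cohort(manifest, cohort_dir, ecfg)
        feats.to_csv(out / "features_raw.csv", index=False)
        (out / "features_raw.json").write_text(json.dumps(ecfg.to_dict(), indent=1))
        _checkpoint("extract")

        log.info("harmonizing (whole-table model, for inspection only)")
        corrected, model = harmonize(feats)
        corrected.to_csv(out / "features_combat.csv", index=False)
        model.to_json(out / "combat_model.json")
        _checkpoint("harmonize")

        log.info("benchmarking 4 classifiers x {raw, combat}")
        plan = make_cv_plan(feats, k=config.cv_k, seed=config.seed)
        grids = FAST_GRIDS if config.fast_grids else DEFAULT_GRIDS
        report = run_benchmark(
            feats, plan=plan, grids=grids, seed=config.seed, threshold=config.threshold
        )
        _checkpoint("benchmark")

        if config.run_cnn:
            log.info("training the CNN baseline")
            images, cids, labs = build_slice_dataset(spec)
            ccfg = cnn_mod.CNNConfig(max_epochs=config.cnn_epochs)
            scores = cnn_mod.train_cnn_cv(images, cids, labs, plan, config=ccfg, seed=config.seed)
            scores.to_csv(out / "cnn_scores.csv", index=False)
            cnn_auc = auc_mann_whitney(scores.score, scores.label)
            report["cnn"] = {"case_auc": cnn_auc, "n_slices": int(len(images))}
            _checkpoint("cnn")

        (out / "report.json").write_text(json.dumps(report, indent=1))
        _write_report_md(out / "report.md", report)
        _checkpoint("report")
        return report
    except Exception:
        manifest_path.write_text(
            json.dumps({"completed_stages": completed, "failed": True}, indent=1)
        )
        raise


def _write_report_md(path: Path, report: dict) -> None:
    lines = ["# Benchmark report", "", "| dataset | classifier | AUC | sensitivity | specificity |", "|---|---|---|---|---|"]
    for row in report["rows"]:
        lines.append(
            "| {dataset} | {classifier} | {auc_mean:.3f} ± {auc_sd:.3f} "
            "| {sensitivity_mean:.3f} ± {sensitivity_sd:.3f} "
            "| {specificity_mean:.3f} ± {specificity_sd:.3f} |".format(**row)
        )
    if "cnn" in report:
        lines += ["", f"CNN case-level AUC: {report['cnn']['case_auc']:.3f}"]
    lines += ["", "## Raw vs. ComBat comparisons", "", "| classifier | AUC raw | AUC combat | DeLong p | McNemar p |", "|---|---|---|---|---|"]
    for c in report["comparisons"]:
        lines.append(
            "| {classifier} | {auc_a:.3f} | {auc_b:.3f} | {p:.3g} | {mcnemar_p:.3g} |".format(**c)
        )
    path.write_text("\n".join(lines) + "\n")
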