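"""End-to-end pipeline: simulate -> preprocess -> train -> segment ->
extract -> select -> SMOTE -> classify -> evaluate.

All randomness flows from one global seed through per-stage derived
seeds; every default that fills a methodological gap (lambda, eta_min,
quantization bins, averaging modes, ...) is echoed into the run log so a
rerun reproduces the artifacts bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, evaluate, fit_with_grid, smote_balance
from .features import FeatureConfig, build_catalogue, extract_all
from .io import write_cohort_csv
from .network import SegmentationModelSpec
from .objective import LossConfig
from .phantom import PhantomConfig, generate_cohort, scaled_phantom_config
from .preprocess import SplitSpec, split_cohort, zscore
from .segmetrics import overlap_metrics
from .selection import SelectionConfig, select_biomarkers, standardize_features
from .train import TrainConfig, train, validation_dice

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    n_phantoms: int = 60
    image_size: int = 64
    class_probabilities: tuple | None = None
    phantom: PhantomConfig | None = None
    model: SegmentationModelSpec | None = None
    training: TrainConfig | None = None
    loss: LossConfig | None = None
    split: SplitSpec | None = None
    features: FeatureConfig | None = None
    selection: SelectionConfig | None = None
    classifier: ClassifierSpec | None = None
    seed: int = 0
    out_dir: str = "crferad_run"


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.default_rng([seed, stage]).integers(0, 2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also written to
    ``<out_dir>/summary.json`` along with per-stage CSV artifacts)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    phantom_cfg = config.phantom or scaled_phantom_config(
        config.image_size, seed=_stage_seed(seed, 1)
    )
    model_spec = config.model or SegmentationModelSpec(
        input_size=config.image_size, encoder_channels=(8, 16, 32),
        recurrent_units=32, seed=_stage_seed(seed, 2),
    )
    train_cfg = config.training or TrainConfig(
        max_epochs=20, seed=_stage_seed(seed, 3)
    )
    loss_cfg = config.loss or LossConfig(pixel_spacing=phantom_cfg.pixel_spacing)
    split_spec = config.split or SplitSpec(seed=_stage_seed(seed, 4))
    feat_cfg = config.features or FeatureConfig(pixel_spacing=phantom_cfg.pixel_spacing)
    sel_cfg = config.selection or SelectionConfig(
        count_grid=tuple(range(5, 51, 5)), seed=_stage_seed(seed, 5)
    )
    clf_spec = config.classifier or ClassifierSpec(
        grid={"n_estimators": [100], "max_depth": [None, 10]},
        seed=_stage_seed(seed, 6),
    )

    # -- simulate -----------------------------------------------------------
    cohort = generate_cohort(phantom_cfg, config.n_phantoms, config.class_probabilities)
    write_cohort_csv(cohort, out / "cohort.csv")

    # -- preprocess + split -------------------------------------------------
    images = np.stack([zscore(ph.image) for ph in cohort])
    masks = np.stack([ph.mask for ph in cohort])
    train_ids, val_ids, test_ids = split_cohort(range(len(cohort)), split_spec)

    # -- train segmentation -------------------------------------------------
    net, log = train(
        model_spec,
        images[train_ids], masks[train_ids],
        images[val_ids], masks[val_ids],
        train_cfg, loss_cfg,
    )
    pd.DataFrame({
        "epoch": range(1, len(log.train_loss) + 1),
        "train_loss": log.train_loss,
        "val_dice": log.val_dice,
        "learning_rate": log.learning_rate,
    }).to_csv(out / "train_log.csv", index=False)
    net.save(out / "checkpoint.npz")

    # -- segment the test split --------------------------------------------
    test_dice = validation_dice(net, images[test_ids], masks[test_ids])
    seg_reports = []
    for i in test_ids:
        prob = net.forward(images[i:i + 1]).data[0, 0]
        seg_reports.append(overlap_metrics((prob >= 0.5).astype(int), masks[i]))

    # -- radiomics on ground-truth masks ------------------------------------
    catalogue = build_catalogue(feat_cfg)
    rows = [extract_all(ph, feat_cfg) for ph in cohort]
    feats = pd.DataFrame(rows)[catalogue.names]
    feats.insert(0, "id", [f"subj{i:04d}" for i in range(len(cohort))])
    feats.to_csv(out / "features.csv", index=False)
    labels = np.array([ph.label.category for ph in cohort])

    # -- selection + classification (train on train+val, test held out) -----
    fit_ids = np.array(train_ids + val_ids)
    x_all = feats[catalogue.names].to_numpy(dtype=float)
    x_fit_std, scaler, keep = standardize_features(x_all[fit_ids])
    names_kept = [catalogue.names[i] for i in keep]
    sel = select_biomarkers(x_fit_std, labels[fit_ids], names_kept, sel_cfg)
    cols = [names_kept.index(n) for n in sel.selected_names]
    x_test_std = scaler.transform(x_all[np.array(test_ids)][:, keep])

    x_bal, y_bal = smote_balance(x_fit_std[:, cols], labels[fit_ids],
                                 seed=_stage_seed(seed, 7))
    model, best_params, _ = fit_with_grid(x_bal, y_bal, clf_spec)
    report = evaluate(model, x_test_std[:, cols], labels[np.array(test_ids)])

    summary = {
        "n_phantoms": config.n_phantoms,
        "split_sizes": [len(train_ids), len(val_ids), len(test_ids)],
        "best_val_dice": log.best_val_dice,
        "test_dice": test_dice,
        "test_iou_foreground": float(np.mean([r.iou_foreground for r in seg_reports])),
        "n_features": len(catalogue),
        "n_selected": len(sel.selected_names),
        "selected_features": sel.selected_names,
        "classifier_best_params": {k: (None if v is None else v) for k, v in best_params.items()},
        "accuracy": report.accuracy,
        "macro_f1": report.macro_f1,
        "resolved_defaults": {
            "lambda_global": loss_cfg.lambda_global,
            "module_terms": loss_cfg.module_terms,
            "n_gray_levels": feat_cfg.n_gray_levels,
            "rfe_step": sel_cfg.rfe_step,
            "ensemble": "mean reciprocal rank",
            "macro_averaging": True,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
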