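"""Desk-scale synthetic benchmarks of the full pipeline.

These experiments run the complete method on generated data with known
ground truth, at problem sizes chosen to finish in minutes on one CPU:

* :func:`biomarker_recovery_experiment` — train the seven single
  classifiers on a modeling dataset (no translocations), screen a separate
  biomarker dataset in which half the proteins translocate, and measure how
  well the flagged set matches the ground truth.
* :func:`partition_gap_experiment` — measure per-image vs per-protein
  cross-validation accuracy on feature-level data with protein-specific
  nuisance structure (the leakage effect that makes per-image optimistic).

Image sizes, patch counts and network widths are reduced relative to a
full-scale IHC study (the methods note records the exact sizes); the
statistical structure under test is preserved.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import crossval
from .core_io import load_manifest
from .pipeline import (
    PipelineConfig,
    build_backbone_models,
    featurize_manifest,
    score_vectors,
    screen_manifest,
    train_single_classifiers,
)
from .synthdata import SynthSpec, synth_dataset


def default_benchmark_config(workdir: str, seed: int) -> PipelineConfig:
    """Desk-scale pipeline settings used by the synthetic benchmarks."""
    return PipelineConfig(
        workdir=workdir,
        patch_n=5, patch_size=48,
        deep_input_side=48, gapnet_base_width=4,
        sda_max_k=30, seed=seed,
    )


def biomarker_recovery_experiment(seed: int, *, n_screen_proteins: int = 20,
                                  images_per_state: tuple[int, int] = (4, 12),
                                  biomarker_fraction: float = 0.5,
                                  n_model_proteins: int = 18,
                                  model_images: tuple[int, int] = (3, 2),
                                  image_size: int = 160, n_nuclei: int = 10,
                                  workdir: str | None = None) -> dict:
    """Full-pipeline biomarker recovery on synthetic data with known truth.

    Returns a dict with balanced accuracy of the biomarker flags against the
    generator's truth, the detection rate among true translocators, and the
    voting accuracy of the predicted normal/cancer locations.
    """
    tmp = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="ihcloc_bench_"))
    tmp.mkdir(parents=True, exist_ok=True)
    spec = SynthSpec(image_size=image_size, n_nuclei=n_nuclei, seed=seed)
    synth_dataset(tmp / "model", n_model_proteins, model_images, 0.0, spec, seed=seed)
    synth_dataset(tmp / "screen", n_screen_proteins, images_per_state,
                  biomarker_fraction, spec, seed=seed + 1000)
    cfg = default_benchmark_config(str(tmp / "run"), seed)
    backbone_models = build_backbone_models(cfg)
    man_tr = load_manifest(tmp / "model" / "manifest.csv")
    eng_tr, deep_tr = featurize_manifest(man_tr, tmp / "model", cfg, backbone_models)
    classifiers = train_single_classifiers(man_tr, eng_tr, deep_tr, cfg)
    man_sc = load_manifest(tmp / "screen" / "manifest.csv")
    eng_sc, deep_sc = featurize_manifest(man_sc, tmp / "screen", cfg, backbone_models)
    vecs = score_vectors(man_sc, eng_sc, deep_sc, classifiers, cfg)
    reports = screen_manifest(man_sc, vecs, cfg)

    truth = pd.read_csv(tmp / "screen" / "truth.csv").set_index("protein_id")
    tp = fp = tn = fn = 0
    loc_normal = []
    loc_cancer = []
    for r in reports:
        actual = bool(truth.loc[r.protein_id, "is_biomarker"])
        if r.is_biomarker and actual:
            tp += 1
        elif r.is_biomarker:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
        loc_normal.append(r.predicted_normal_location
                          == truth.loc[r.protein_id, "normal_class"])
        loc_cancer.append(r.predicted_cancer_location
                          == truth.loc[r.protein_id, "cancer_class"])
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "balanced_accuracy": 0.5 * (sensitivity + specificity),
        "detection_rate": sensitivity,
        "specificity": specificity,
        "normal_location_accuracy": float(np.mean(loc_normal)),
        "cancer_location_accuracy": float(np.mean(loc_cancer)),
        "n_proteins": len(reports),
    }


def partition_gap_experiment(n_seeds: int = 20, *, n_proteins: int = 12,
                             images_per_protein: int = 5, nuisance: float = 2.0,
                             noise: float = 0.5, k: int = 5) -> dict:
    """Per-image vs per-protein CV accuracy under protein-specific nuisance.

    Images of one protein share an appearance offset, so the per-image
    partition leaks protein identity between train and test and scores
    optimistically; grouped per-protein folds remove the leakage.  Returns
    mean accuracies and the fraction of seeds where per-image >= per-protein.
    """
    from .core_io import DatasetManifest, ManifestRecord
    from .engineered_features import FeatureMatrix

    per_image_acc, per_protein_acc = [], []
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        means = np.zeros((3, 4))
        means[1, 0::2] = 2.0
        means[2, 1::2] = 2.0
        records, rows = [], []
        for p in range(n_proteins):
            cls = p % 3
            offset = rng.normal(0, nuisance, 4)
            for i in range(images_per_protein):
                records.append(ManifestRecord(f"P{p:02d}", f"P{p:02d}_{i}.png",
                                              "normal", ["i", "ii", "iii"][cls]))
                rows.append(means[cls] + offset + rng.normal(0, noise, 4))
        manifest = DatasetManifest(records=records)
        manifest.rebuild_groups()
        features = FeatureMatrix(values=np.array(rows),
                                 row_ids=[r.image_path for r in records],
                                 column_names=[f"f{j}" for j in range(4)])
        per_image_acc.append(crossval(manifest, features, "per_image", k=k,
                                      seed=seed).accuracy)
        per_protein_acc.append(crossval(manifest, features, "per_protein", k=k,
                                        seed=seed).accuracy)
    per_image_acc = np.array(per_image_acc)
    per_protein_acc = np.array(per_protein_acc)
    return {
        "per_image_accuracy": float(per_image_acc.mean()),
        "per_protein_accuracy": float(per_protein_acc.mean()),
        "fraction_per_image_wins": float((per_image_acc >= per_protein_acc).mean()),
        "n_seeds": n_seeds,
    }
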