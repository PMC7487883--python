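"""End-to-end orchestration: images -> features -> classifiers -> biomarker screen.

The pipeline mirrors the two-stage experimental design: (1) build seven
single classifiers, one per feature route (engineered features concatenated
with one backbone's deep features), on a labelled modeling dataset; (2)
apply all seven to the images of each screened protein, concatenate their
3-class score vectors into per-image 21-dim vectors, and t-test normal
against cancer vectors per protein.

Every stage writes CSV artifacts into the working directory and a JSON
summary keyed by a hash of the stage configuration, so re-runs with an
unchanged configuration skip completed stages ("cached" in the log).
All randomness derives from one top-level seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker as bm
from .classify import SMALL_C_GRID, SMALL_G_GRID, TrainedModel, crossval, train_svm
from .core_io import LABEL_TO_INT, DatasetManifest, load_manifest, read_image
from .deep_features import (
    BACKBONE_ORDER,
    BackboneSpec,
    build_backbone,
    extract_deep,
    image_deep_vector,
)
from .engineered_features import (
    FeatureMatrix,
    HaralickConfig,
    engineered_block_index,
    engineered_column_names,
    featurize_image,
)
from .feature_selection import sda_select
from .patching import select_patches
from .unmixing import default_basis, unmix_linear, unmix_nmf

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stream: str) -> int:
    """Named deterministic substream of a top-level seed (kept below 2^31)."""
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """Every paper-silent knob, visible and versioned."""

    workdir: str = "run"
    train_manifest: str = ""
    screen_manifest: str = ""
    unmix_method: str = "lin"          # lin | nmf
    patch_n: int = 205
    patch_size: int = 75
    patch_max_overlap: float = 0.25
    patch_sigma: float = 0.0           # 0 -> size/8
    wavelet_filter: str = "db4"
    sda_f_enter: float = 3.84
    sda_f_remove: float = 2.71
    sda_max_k: int = 97
    svm_grid: str = "small"            # small | full
    cv_folds: int = 10
    backbones: tuple = BACKBONE_ORDER
    deep_input_side: int = 64
    gapnet_base_width: int = 8
    alpha: float = 0.05
    test_variant: str = "student"
    seed: int = 0

    _KNOWN = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "backbones" in raw:
            raw["backbones"] = tuple(raw["backbones"])
        return cls(**raw)

    def digest(self, *fields_: str) -> str:
        d = asdict(self)
        if fields_:
            d = {k: d[k] for k in fields_}
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _grid(cfg: PipelineConfig):
    if cfg.svm_grid == "full":
        from .classify import DEFAULT_C_GRID, DEFAULT_G_GRID

        return (DEFAULT_C_GRID, DEFAULT_G_GRID)
    return (SMALL_C_GRID, SMALL_G_GRID)


def build_backbone_models(cfg: PipelineConfig) -> dict[str, tuple[BackboneSpec, object]]:
    """One fixed random-weight model per configured backbone slot."""
    models = {}
    for name in cfg.backbones:
        spec = BackboneSpec(name=name, weights="random",
                            input_side=cfg.deep_input_side,
                            seed=derive_seed(cfg.seed, f"backbone:{name}"),
                            gapnet_base_width=cfg.gapnet_base_width)
        models[name] = (spec, build_backbone(spec))
    return models


def featurize_manifest(manifest: DatasetManifest, image_root, cfg: PipelineConfig,
                       backbone_models: dict) -> tuple[FeatureMatrix, dict[str, np.ndarray]]:
    """Per-image engineered and deep feature matrices for every record.

    Returns (engineered FeatureMatrix, {backbone: n_images x dim array}),
    rows aligned with manifest record order.
    """
    image_root = Path(image_root)
    hcfg = HaralickConfig(wavelet_filter=cfg.wavelet_filter)
    basis = default_basis()
    eng_rows, row_ids = [], []
    deep_rows: dict[str, list[np.ndarray]] = {n: [] for n in backbone_models}
    for i, rec in enumerate(manifest.records):
        img = read_image(image_root / rec.image_path, protein_id=rec.protein_id,
                         tissue_state=rec.tissue_state, label=rec.label)
        if cfg.unmix_method == "nmf":
            channels = unmix_nmf(img, seed=derive_seed(cfg.seed, f"nmf:{i}"))
        else:
            channels = unmix_linear(img, basis)
        patches = select_patches(channels, cfg.patch_n, cfg.patch_size,
                                 cfg.patch_max_overlap,
                                 sigma=cfg.patch_sigma or None,
                                 image_ref=rec.image_path)
        eng_rows.append(featurize_image(patches, hcfg))
        row_ids.append(rec.image_path)
        for name, (spec, model) in backbone_models.items():
            F = extract_deep(patches, spec, model=model)
            deep_rows[name].append(image_deep_vector(F))
    eng = FeatureMatrix.from_rows(eng_rows, row_ids, engineered_column_names(hcfg),
                                  engineered_block_index(hcfg))
    deep = {n: np.vstack(v) for n, v in deep_rows.items()}
    return eng, deep


@dataclass
class SingleClassifier:
    """One feature route: engineered + one backbone, SDA-reduced, RBF-SVM."""

    backbone: str
    selected: list[int]
    model: TrainedModel


def train_single_classifiers(manifest: DatasetManifest, engineered: FeatureMatrix,
                             deep: dict[str, np.ndarray], cfg: PipelineConfig
                             ) -> dict[str, SingleClassifier]:
    """The seven single classifiers of the integrated model."""
    y = np.array([LABEL_TO_INT[r.label] for r in manifest.records])
    out = {}
    for name in cfg.backbones:
        X = np.hstack([engineered.values, deep[name]])
        sel = sda_select(X, y, cfg.sda_f_enter, cfg.sda_f_remove, cfg.sda_max_k).selected
        if not sel:
            logger.warning("SDA selected nothing for %s; using all columns", name)
            sel = list(range(X.shape[1]))
        model = train_svm(X[:, sel], y, grid=_grid(cfg),
                          seed=derive_seed(cfg.seed, f"svm:{name}"))
        out[name] = SingleClassifier(backbone=name, selected=sel, model=model)
    return out


def score_vectors(manifest: DatasetManifest, engineered: FeatureMatrix,
                  deep: dict[str, np.ndarray],
                  classifiers: dict[str, SingleClassifier],
                  cfg: PipelineConfig) -> np.ndarray:
    """n_images x 21 matrix of concatenated 7-classifier score triples."""
    feats = {}
    for name in cfg.backbones:
        X = np.hstack([engineered.values, deep[name]])
        feats[name] = X[:, classifiers[name].selected]
    n = len(manifest)
    vecs = np.empty((n, bm.SCORE_DIM))
    for i in range(n):
        vecs[i] = bm.image_score_vector(
            [classifiers[name].model for name in cfg.backbones],
            [feats[name][i] for name in cfg.backbones])
    return vecs


def screen_manifest(manifest: DatasetManifest, vectors: np.ndarray,
                    cfg: PipelineConfig) -> list[bm.TranslocationReport]:
    """Per-protein translocation screen from per-image score vectors."""
    reports = []
    for pid, idxs in manifest.groups.items():
        normal = [i for i in idxs if manifest.records[i].tissue_state == "normal"]
        cancer = [i for i in idxs if manifest.records[i].tissue_state == "cancer"]
        if len(normal) < 2 or len(cancer) < 2:
            logger.warning("protein %s lacks >=2 images per state; skipped", pid)
            continue
        reports.append(bm.screen_protein(pid, vectors[normal], vectors[cancer],
                                         alpha=cfg.alpha, variant=cfg.test_variant))
    return reports


def reports_to_frame(reports: list[bm.TranslocationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "protein_id": r.protein_id,
            "normal_loc": r.predicted_normal_location,
            "cancer_loc": r.predicted_cancer_location,
            "min_p": float(r.p_values.min()),
            "is_biomarker": int(r.is_biomarker),
        }
        row.update({f"p{j:02d}": float(p) for j, p in enumerate(r.p_values)})
        rows.append(row)
    return pd.DataFrame(rows)


class _StageCache:
    def __init__(self, workdir: Path):
        self.workdir = workdir
        self.summary_path = workdir / "summary.json"
        self.summary = {}
        if self.summary_path.exists():
            self.summary = json.loads(self.summary_path.read_text())

    def fresh(self, stage: str, digest: str, artifacts: list[Path]) -> bool:
        ok = (self.summary.get(stage, {}).get("digest") == digest
              and all(a.exists() for a in artifacts))
        if ok:
            logger.info("stage %s: cached", stage)
        return ok

    def record(self, stage: str, digest: str, **extra) -> None:
        self.summary[stage] = {"digest": digest, **extra}
        self.summary_path.write_text(json.dumps(self.summary, indent=2, sort_keys=True))


def _feature_paths(workdir: Path, tag: str, backbones) -> list[Path]:
    return [workdir / f"features_{tag}_engineered.csv"] + [
        workdir / f"features_{tag}_deep_{n}.csv" for n in backbones]


def _save_features(workdir: Path, tag: str, eng: FeatureMatrix, deep: dict) -> None:
    df = pd.DataFrame(eng.values, index=eng.row_ids, columns=eng.column_names)
    df.to_csv(workdir / f"features_{tag}_engineered.csv", float_format="%.17g")
    for name, arr in deep.items():
        pd.DataFrame(arr, index=eng.row_ids).to_csv(
            workdir / f"features_{tag}_deep_{name}.csv", float_format="%.17g")


def _load_features(workdir: Path, tag: str, backbones) -> tuple[FeatureMatrix, dict]:
    df = pd.read_csv(workdir / f"features_{tag}_engineered.csv", index_col=0)
    eng = FeatureMatrix(values=df.values, row_ids=list(df.index),
                        column_names=list(df.columns))
    deep = {}
    for name in backbones:
        d = pd.read_csv(workdir / f"features_{tag}_deep_{name}.csv", index_col=0)
        deep[name] = d.values
    return eng, deep


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a result summary dict.

    Stages: featurize training set -> train 7 single classifiers (+ a
    cross-validation report) -> featurize screening set -> score and screen.
    Feature stages are resumable from their CSV artifacts.
    """
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log_path = workdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ihcloc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("pipeline config: %s", json.dumps(asdict(cfg), default=str, sort_keys=True))
        cache = _StageCache(workdir)
        backbone_models = build_backbone_models(cfg)
        feat_fields = ("unmix_method", "patch_n", "patch_size", "patch_max_overlap",
                       "patch_sigma", "wavelet_filter", "backbones",
                       "deep_input_side", "gapnet_base_width", "seed")

        train_manifest = load_manifest(cfg.train_manifest)
        train_root = Path(cfg.train_manifest).parent
        digest = cache_digest = cfg.digest(*feat_fields) + "-" + _manifest_digest(train_manifest)
        arts = _feature_paths(workdir, "train", cfg.backbones)
        if cache.fresh("featurize_train", digest, arts):
            eng_tr, deep_tr = _load_features(workdir, "train", cfg.backbones)
        else:
            logger.info("stage featurize_train: computing %d images", len(train_manifest))
            eng_tr, deep_tr = featurize_manifest(train_manifest, train_root, cfg,
                                                 backbone_models)
            _save_features(workdir, "train", eng_tr, deep_tr)
            cache.record("featurize_train", digest, n_images=len(train_manifest))

        classifiers = train_single_classifiers(train_manifest, eng_tr, deep_tr, cfg)
        cv = crossval(train_manifest,
                      FeatureMatrix(values=np.hstack([eng_tr.values] +
                                                     [deep_tr[n] for n in cfg.backbones]),
                                    row_ids=eng_tr.row_ids,
                                    column_names=[f"c{j}" for j in range(
                                        eng_tr.values.shape[1] +
                                        sum(deep_tr[n].shape[1] for n in cfg.backbones))]),
                      mode="per_protein",
                      k=min(cfg.cv_folds, len(train_manifest.groups)),
                      seed=derive_seed(cfg.seed, "cv"))
        pd.DataFrame(cv.confusion).to_csv(workdir / "cv_confusion.csv")

        result = {"cv_accuracy": cv.accuracy, "cv_macro_f1": cv.macro_f1,
                  "n_train_images": len(train_manifest)}

        if cfg.screen_manifest:
            screen_man = load_manifest(cfg.screen_manifest)
            screen_root = Path(cfg.screen_manifest).parent
            digest = cfg.digest(*feat_fields) + "-" + _manifest_digest(screen_man)
            arts = _feature_paths(workdir, "screen", cfg.backbones)
            if cache.fresh("featurize_screen", digest, arts):
                eng_sc, deep_sc = _load_features(workdir, "screen", cfg.backbones)
            else:
                logger.info("stage featurize_screen: computing %d images", len(screen_man))
                eng_sc, deep_sc = featurize_manifest(screen_man, screen_root, cfg,
                                                     backbone_models)
                _save_features(workdir, "screen", eng_sc, deep_sc)
                cache.record("featurize_screen", digest, n_images=len(screen_man))
            vecs = score_vectors(screen_man, eng_sc, deep_sc, classifiers, cfg)
            reports = screen_manifest(screen_man, vecs, cfg)
            frame = reports_to_frame(reports)
            frame.to_csv(workdir / "translocation_report.csv", index=False,
                         float_format="%.10g")
            result["n_screened"] = len(reports)
            result["n_flagged"] = int(frame["is_biomarker"].sum()) if len(frame) else 0
        cache.record("summary", cache_digest, **{k: (float(v) if isinstance(v, float) else v)
                                                 for k, v in result.items()})
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


def _manifest_digest(manifest: DatasetManifest) -> str:
    payload = ";".join(f"{r.protein_id},{r.image_path},{r.tissue_state},{r.label}"
                       for r in manifest.records)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
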