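import numpy as np
import pytest

from ihcloc.core_io import DatasetManifest, ManifestRecord
from ihcloc.engineered_features import FeatureMatrix
from ihcloc.synthdata import SynthSpec, synth_image


@pytest.fixture(scope="session")
def synth_pair():
    """One small noise-free class-ii synthetic image with its ground truth."""
    spec = SynthSpec(image_size=128, n_nuclei=8, seed=7, class_pattern="ii")
    return synth_image(spec)


@pytest.fixture(scope="session")
def synth_pairs_all_classes():
    return {
        cls: synth_image(SynthSpec(image_size=128, n_nuclei=8, seed=11, class_pattern=cls))
        for cls in ("i", "ii", "iii")
    }


def make_feature_dataset(seed, n_proteins=12, images_per_protein=5, nuisance=2.0,
                         noise=0.5, n_features=4):
    """Feature-level synthetic dataset: 3 Gaussian classes plus a
    protein-specific nuisance offset shared by all images of one protein."""
    rng = np.random.default_rng(seed)
    means = np.zeros((3, n_features))
    means[1, 0::2] = 2.0
    means[2, 1::2] = 2.0
    records, rows = [], []
    for p in range(n_proteins):
        cls = p % 3
        offset = rng.normal(0, nuisance, n_features)
        for i in range(images_per_protein):
            records.append(ManifestRecord(f"P{p:02d}", f"P{p:02d}_{i}.png", "normal",
                                          ["i", "ii", "iii"][cls]))
            rows.append(means[cls] + offset + rng.normal(0, noise, n_features))
    manifest = DatasetManifest(records=records)
    manifest.rebuild_groups()
    features = FeatureMatrix(values=np.array(rows),
                             row_ids=[r.image_path for r in records],
                             column_names=[f"f{j}" for j in range(n_features)])
    return manifest, features
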