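"""Synthetic IHC-like image generation with known ground truth.

Real IHC images of colon tissue are brightfield micrographs where the
antibody-targeted protein is stained brown (DAB) and nuclear DNA purple
(hematoxylin).  This module emulates their *statistical* structure — not
histological realism — so every pipeline stage can be exercised against a
known answer:

* nuclei are random ellipses carrying hematoxylin optical density;
* the protein occupies one of three patterns matching the location classes:
  class i inside nuclei, class ii in annular cytoplasm/membrane rings
  around nuclei (excluded from nuclei), class iii their union;
* RGB is rendered by Beer-Lambert mixing, ``RGB = 255 · 10^(−C·B)`` for
  concentration maps C and the stain color basis B, plus optional Gaussian
  OD noise, then quantized to 8 bits.

Ground truth (masks, continuous OD concentration maps, the basis, the class
label) is returned alongside each image.  ``synth_dataset`` assembles a
multi-protein dataset in which a chosen fraction of proteins *translocate*
— their cancer-state images use a different pattern class than their
normal-state images — which is exactly the signal the biomarker stage is
built to detect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import DatasetManifest, IHCImage, ManifestRecord, StainBasis, write_image
from .unmixing import default_basis

CLASSES = ("i", "ii", "iii")


class GenerationError(RuntimeError):
    """Raised when nuclei cannot be placed under the overlap constraint."""


@dataclass
class SynthSpec:
    """Parameters of one synthetic image.

    OD strengths are peak optical densities of each stain (typical stained
    tissue sits around 0.3-1.0 OD); noise_sd is the standard deviation of
    additive Gaussian noise in OD units.
    """

    image_size: int = 512
    n_nuclei: int = 40
    nucleus_axes: tuple[int, int] = (12, 26)
    class_pattern: str = "i"
    dab_strength: float = 0.9
    hema_strength: float = 0.7
    ring_thickness: int = 8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_pattern not in CLASSES:
            raise ValueError(f"class_pattern must be one of {CLASSES}")


@dataclass
class SynthTruth:
    """Ground truth for one synthetic image."""

    dna_mask: np.ndarray
    protein_mask: np.ndarray
    basis: StainBasis
    class_label: str
    od_dna: np.ndarray      # continuous hematoxylin concentration map
    od_protein: np.ndarray  # continuous DAB concentration map


def _place_nuclei(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-ellipse nucleus mask; bounded retries against total overlap."""
    size = spec.image_size
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = np.mgrid[0:size, 0:size]
    placed = 0
    for _ in range(spec.n_nuclei * 30):
        if placed >= spec.n_nuclei:
            break
        a = rng.uniform(spec.nucleus_axes[0], spec.nucleus_axes[1]) / 2.0
        b = rng.uniform(spec.nucleus_axes[0], spec.nucleus_axes[1]) / 2.0
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a + 1, size - a - 1)
        cx = rng.uniform(b + 1, size - b - 1)
        ct, st = np.cos(theta), np.sin(theta)
        u = (rr - cy) * ct + (cc - cx) * st
        v = -(rr - cy) * st + (cc - cx) * ct
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # reject nuclei mostly hidden under already-placed ones
        if ell.sum() == 0 or (ell & mask).sum() / ell.sum() > 0.5:
            continue
        mask |= ell
        placed += 1
    if placed < spec.n_nuclei:
        raise GenerationError(
            f"placed only {placed}/{spec.n_nuclei} nuclei without excessive overlap"
        )
    return mask


def _texture_field(shape, rng: np.random.Generator, smooth: float = 3.0) -> np.ndarray:
    """Smooth positive multiplicative texture in [0.55, 1.0].

    Gives patches non-trivial co-occurrence structure; without it every
    stained region would be flat and all texture features degenerate.
    """
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
    f = (f - f.min()) / (f.max() - f.min() + 1e-12)
    return 0.55 + 0.45 * f


def render_rgb(od_dna: np.ndarray, od_protein: np.ndarray, basis: StainBasis,
               noise_sd: float = 0.0, rng: np.random.Generator | None = None,
               quantize: bool = True) -> np.ndarray:
    """Beer-Lambert rendering of two concentration maps to RGB.

    With ``quantize=False`` the continuous float image is returned, on which
    the linear-unmixing inverse is exact; 8-bit quantization otherwise
    limits round-trip accuracy to about 1e-2 OD.
    """
    od = od_dna[..., None] * basis.dna_row + od_protein[..., None] * basis.protein_row
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        od = od + rng.normal(0.0, noise_sd, od.shape)
    od = np.maximum(od, 0.0)
    px = 255.0 * np.power(10.0, -od) - 1.0  # exact inverse of od_transform's +1 offset
    px = np.clip(px, 0.0, 255.0)
    if quantize:
        px = np.round(px).astype(np.uint8)
    return px


def synth_image(spec: SynthSpec, *, basis: StainBasis | None = None
                ) -> tuple[IHCImage, SynthTruth]:
    """Generate one synthetic IHC image and its ground truth.

    Deterministic given ``spec.seed``.
    """
    basis = basis or default_basis()
    rng = np.random.default_rng(spec.seed)
    dna_mask = _place_nuclei(spec, rng)
    ring = ndimage.binary_dilation(dna_mask, iterations=spec.ring_thickness) & ~dna_mask
    if spec.class_pattern == "i":
        protein_mask = dna_mask.copy()
    elif spec.class_pattern == "ii":
        protein_mask = ring
    else:
        protein_mask = dna_mask | ring
    tex_d = _texture_field(dna_mask.shape, rng)
    tex_p = _texture_field(dna_mask.shape, rng)
    od_dna = spec.hema_strength * dna_mask * tex_d
    od_protein = spec.dab_strength * protein_mask * tex_p
    px = render_rgb(od_dna, od_protein, basis, spec.noise_sd, rng, quantize=True)
    image = IHCImage(pixels=px, label=spec.class_pattern)
    truth = SynthTruth(dna_mask=dna_mask, protein_mask=protein_mask, basis=basis,
                       class_label=spec.class_pattern, od_dna=od_dna, od_protein=od_protein)
    return image, truth


def synth_dataset(outdir, n_proteins: int, images_per_state: tuple[int, int],
                  biomarker_fraction: float, spec: SynthSpec | None = None,
                  seed: int = 0, *, protein_jitter: float = 0.15) -> DatasetManifest:
    """Write a multi-protein synthetic dataset to ``outdir``.

    Every protein is assigned a normal-state class (cycling i, ii, iii).
    The first ``round(biomarker_fraction * n_proteins)`` proteins are
    *biomarkers*: their cancer-state images use the next class in the cycle
    (a translocation); non-biomarkers keep the same class in both states.
    ``images_per_state = (m, n)`` gives m normal and n cancer images per
    protein, matching the few-normal / many-cancer structure of real
    biomarker datasets (typically m in 3-6, n in 10-29).

    Each protein also carries a protein-specific appearance nuisance (its
    own stain-strength and nucleus-size jitter, drawn once per protein), so
    images of one protein are more alike than images of different proteins
    — the structure that makes per-protein cross-validation strictly harder
    than per-image.

    Writes PNGs, ``manifest.csv`` and ``truth.csv`` (protein_id,
    normal_class, cancer_class, is_biomarker); returns the manifest.
    """
    if n_proteins < 1 or images_per_state[0] < 1 or images_per_state[1] < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 <= biomarker_fraction <= 1.0):
        raise ValueError("biomarker_fraction must be in [0, 1]")
    spec = spec or SynthSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_bio = int(round(biomarker_fraction * n_proteins))
    records: list[ManifestRecord] = []
    truth_rows = []
    img_index = 0
    for p in range(n_proteins):
        pid = f"P{p:03d}"
        normal_class = CLASSES[p % 3]
        is_bio = p < n_bio
        cancer_class = CLASSES[(p + 1) % 3] if is_bio else normal_class
        dab_j = float(spec.dab_strength * (1.0 + protein_jitter * rng.uniform(-1, 1)))
        hema_j = float(spec.hema_strength * (1.0 + protein_jitter * rng.uniform(-1, 1)))
        ax_scale = 1.0 + 0.25 * protein_jitter / 0.15 * rng.uniform(-0.15, 0.15)
        axes = (max(4, int(round(spec.nucleus_axes[0] * ax_scale))),
                max(6, int(round(spec.nucleus_axes[1] * ax_scale))))
        truth_rows.append((pid, normal_class, cancer_class, int(is_bio)))
        for state, klass, count in (("normal", normal_class, images_per_state[0]),
                                    ("cancer", cancer_class, images_per_state[1])):
            for _ in range(count):
                ispec = replace(spec, class_pattern=klass, seed=seed + 1 + img_index,
                                dab_strength=dab_j, hema_strength=hema_j,
                                nucleus_axes=axes)
                image, _t = synth_image(ispec)
                fname = f"{pid}_{state}_{img_index:04d}.png"
                write_image(image.pixels, outdir / fname)
                records.append(ManifestRecord(protein_id=pid, image_path=fname,
                                              tissue_state=state, label=klass))
                img_index += 1
    manifest = DatasetManifest(records=records)
    manifest.validate()
    manifest.rebuild_groups()
    from .core_io import write_manifest

    write_manifest(manifest, outdir / "manifest.csv")
    with open(outdir / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "normal_class", "cancer_class", "is_biomarker"])
        w.writerows(truth_rows)
    return manifest
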