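"""Input conditioning for the encoder-decoder, and its exact inverse.

The forward chain normalises PET by a fixed activity scale (6000 Bq/ml)
and CT by an offset-plus-scale (HU + 1000)/2000, crops both volumes to a
single bounding box computed from the PET object, resamples every axial
slice to the network matrix with corner-aligned bilinear interpolation,
and finally compresses the dynamic range with the Softsign map
``x ↦ x/(1+|x|)``.  Each step is invertible, so a network prediction can
be carried back to Hounsfield units on the original CT grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from pseudoct.phantom import CTVolume
from pseudoct.physics import PETImage

__all__ = [
    "PreprocessConfig",
    "SlicePair",
    "softsign",
    "inverse_softsign",
    "normalize_pet",
    "normalize_ct",
    "rescale_to_hu",
    "crop_bounding_box",
    "resample_bilinear",
    "restore_to_source",
    "build_slice_pairs",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Fixed intensity and geometry conditioning constants.

    ``pet_scale`` and ``ct_scale`` set the dynamic-range match between
    the two modalities; ``ct_offset`` maps the air floor (−1000 HU) to
    zero before scaling.  ``target_matrix`` is the network input matrix
    (200×180 for the full-scale configuration, small squares for desk
    work).
    """

    pet_scale: float = 6000.0  # Bq/ml
    ct_scale: float = 2000.0  # HU
    ct_offset: float = 1000.0  # HU added before scaling
    target_matrix: tuple[int, int] = (200, 180)
    crop_threshold: float = 0.01  # fraction of per-volume max
    crop_margin: int = 2  # pixels

    def __post_init__(self) -> None:
        if self.pet_scale <= 0 or self.ct_scale <= 0:
            raise ValueError("scales must be positive")
        if min(self.target_matrix) < 8:
            raise ValueError("target_matrix must be at least 8 per side")


@dataclass
class SlicePair:
    """One training example: normalised NAC-PET input and CT target.

    Both slices share the target matrix shape and live in the Softsign
    domain (−1, 1).  ``crop_box`` records the half-open (row0, col0,
    row1, col1) source-grid window the slice was cut from, shared by all
    slices of a volume.
    """

    input_slice: np.ndarray
    target_slice: np.ndarray
    crop_box: tuple[int, int, int, int]
    source_id: str = ""
    slice_index: int = 0


def softsign(x: np.ndarray) -> np.ndarray:
    """Elementwise ``x / (1 + |x|)``; strictly monotone into (−1, 1)."""
    x = np.asarray(x, dtype=np.float64)
    return x / (1.0 + np.abs(x))


def inverse_softsign(y: np.ndarray) -> np.ndarray:
    """Exact inverse ``y / (1 − |y|)``; requires ``|y| < 1``."""
    y = np.asarray(y, dtype=np.float64)
    if (np.abs(y) >= 1.0).any():
        raise ValueError("inverse_softsign requires |y| < 1")
    return y / (1.0 - np.abs(y))


def normalize_pet(pet: PETImage | np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Scale PET activity to network units: ``v → v / pet_scale``."""
    v = pet.voxels if isinstance(pet, PETImage) else np.asarray(pet, dtype=np.float64)
    if (v < 0).any():
        raise ValueError("NAC PET input must be non-negative")
    return v / cfg.pet_scale


def normalize_ct(ct: CTVolume | np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Offset and scale CT numbers: ``HU → (HU + ct_offset) / ct_scale``."""
    v = ct.voxels if isinstance(ct, CTVolume) else np.asarray(ct, dtype=np.float64)
    if not np.isfinite(v).all():
        raise ValueError("CT input must be finite")
    return (v + cfg.ct_offset) / cfg.ct_scale


def rescale_to_hu(pred: np.ndarray, cfg: PreprocessConfig,
                  clip: float = 1.0 - 1e-9) -> np.ndarray:
    """Map a Softsign-domain prediction back to Hounsfield units.

    Applies the Softsign inverse then undoes the CT offset/scale.  Raw
    network output can stray outside (−1, 1), where the inverse is
    undefined; values are clipped to ``±clip`` first.  For targets that
    genuinely came from the forward chain the round trip is exact to
    well below 1e−6 HU.
    """
    y = np.clip(np.asarray(pred, dtype=np.float64), -clip, clip)
    return inverse_softsign(y) * cfg.ct_scale - cfg.ct_offset


def crop_bounding_box(volume: np.ndarray, cfg: PreprocessConfig
                      ) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Tight in-plane bounding box around the object, one box per volume.

    The box is the union over slices of all pixels above
    ``crop_threshold × max(volume)``, expanded by ``crop_margin`` and
    clipped to bounds, so every slice of a volume shares the same window
    and the cropped stack reassembles consistently in 3D.
    """
    v = np.asarray(volume, dtype=np.float64)
    if v.ndim == 2:
        v = v[..., None]
    fg = v > cfg.crop_threshold * v.max()
    if not fg.any():
        raise ValueError(
            "no foreground above crop_threshold; lower the threshold")
    mask = fg.any(axis=2)
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    r0 = max(int(rows[0]) - cfg.crop_margin, 0)
    c0 = max(int(cols[0]) - cfg.crop_margin, 0)
    r1 = min(int(rows[-1]) + 1 + cfg.crop_margin, v.shape[0])
    c1 = min(int(cols[-1]) + 1 + cfg.crop_margin, v.shape[1])
    box = (r0, c0, r1, c1)
    cropped = np.asarray(volume)[r0:r1, c0:c1, ...]
    return cropped, box


def resample_bilinear(slice2d: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear resampling of a 2D slice.

    When the target equals the source shape the output is the input
    exactly (identity sampling grid).
    """
    src = np.asarray(slice2d, dtype=np.float64)
    if min(target) < 2:
        raise ValueError("target must be at least 2 per side")
    if src.shape == tuple(target):
        return src.copy()
    r = np.linspace(0.0, src.shape[0] - 1.0, target[0])
    c = np.linspace(0.0, src.shape[1] - 1.0, target[1])
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return ndimage.map_coordinates(src, [rr, cc], order=1, mode="nearest")


def restore_to_source(pred_slice: np.ndarray, crop_box: tuple[int, int, int, int],
                      source_shape: tuple[int, int], fill_value: float = 0.0
                      ) -> np.ndarray:
    """Embed a network-matrix prediction back into the source grid.

    The prediction is resampled to the crop-box size and pasted into a
    canvas of ``source_shape`` filled with ``fill_value`` — by default
    0.0, the normalised-CT value of air, so the restored pseudo-CT has
    air (not zeros ≙ water) outside the cropped field of view.
    """
    r0, c0, r1, c1 = crop_box
    canvas = np.full(source_shape, float(fill_value))
    canvas[r0:r1, c0:c1] = resample_bilinear(pred_slice, (r1 - r0, c1 - c0))
    return canvas


def build_slice_pairs(nac: PETImage, ct: CTVolume, cfg: PreprocessConfig,
                      source_id: str = "") -> list[SlicePair]:
    """Full forward conditioning: normalise → crop → resample → Softsign.

    The crop box is computed from the PET object and applied identically
    to the CT (single source of truth), then each axial slice is
    resampled to the target matrix and Softsign-compressed.  One
    SlicePair per axial slice.
    """
    if nac.voxels.shape != ct.voxels.shape:
        raise ValueError(
            f"NAC PET grid {nac.voxels.shape} and CT grid {ct.voxels.shape} differ")
    pet_n = normalize_pet(nac, cfg)
    ct_n = normalize_ct(ct, cfg)
    _, box = crop_bounding_box(pet_n, cfg)
    r0, c0, r1, c1 = box
    pairs = []
    for k in range(pet_n.shape[2]):
        x = resample_bilinear(pet_n[r0:r1, c0:c1, k], cfg.target_matrix)
        t = resample_bilinear(ct_n[r0:r1, c0:c1, k], cfg.target_matrix)
        pairs.append(SlicePair(
            input_slice=softsign(x), target_slice=softsign(t),
            crop_box=box, source_id=source_id, slice_index=k))
    return pairs
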