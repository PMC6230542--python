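"""Seeded head-like CT / FDG-activity phantom generator.

Each phantom is an extruded-ellipse "head": an outer soft-tissue scalp, a
closed elliptical bone shell (skull), a brain interior with gray/white
contrast, and optional internal air cavities (sinus-like).  Slice axes
taper toward the volume ends so the stack is head-like rather than a
cylinder.  The same spec and seed always reproduce the phantom
bit-identically; phantom ``index`` selects an independent substream so a
dataset is reproducible under reordering.

Hounsfield values are placed well inside the standard threshold bands
(air < −400 HU, bone > 300 HU) so that thresholding the generated CT
recovers the generator's internal tissue labels exactly — a property the
test-suite relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from pseudoct._seeding import rng_for

__all__ = [
    "PhantomSpec",
    "CTVolume",
    "ActivityMap",
    "DatasetManifest",
    "InvalidGeometryError",
    "generate_phantom",
    "make_dataset",
    "TISSUE_AIR",
    "TISSUE_SOFT",
    "TISSUE_BONE",
]

# internal tissue codes (also used by evaluation.discretize_ct)
TISSUE_AIR = 0
TISSUE_SOFT = 1
TISSUE_BONE = 2


class InvalidGeometryError(ValueError):
    """Requested phantom geometry cannot form a closed head."""


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a phantom population.

    Ranges are sampled per phantom from the seeded substream; scalar
    defaults describe a 64×64, 8-slice desk-scale head with 3 mm pixels
    (192 mm field of view).
    """

    grid_size: int = 64
    n_slices: int = 8
    pixel_size: float = 3.0  # mm, in-plane
    slice_thickness: float = 6.0  # mm
    head_axes_range: tuple[tuple[float, float], tuple[float, float]] = (
        (66.0, 82.0),  # row semi-axis, mm
        (52.0, 66.0),  # col semi-axis, mm
    )
    skull_thickness_range: tuple[float, float] = (5.0, 9.0)
    scalp_thickness: float = 5.0  # mm of soft tissue outside the skull
    n_air_cavities_range: tuple[int, int] = (1, 3)
    cavity_radius_range: tuple[float, float] = (5.0, 9.0)  # mm
    hu_values: dict[str, float] = field(
        default_factory=lambda: {"air": -1000.0, "soft": 40.0, "bone": 1200.0}
    )
    hu_jitter: float = 0.05  # ±fraction applied per phantom
    activity_levels: dict[str, float] = field(
        default_factory=lambda: {
            "background": 1500.0,  # scalp / extracerebral soft tissue
            "gray": 12000.0,  # cortical band + deep nuclei
            "white": 4000.0,
            "bone": 300.0,
            "lesion": 24000.0,
        }
    )
    abnormality: str = "none"  # none | skull_defect | hot_lesion
    seed: int = 0

    def __post_init__(self) -> None:
        hv = self.hu_values
        if not (hv["air"] < -400.0 and -400.0 < hv["soft"] < 300.0 and hv["bone"] > 300.0):
            raise ValueError(
                "hu_values must satisfy air < -400, soft in (-400, 300), bone > 300"
            )
        if any(v < 0 for v in self.activity_levels.values()):
            raise ValueError("activity_levels must be non-negative")
        if self.abnormality not in ("none", "skull_defect", "hot_lesion"):
            raise ValueError(f"unknown abnormality {self.abnormality!r}")
        if self.grid_size < 16 or self.n_slices < 1:
            raise ValueError("grid too small")


@dataclass
class CTVolume:
    """CT voxel grid in Hounsfield units, clamped to [−1024, 3000].

    ``voxels`` has shape (rows, cols, n_slices); the axial slice axis is
    the last array axis throughout the package.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # mm (row, col, slice)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.voxels = np.clip(np.asarray(self.voxels, dtype=np.float64), -1024.0, 3000.0)


@dataclass
class ActivityMap:
    """True tracer distribution in Bq/ml with a phantom-defined ROI map.

    ``label_map`` holds one integer ROI id per voxel, ids contiguous from
    0 (= background); the ROIs partition the brain interior and feed the
    region-level PET statistics.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: np.ndarray | None = None
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if (self.voxels < 0).any():
            raise ValueError("activity must be non-negative")
        if self.label_map is not None:
            ids = np.unique(self.label_map)
            if not np.array_equal(ids, np.arange(ids.size)):
                raise ValueError("label ids must be contiguous starting at 0")


def _ellipse_mask(shape: tuple[int, int], center_mm: tuple[float, float],
                  semi_axes_mm: tuple[float, float], pixel_size: float) -> np.ndarray:
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2.0) * pixel_size
    c = (np.arange(cols) - (cols - 1) / 2.0) * pixel_size
    rr, cc = np.meshgrid(r, c, indexing="ij")
    a, b = semi_axes_mm
    if a <= 0 or b <= 0:
        return np.zeros(shape, dtype=bool)
    return ((rr - center_mm[0]) / a) ** 2 + ((cc - center_mm[1]) / b) ** 2 <= 1.0


def _smooth_texture(rng: np.random.Generator, shape: tuple[int, ...],
                    sigma_px: float, amplitude: float) -> np.ndarray:
    """Band-limited zero-mean texture, clipped to ±amplitude."""
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma=sigma_px)
    sd = noise.std()
    if sd > 0:
        noise *= (amplitude / 3.0) / sd
    return np.clip(noise, -amplitude, amplitude)


def generate_phantom(spec: PhantomSpec, index: int) -> tuple[CTVolume, ActivityMap]:
    """Generate the ``index``-th phantom of a spec's population.

    Returns a paired CT (HU) and activity map (Bq/ml) on the same grid.
    Deterministic: the same (spec, index) yields bit-identical arrays.

    Raises
    ------
    InvalidGeometryError
        If the sampled skull thickness (plus scalp) reaches the smaller
        head semi-axis, so no closed shell with a brain interior exists.
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = rng_for(spec.seed, "phantom", index)
    n = spec.grid_size
    nz = spec.n_slices
    px = spec.pixel_size

    (ar_lo, ar_hi), (ac_lo, ac_hi) = spec.head_axes_range
    a_row = rng.uniform(ar_lo, ar_hi)
    a_col = rng.uniform(ac_lo, ac_hi)
    skull_t = rng.uniform(*spec.skull_thickness_range)
    center = tuple(rng.uniform(-3.0, 3.0, size=2))

    if skull_t + spec.scalp_thickness >= min(a_row, a_col):
        raise InvalidGeometryError(
            f"skull thickness {skull_t:.1f} mm (+ scalp {spec.scalp_thickness:.1f} mm) "
            f"reaches the smaller head semi-axis {min(a_row, a_col):.1f} mm"
        )

    # per-phantom HU draw, kept inside the threshold bands by construction
    j = spec.hu_jitter
    hu_air = spec.hu_values["air"] * (1 + rng.uniform(-j, j))
    hu_soft = spec.hu_values["soft"] * (1 + rng.uniform(-j, j))
    hu_bone = spec.hu_values["bone"] * (1 + rng.uniform(-j, j))

    # sinus-like cavities, anterior brain, fixed across slices they span
    n_cav = int(rng.integers(spec.n_air_cavities_range[0], spec.n_air_cavities_range[1] + 1))
    cavities = []
    for _ in range(n_cav):
        cr = rng.uniform(*spec.cavity_radius_range)
        # position as fraction of the brain semi-axes, biased anterior
        fr = rng.uniform(-0.55, -0.1)
        fc = rng.uniform(-0.45, 0.45)
        z0 = int(rng.integers(0, max(1, nz - 1)))
        z1 = min(nz, z0 + int(rng.integers(1, max(2, nz // 2 + 1))))
        cavities.append((fr, fc, cr, z0, z1))

    lesion = None
    if spec.abnormality == "hot_lesion":
        lesion = (rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3),
                  rng.uniform(6.0, 10.0), nz // 2)
    defect_angles = None
    if spec.abnormality == "skull_defect":
        a0 = rng.uniform(0, 2 * np.pi)
        defect_angles = (a0, a0 + rng.uniform(0.6, 1.1))  # rad sector

    tissue = np.full((n, n, nz), TISSUE_AIR, dtype=np.int8)
    rois = np.zeros((n, n, nz), dtype=np.int16)
    activity = np.zeros((n, n, nz), dtype=np.float64)

    zc = (nz - 1) / 2.0
    zr = max(zc, 0.5)
    lv = spec.activity_levels
    cortex_t = 8.0  # mm gray cortical band inside the skull

    r_mm = (np.arange(n) - (n - 1) / 2.0) * px
    rr, cc = np.meshgrid(r_mm, r_mm, indexing="ij")

    for k in range(nz):
        taper = np.sqrt(max(0.35, 1.0 - 0.5 * ((k - zc) / zr) ** 2))
        ax_r, ax_c = a_row * taper, a_col * taper
        head = _ellipse_mask((n, n), center, (ax_r, ax_c), px)
        skull_out = _ellipse_mask(
            (n, n), center, (ax_r - spec.scalp_thickness, ax_c - spec.scalp_thickness), px)
        skull_in = _ellipse_mask(
            (n, n), center,
            (ax_r - spec.scalp_thickness - skull_t, ax_c - spec.scalp_thickness - skull_t), px)
        brain = skull_in
        shell = skull_out & ~skull_in
        if defect_angles is not None and k >= nz // 3:
            theta = np.arctan2(rr - center[0], cc - center[1]) % (2 * np.pi)
            a0, a1 = defect_angles
            sector = (theta >= a0 % (2 * np.pi)) & (theta <= a1 % (2 * np.pi)) \
                if a1 % (2 * np.pi) > a0 % (2 * np.pi) else \
                (theta >= a0 % (2 * np.pi)) | (theta <= a1 % (2 * np.pi))
            shell = shell & ~sector

        tissue[..., k][head] = TISSUE_SOFT
        tissue[..., k][shell] = TISSUE_BONE

        # gray cortical band + white interior
        core = _ellipse_mask(
            (n, n), center,
            (ax_r - spec.scalp_thickness - skull_t - cortex_t,
             ax_c - spec.scalp_thickness - skull_t - cortex_t), px)
        gray = brain & ~core
        white = core

        # deep-gray central ellipse inside the white matter
        deep = _ellipse_mask((n, n), center, (0.28 * ax_r, 0.30 * ax_c), px) & white

        act_k = np.zeros((n, n))
        act_k[head] = lv["background"]
        act_k[shell] = lv["bone"]
        act_k[white] = lv["white"]
        act_k[gray | deep] = lv["gray"]

        # ROI partition of the brain: deep nuclei + four cortical/lobar quadrants
        roi_k = np.zeros((n, n), dtype=np.int16)
        ant = rr < center[0]
        left = cc < center[1]
        roi_k[brain & ant & left] = 1
        roi_k[brain & ant & ~left] = 2
        roi_k[brain & ~ant & left] = 3
        roi_k[brain & ~ant & ~left] = 4
        roi_k[deep] = 5

        for (fr, fc, cr_mm, z0, z1) in cavities:
            if not (z0 <= k < z1):
                continue
            cav = _ellipse_mask(
                (n, n),
                (center[0] + fr * (ax_r - spec.scalp_thickness - skull_t),
                 center[1] + fc * (ax_c - spec.scalp_thickness - skull_t)),
                (cr_mm, cr_mm), px)
            cav &= brain
            tissue[..., k][cav] = TISSUE_AIR
            act_k[cav] = 0.0
            roi_k[cav] = 0

        if lesion is not None:
            flr, flc, lr_mm, lz = lesion
            dz_mm = abs(k - lz) * spec.slice_thickness
            if dz_mm < lr_mm:
                r_in_plane = np.sqrt(lr_mm**2 - dz_mm**2)
                les = _ellipse_mask(
                    (n, n),
                    (center[0] + flr * ax_r, center[1] + flc * ax_c),
                    (r_in_plane, r_in_plane), px)
                les &= brain & (tissue[..., k] == TISSUE_SOFT)
                act_k[les] = lv["lesion"]

        activity[..., k] = act_k
        rois[..., k] = roi_k

    # continuous CT: tissue plateaus plus band-limited texture that stays
    # inside the threshold bands
    ct = np.empty((n, n, nz))
    ct[tissue == TISSUE_AIR] = hu_air
    ct[tissue == TISSUE_SOFT] = hu_soft
    ct[tissue == TISSUE_BONE] = hu_bone
    ct[tissue == TISSUE_SOFT] += _smooth_texture(rng, ct.shape, 1.5, 60.0)[tissue == TISSUE_SOFT]
    ct[tissue == TISSUE_BONE] += _smooth_texture(rng, ct.shape, 1.5, 250.0)[tissue == TISSUE_BONE]

    # mild smooth activity heterogeneity (±10%), zero stays zero
    activity *= 1.0 + _smooth_texture(rng, activity.shape, 2.0, 0.10)

    spacing = (px, px, spec.slice_thickness)
    roi_names = ("background", "frontal_left", "frontal_right",
                 "posterior_left", "posterior_right", "deep_gray")
    ct_vol = CTVolume(voxels=ct, spacing=spacing)
    act_map = ActivityMap(voxels=activity, spacing=spacing,
                          label_map=rois, roi_names=roi_names)
    return ct_vol, act_map


@dataclass
class DatasetManifest:
    """Train/test split listing written alongside generated phantoms."""

    table: pd.DataFrame  # columns: id, split, ct_path, act_path, label_path, seed

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path) -> "DatasetManifest":
        return DatasetManifest(pd.read_csv(path, sep="\t"))


def split_indices(seed: int, n_train: int, n_test: int) -> tuple[list[int], list[int]]:
    """Random disjoint train/test split over phantom indices, seed-determined."""
    total = n_train + n_test
    order = rng_for(seed, "split").permutation(total)
    return sorted(int(i) for i in order[:n_train]), sorted(int(i) for i in order[n_train:])


def make_dataset(spec: PhantomSpec, n_train: int, n_test: int,
                 out_dir: str | Path, overwrite: bool = False) -> DatasetManifest:
    """Generate and write a phantom dataset with a random train/test split.

    Writes one NIfTI per phantom for CT, activity and ROI labels, plus a
    tab-delimited manifest. The split depends only on ``spec.seed``.
    """
    from pseudoct.io import save_volume  # local import avoids a cycle

    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    out_dir.mkdir(parents=True, exist_ok=True)

    train_idx, test_idx = split_indices(spec.seed, n_train, n_test)
    split_of = {i: "train" for i in train_idx}
    split_of.update({i: "test" for i in test_idx})

    rows = []
    for i in range(n_train + n_test):
        ct, act = generate_phantom(spec, i)
        ct_path = out_dir / f"phantom_{i:04d}_ct.nii.gz"
        act_path = out_dir / f"phantom_{i:04d}_act.nii.gz"
        lab_path = out_dir / f"phantom_{i:04d}_rois.nii.gz"
        save_volume(ct.voxels, ct.spacing, ct_path)
        save_volume(act.voxels, act.spacing, act_path)
        save_volume(act.label_map.astype(np.int16), act.spacing, lab_path)
        rows.append({
            "id": i, "split": split_of[i],
            "ct_path": ct_path.name, "act_path": act_path.name,
            "label_path": lab_path.name, "seed": spec.seed,
        })
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.to_tsv(manifest_path)
    return manifest
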