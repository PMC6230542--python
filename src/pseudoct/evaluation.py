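"""Quantitative evaluation: tissue overlap, HU error, PET percent error.

Pseudo-CT accuracy is scored by discretising both CT volumes into
air / soft tissue / bone with the standard cutpoints (bone if HU > 300,
air if HU < −400, otherwise soft — strict inequalities), computing the
per-class Dice coefficient, and the mean absolute error in HU.

PET quantification is scored against the CT-corrected reference with
the pixel-wise percent error ``(I_test − I_ref) / I_ref × 100`` inside
a mask, summarised per ROI across subjects with paired t-tests and a
Bonferroni-corrected significance level (0.05 / m tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pseudoct.phantom import CTVolume, TISSUE_AIR, TISSUE_BONE, TISSUE_SOFT
from pseudoct.physics import PETImage

__all__ = [
    "TissueLabelMap",
    "ErrorMap",
    "discretize_ct",
    "dice",
    "mae",
    "error_map",
    "roi_statistics",
    "TISSUE_NAMES",
]

log = logging.getLogger(__name__)

TISSUE_NAMES = {"air": TISSUE_AIR, "soft": TISSUE_SOFT, "bone": TISSUE_BONE}

AIR_BELOW_HU = -400.0
BONE_ABOVE_HU = 300.0


@dataclass
class TissueLabelMap:
    """Discrete air/soft/bone labels from HU thresholding."""

    labels: np.ndarray
    thresholds: tuple[float, float] = (AIR_BELOW_HU, BONE_ABOVE_HU)


@dataclass
class ErrorMap:
    """Signed and absolute percent error inside an object mask."""

    err: np.ndarray
    abs_err: np.ndarray
    mask: np.ndarray


def discretize_ct(ct: CTVolume | np.ndarray) -> TissueLabelMap:
    """Threshold a (pseudo-)CT into tissue classes.

    Strict inequalities: a voxel exactly at 300 or −400 HU is soft
    tissue.
    """
    hu = ct.voxels if isinstance(ct, CTVolume) else np.asarray(ct, dtype=np.float64)
    if not np.isfinite(hu).all():
        raise ValueError("CT contains non-finite values")
    labels = np.full(hu.shape, TISSUE_SOFT, dtype=np.int8)
    labels[hu > BONE_ABOVE_HU] = TISSUE_BONE
    labels[hu < AIR_BELOW_HU] = TISSUE_AIR
    return TissueLabelMap(labels=labels)


def dice(a: TissueLabelMap, b: TissueLabelMap, tissue: str | int,
         mask: np.ndarray | None = None) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) for one tissue class.

    Both sets empty counts as perfect (vacuous) agreement and returns
    1.0 with a log note.  An optional boolean mask restricts the
    comparison (e.g. air inside the head only).
    """
    if a.labels.shape != b.labels.shape:
        raise ValueError(f"shape mismatch {a.labels.shape} vs {b.labels.shape}")
    code = TISSUE_NAMES[tissue] if isinstance(tissue, str) else int(tissue)
    sa = a.labels == code
    sb = b.labels == code
    if mask is not None:
        sa = sa & mask
        sb = sb & mask
    denom = int(sa.sum()) + int(sb.sum())
    if denom == 0:
        log.info("dice: both label sets empty for tissue %r; returning 1.0", tissue)
        return 1.0
    return 2.0 * int((sa & sb).sum()) / denom


def mae(pseudo: CTVolume | np.ndarray, truth: CTVolume | np.ndarray,
        mask: np.ndarray | None = None) -> float:
    """Mean absolute HU error over the mask (default: everywhere)."""
    p = pseudo.voxels if isinstance(pseudo, CTVolume) else np.asarray(pseudo, dtype=float)
    t = truth.voxels if isinstance(truth, CTVolume) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch {p.shape} vs {t.shape}")
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return float(np.abs(p - t)[mask].mean())


def error_map(pet_test: PETImage | np.ndarray, pet_ref: PETImage | np.ndarray,
              mask: np.ndarray | None = None,
              ref_floor_fraction: float = 0.01) -> ErrorMap:
    """Pixel-wise percent error of a test PET against the reference.

    ``Err = (I_test − I_ref) / I_ref × 100`` within the mask.  Voxels
    whose reference intensity falls below ``ref_floor_fraction`` of the
    reference maximum are excluded, so near-zero denominators never
    enter the statistics.
    """
    it = pet_test.voxels if isinstance(pet_test, PETImage) else np.asarray(pet_test, float)
    ir = pet_ref.voxels if isinstance(pet_ref, PETImage) else np.asarray(pet_ref, float)
    if it.shape != ir.shape:
        raise ValueError(f"grid mismatch {it.shape} vs {ir.shape}")
    floor = ref_floor_fraction * ir.max()
    valid = ir > floor
    if mask is not None:
        valid &= mask
    if not valid.any():
        raise ValueError("empty mask after reference flooring")
    err = np.zeros(it.shape)
    err[valid] = (it[valid] - ir[valid]) / ir[valid] * 100.0
    return ErrorMap(err=err, abs_err=np.abs(err), mask=valid)


def _paired_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t-test p-value; degenerate all-equal pairs → p = 1."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if d.size < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    if np.allclose(d.std(ddof=1), 0.0):
        log.info("paired t-test: zero-variance differences; reporting p = 1")
        return 1.0
    return float(stats.ttest_rel(x, y).pvalue)


def roi_statistics(err_maps: list[ErrorMap], rois: np.ndarray | list[np.ndarray],
                   pet_tests: list[PETImage] | None = None,
                   pet_refs: list[PETImage] | None = None,
                   roi_names: dict[int, str] | None = None,
                   alpha: float = 0.05, m_tests: int | None = None
                   ) -> pd.DataFrame:
    """Across-subject ROI summary with paired t-tests.

    ``rois`` is either a single ROI label volume shared by all subjects
    or one volume per subject.  For every ROI id > 0 the subject-level
    ROI means of the signed and absolute percent error are summarised as
    mean, sd, min and max; when the per-subject PET images are supplied,
    a two-sided paired t-test compares the ROI-mean activities of test
    vs reference.  Significance is reported uncorrected (p < alpha) and
    Bonferroni-corrected (p < alpha / m_tests; m defaults to the number
    of ROIs).  A pooled "all_regions" row aggregates the per-ROI subject
    means.
    """
    if len(err_maps) < 2:
        raise ValueError("roi_statistics needs at least 2 subjects")
    if isinstance(rois, np.ndarray):
        roi_list = [rois] * len(err_maps)
    else:
        roi_list = list(rois)
        if len(roi_list) != len(err_maps):
            raise ValueError("one ROI volume per subject required")
    roi_ids = sorted({int(i) for r in roi_list for i in np.unique(r) if i != 0})
    if m_tests is None:
        m_tests = len(roi_ids)
    threshold = alpha / m_tests

    rows = []
    all_signed, all_abs = [], []
    for rid in roi_ids:
        sels = [r == rid for r in roi_list]
        if any(not s.any() for s in sels):
            raise ValueError(f"ROI {rid} is empty in at least one subject")
        signed = np.array([em.err[s & em.mask].mean()
                           for em, s in zip(err_maps, sels)])
        abserr = np.array([em.abs_err[s & em.mask].mean()
                           for em, s in zip(err_maps, sels)])
        all_signed.append(signed)
        all_abs.append(abserr)
        p = np.nan
        if pet_tests is not None and pet_refs is not None:
            mt = np.array([im.voxels[s].mean() for im, s in zip(pet_tests, sels)])
            mr = np.array([im.voxels[s].mean() for im, s in zip(pet_refs, sels)])
            p = _paired_t(mt, mr)
        rows.append({
            "region": (roi_names or {}).get(rid, f"roi_{rid}"),
            "mean_err": signed.mean(), "sd_err": signed.std(ddof=1),
            "min_err": signed.min(), "max_err": signed.max(),
            "mean_abs_err": abserr.mean(), "sd_abs_err": abserr.std(ddof=1),
            "min_abs_err": abserr.min(), "max_abs_err": abserr.max(),
            "p_value": p,
            "significant_uncorrected": bool(p < alpha) if np.isfinite(p) else False,
            "significant_bonferroni": bool(p < threshold) if np.isfinite(p) else False,
        })

    pooled_signed = np.concatenate(all_signed)
    pooled_abs = np.concatenate(all_abs)
    rows.append({
        "region": "all_regions",
        "mean_err": pooled_signed.mean(), "sd_err": pooled_signed.std(ddof=1),
        "min_err": pooled_signed.min(), "max_err": pooled_signed.max(),
        "mean_abs_err": pooled_abs.mean(), "sd_abs_err": pooled_abs.std(ddof=1),
        "min_abs_err": pooled_abs.min(), "max_abs_err": pooled_abs.max(),
        "p_value": np.nan,
        "significant_uncorrected": False,
        "significant_bonferroni": False,
    })
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["m_tests"] = m_tests
    df.attrs["bonferroni_threshold"] = threshold
    return df
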