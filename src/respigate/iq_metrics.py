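"""NEMA-style image-quality metrics: CR, BV, CNR, liver-VOI noise, SUVmax.

Hot-sphere ROIs are planar circles with the sphere's inner diameter on the
central sphere plane; twelve background ROIs of each diameter sit on a ring
in the uniform background, clear of the spheres and the body edge.  From
the ROI counts:

    CR_j  = (C_H/C_B - 1) / (a_H/a_B - 1) x 100      [percent]
    BV_j  = SD_j / C_B x 100                          [percent]
    CNR_j = CR_j / BV_j

where C_H is the mean count in the sphere ROI, C_B the mean over the
background ROI means, and SD_j the dispersion of the background counts —
by default the SD across the twelve ROI means (NEMA convention), optionally
the pooled voxelwise SD.  Liver-like noise is summarised by a 30 mm
spherical VOI in the uniform background: SNR = mean(VOI)/SD(VOI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phantom_sim import ImageVolume, PhantomSpec, PhantomError

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """Undefined or inconsistent IQ-metric computation."""


@dataclass(frozen=True)
class RoiStats:
    """Per-sphere ROI count summary feeding the CR/BV equations."""

    sphere_id: int
    diameter_mm: float
    c_hot: float
    c_background: float
    sd_background: float
    n_background_rois: int

    def __post_init__(self) -> None:
        if self.n_background_rois < 2:
            raise MetricError("need at least 2 background ROIs")


@dataclass(frozen=True)
class IQResult:
    """Per-sphere CR/BV/CNR for one reconstruction arm."""

    arm: str
    table: pd.DataFrame  # columns: sphere_mm, CR, BV, CNR


@dataclass(frozen=True)
class LiverNoiseResult:
    """Mean, SD and SNR over a spherical background VOI."""

    voi_mean: float
    voi_sd: float
    snr: float
    voi_diameter_mm: float


def _slice_index(volume: ImageVolume, z_mm: float) -> int:
    nz = volume.data.shape[2]
    zc = volume.origin_mm[2] + volume.voxel_size_mm * np.arange(nz)
    return int(np.argmin(np.abs(zc - z_mm)))


def _circle_mask(volume: ImageVolume, center_mm: Sequence[float], diameter_mm: float) -> np.ndarray:
    """In-plane circular ROI on the slice nearest the centre's z."""
    x, y, _ = volume.coords()
    k = _slice_index(volume, center_mm[2])
    mask = np.zeros(volume.data.shape, dtype=bool)
    in_plane = (x[:, :, 0] - center_mm[0]) ** 2 + (y[:, :, 0] - center_mm[1]) ** 2 <= (
        diameter_mm / 2.0
    ) ** 2
    mask[:, :, k] = in_plane
    return mask


def _sphere_mask(volume: ImageVolume, center_mm: Sequence[float], diameter_mm: float) -> np.ndarray:
    x, y, z = volume.coords()
    return (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2 <= (
        diameter_mm / 2.0
    ) ** 2


def sphere_rois(
    volume: ImageVolume, spec: PhantomSpec
) -> tuple[dict[int, np.ndarray], dict[int, list[np.ndarray]]]:
    """Hot-sphere and background ROI masks for every sphere diameter.

    Returns ``(hot, background)``: ``hot[j]`` is the circular ROI on sphere
    ``j``'s central plane; ``background[j]`` the twelve same-diameter ROIs
    at the background ring positions.  Raises if a background ROI would
    collide with a sphere or the body edge (15 mm clearance).
    """
    hot: dict[int, np.ndarray] = {}
    background: dict[int, list[np.ndarray]] = {}
    centers = spec.sphere_centers
    bg_centers = spec.background_roi_centers
    for j, d in enumerate(spec.sphere_diameters_mm):
        roi_r = d / 2.0
        for bc in bg_centers:
            for sc, sd in zip(centers, spec.sphere_diameters_mm):
                if np.linalg.norm(bc - sc) < roi_r + sd / 2.0 + spec.clearance_mm:
                    raise PhantomError("background ROI collides with a sphere")
            if np.linalg.norm(bc[:2]) + roi_r + spec.clearance_mm > spec.body_radius_mm:
                raise PhantomError("background ROI too close to the body edge")
        hot[j] = _circle_mask(volume, centers[j], d)
        background[j] = [_circle_mask(volume, bc, d) for bc in bg_centers]
    return hot, background


def roi_stats(
    volume: ImageVolume,
    spec: PhantomSpec,
    bv_mode: str = "across_roi",
) -> list[RoiStats]:
    """Per-sphere hot/background ROI count statistics.

    ``bv_mode="across_roi"`` takes SD across the background ROI means;
    ``"voxelwise"`` pools all background-ROI voxels and takes their SD.
    """
    if bv_mode not in ("across_roi", "voxelwise"):
        raise MetricError("bv_mode must be 'across_roi' or 'voxelwise'")
    hot, background = sphere_rois(volume, spec)
    out = []
    for j, d in enumerate(spec.sphere_diameters_mm):
        c_hot = float(volume.data[hot[j]].mean())
        means = np.array([float(volume.data[m].mean()) for m in background[j]])
        c_bg = float(means.mean())
        if bv_mode == "across_roi":
            sd = float(means.std(ddof=1))
        else:
            pooled = np.concatenate([volume.data[m].ravel() for m in background[j]])
            sd = float(pooled.std(ddof=1))
        out.append(
            RoiStats(
                sphere_id=j,
                diameter_mm=float(d),
                c_hot=c_hot,
                c_background=c_bg,
                sd_background=sd,
                n_background_rois=len(background[j]),
            )
        )
    return out


def contrast_recovery(c_hot: float, c_background: float, contrast_ratio: float) -> float:
    """Percent contrast recovery: ((C_H/C_B - 1)/(a_H/a_B - 1)) x 100."""
    if c_background == 0:
        raise MetricError("CR undefined: zero background counts")
    if contrast_ratio == 1:
        raise MetricError("CR undefined: activity ratio of 1")
    return (c_hot / c_background - 1.0) / (contrast_ratio - 1.0) * 100.0


def background_variability(sd_background: float, c_background: float) -> float:
    """Percent background variability: (SD / C_B) x 100."""
    if c_background == 0:
        raise MetricError("BV undefined: zero background counts")
    return sd_background / c_background * 100.0


def cnr(cr: float, bv: float) -> Optional[float]:
    """Contrast-to-noise ratio CR/BV; None (undefined) when BV is 0."""
    if bv == 0:
        logger.warning("CNR undefined: BV is zero")
        return None
    return cr / bv


def analyze_image_quality(
    volume: ImageVolume,
    spec: PhantomSpec,
    arm: str = "",
    bv_mode: str = "across_roi",
) -> IQResult:
    """CR/BV/CNR for every sphere of one reconstructed volume."""
    rows = []
    for st in roi_stats(volume, spec, bv_mode=bv_mode):
        cr = contrast_recovery(st.c_hot, st.c_background, spec.contrast_ratio)
        bv = background_variability(st.sd_background, st.c_background)
        rows.append(
            {
                "sphere_mm": st.diameter_mm,
                "CR": cr,
                "BV": bv,
                "CNR": cnr(cr, bv),
            }
        )
    table = pd.DataFrame(rows)
    table.insert(0, "arm", arm)
    return IQResult(arm=arm, table=table)


def liver_snr(
    volume: ImageVolume,
    voi_center_mm: Sequence[float],
    voi_diameter_mm: float = 30.0,
) -> LiverNoiseResult:
    """Noise summary over a 30 mm spherical VOI in a uniform region.

    SNR = mean(VOI)/SD(VOI).  Raises if the VOI clips the volume bounds or
    the region is noiseless (SD = 0).
    """
    r = voi_diameter_mm / 2.0
    for i in range(3):
        lo = volume.origin_mm[i]
        hi = volume.origin_mm[i] + volume.voxel_size_mm * (volume.data.shape[i] - 1)
        if voi_center_mm[i] - r < lo or voi_center_mm[i] + r > hi:
            raise MetricError("liver VOI clipped by the volume bounds")
    mask = _sphere_mask(volume, voi_center_mm, voi_diameter_mm)
    vals = volume.data[mask]
    if vals.size == 0:
        raise MetricError("empty liver VOI")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise MetricError("SNR undefined: zero VOI standard deviation")
    return LiverNoiseResult(
        voi_mean=mean, voi_sd=sd, snr=mean / sd, voi_diameter_mm=voi_diameter_mm
    )


def suv_max(volume: ImageVolume, voi_mask: np.ndarray) -> float:
    """Maximum voxel value within a lesion VOI (activity-relative units).

    No dose/weight normalisation is applied: the simulator works in relative
    activity, so this is the SUVmax analogue up to a constant.
    """
    if voi_mask.shape != volume.data.shape:
        raise MetricError("VOI mask shape does not match the volume")
    if not voi_mask.any():
        raise MetricError("empty lesion VOI")
    return float(volume.data[voi_mask].max())


def sphere_voi_mask(volume: ImageVolume, spec: PhantomSpec, sphere_id: int) -> np.ndarray:
    """Spherical VOI covering one hot sphere (for SUVmax extraction)."""
    if not 0 <= sphere_id < len(spec.sphere_diameters_mm):
        raise MetricError("sphere_id out of range")
    return _sphere_mask(
        volume, spec.sphere_centers[sphere_id], spec.sphere_diameters_mm[sphere_id]
    )
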