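"""Motion-blurred NEMA-IQ-style phantom synthesis.

The phantom is a simplified image-quality body: a cylindrical warm
background holding a coplanar ring of six hot spheres (10-37 mm diameter,
4:1 contrast), imaged with an isotropic Gaussian PSF.  Respiratory motion
is modelled in image space: the residual displacement distribution of the
retained (gated or ungated) data becomes a 1-D blur kernel along the motion
axis, and count statistics are emulated by Poisson resampling at an
arm-specific count budget.  Reconstruction-algorithm differences (BSREM vs
OSEM vs deep-learning enhancement) are deliberately NOT modelled: arms
differ only in count budget, gating, and optional post-smoothing, so the
six study reconstructions map onto four physically distinguishable arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter

from .gating import GateMask
from .listmode import EventStream
from .waveform import RespiratoryTrace

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_AXES = {"x": 0, "y": 1, "z": 2}


class PhantomError(ValueError):
    """Inconsistent phantom geometry or simulation inputs."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of the simulated IQ phantom.

    All lengths in mm.  ``sphere_ring_radius_mm`` places the six sphere
    centres on a circle in the central plane; ``background_roi_ring_mm``
    is where the NEMA-style background ROIs are drawn, clear of the spheres
    and the body edge.
    """

    sphere_diameters_mm: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    contrast_ratio: float = 4.0
    background_activity: float = 1.0
    body_radius_mm: float = 150.0
    body_length_mm: float = 160.0
    voxel_size_mm: float = 2.7
    psf_fwhm_mm: float = 5.0
    motion_axis: str = "z"
    sphere_ring_radius_mm: float = 57.2
    background_roi_ring_mm: float = 112.0
    n_background_rois: int = 12
    clearance_mm: float = 15.0
    #: extra grid extent (mm) so motion blur does not push activity off-grid
    grid_margin_mm: float = 20.0

    def __post_init__(self) -> None:
        d = np.asarray(self.sphere_diameters_mm, dtype=float)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise PhantomError("sphere diameters must be positive and ascending")
        if self.contrast_ratio <= 1:
            raise PhantomError("contrast_ratio must exceed 1")
        if self.voxel_size_mm <= 0 or self.body_radius_mm <= 0 or self.body_length_mm <= 0:
            raise PhantomError("geometry lengths must be positive")
        if self.motion_axis not in _AXES:
            raise PhantomError("motion_axis must be one of 'x', 'y', 'z'")
        if self.voxel_size_mm > d[0] / 2.0:
            raise PhantomError("voxel larger than the smallest sphere radius")
        max_r = d[-1] / 2.0
        if self.sphere_ring_radius_mm + max_r + self.clearance_mm > self.body_radius_mm:
            raise PhantomError("spheres (plus margin) do not fit inside the body")

    @property
    def sphere_centers(self) -> np.ndarray:
        """(n, 3) sphere centres in mm: a ring in the z=0 plane."""
        n = len(self.sphere_diameters_mm)
        angles = 2.0 * np.pi * np.arange(n) / n
        return np.column_stack(
            [
                self.sphere_ring_radius_mm * np.cos(angles),
                self.sphere_ring_radius_mm * np.sin(angles),
                np.zeros(n),
            ]
        )

    @property
    def background_roi_centers(self) -> np.ndarray:
        """(m, 3) background ROI centres, offset 15 deg from the sphere ring."""
        m = self.n_background_rois
        angles = 2.0 * np.pi * np.arange(m) / m + np.deg2rad(15.0)
        return np.column_stack(
            [
                self.background_roi_ring_mm * np.cos(angles),
                self.background_roi_ring_mm * np.sin(angles),
                np.zeros(m),
            ]
        )


@dataclass(frozen=True)
class ImageVolume:
    """Voxel grid of activity values with isotropic voxel size, origin-centred."""

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise PhantomError("volume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise PhantomError("volume contains non-finite values")

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-centre coordinate arrays in mm."""
        ax = []
        for i, n in enumerate(self.data.shape):
            ax.append(self.origin_mm[i] + self.voxel_size_mm * np.arange(n))
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def total_activity(self) -> float:
        return float(self.data.sum())


@dataclass(frozen=True)
class DisplacementPdf:
    """Normalised histogram of residual axial displacement (mm)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise PhantomError("edges must be one longer than probabilities")
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-6:
            raise PhantomError("displacement pdf must be normalised within 1e-6")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.probabilities))

    @property
    def sd(self) -> float:
        c = self.bin_centers - self.mean
        return float(np.sqrt(np.sum(c**2 * self.probabilities)))


@dataclass(frozen=True)
class ReconArmSpec:
    """One reconstruction arm: count budget, gating choice, optional smoothing.

    ``count_budget`` is relative to the 6-min gold standard (1.0);
    ``gating`` is None (ungated), ``"method1"`` or ``"method2"``;
    ``counts_per_unit`` sets the Poisson scale (None = noiseless);
    ``post_smooth_fwhm_mm`` emulates denoising post-filters.
    """

    label: str
    count_budget: float = 1.0
    gating: Optional[str] = None
    counts_per_unit: Optional[float] = 100.0
    post_smooth_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.count_budget <= 0:
            raise PhantomError("count_budget must be positive")
        if self.gating not in (None, "method1", "method2"):
            raise PhantomError("gating must be None, 'method1' or 'method2'")

    def noise_scale(self, retained_fraction: float = 1.0) -> float:
        """Relative noise magnification, 1/sqrt(budget x retained fraction)."""
        return 1.0 / np.sqrt(self.count_budget * retained_fraction)


def six_study_arms(counts_per_unit: Optional[float] = 100.0) -> list[ReconArmSpec]:
    """The study's six reconstruction arms as count/gating/smoothing budgets.

    Ungated 6 min (gold standard), ungated 3 min (clinical standard), both
    gating methods at full acquisition (half the counts survive the gate),
    and both gating methods with an additional denoising smooth standing in
    for the deep-learning enhancement.
    """
    return [
        ReconArmSpec("ungated_6min", 1.0, None, counts_per_unit),
        ReconArmSpec("ungated_3min", 0.5, None, counts_per_unit),
        ReconArmSpec("method1_gated", 1.0, "method1", counts_per_unit),
        ReconArmSpec("method2_gated", 1.0, "method2", counts_per_unit),
        ReconArmSpec("method1_gated_smoothed", 1.0, "method1", counts_per_unit, 4.0),
        ReconArmSpec("method2_gated_smoothed", 1.0, "method2", counts_per_unit, 4.0),
    ]


def _grid_axes(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    v = spec.voxel_size_mm
    n_xy = 2 * int(np.ceil(spec.body_radius_mm / v)) + 3
    n_z = 2 * int(np.ceil((0.5 * spec.body_length_mm + spec.grid_margin_mm) / v)) + 3
    return (
        v * (np.arange(n_xy) - (n_xy - 1) / 2),
        v * (np.arange(n_xy) - (n_xy - 1) / 2),
        v * (np.arange(n_z) - (n_z - 1) / 2),
    )


def build_static_phantom(spec: PhantomSpec) -> ImageVolume:
    """Noiseless, motion-free phantom volume.

    Voxels inside a sphere take ``contrast_ratio x background_activity``,
    body voxels ``background_activity``, air 0; the result is then blurred
    with the isotropic Gaussian PSF (``psf_fwhm_mm``).
    """
    xs, ys, zs = _grid_axes(spec)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    data = np.zeros((len(xs), len(ys), len(zs)))
    body = (x**2 + y**2 <= spec.body_radius_mm**2) & (
        np.abs(z) <= spec.body_length_mm / 2.0
    )
    data[body] = spec.background_activity
    hot = spec.contrast_ratio * spec.background_activity
    for (cx, cy, cz), d in zip(spec.sphere_centers, spec.sphere_diameters_mm):
        r = d / 2.0
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        data[inside] = hot
    if spec.psf_fwhm_mm > 0:
        sigma = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_size_mm
        data = gaussian_filter(data, sigma=sigma, mode="constant")
    origin = (float(xs[0]), float(ys[0]), float(zs[0]))
    return ImageVolume(
        data=data,
        voxel_size_mm=spec.voxel_size_mm,
        origin_mm=origin,
        meta={"stage": "static", "psf_fwhm_mm": spec.psf_fwhm_mm},
    )


def residual_displacement_pdf(
    trace: RespiratoryTrace,
    gate_mask: Optional[GateMask] = None,
    bin_width_mm: Optional[float] = None,
    voxel_size_mm: float = 2.7,
) -> DisplacementPdf:
    """Distribution of trace displacement over the retained samples.

    With no gate every sample contributes; with a gate, only samples inside
    the retained windows.  The histogram bin width defaults to half a voxel.
    The spread of this pdf is the residual motion that blurs the image.
    """
    if bin_width_mm is None:
        bin_width_mm = voxel_size_mm / 2.0
    if gate_mask is None:
        amps = trace.amplitudes
    else:
        if not gate_mask.windows:
            raise PhantomError("gate mask retains no samples")
        edges = np.ravel([(w.t0, w.t1) for w in gate_mask.windows])
        pos = np.searchsorted(edges, trace.times, side="right")
        amps = trace.amplitudes[pos % 2 == 1]
    if len(amps) == 0:
        raise PhantomError("no retained samples: displacement pdf undefined")
    lo = float(amps.min()) - bin_width_mm / 2.0
    n_bins = max(1, int(np.ceil((float(amps.max()) + bin_width_mm / 2.0 - lo) / bin_width_mm)))
    bin_edges = lo + bin_width_mm * np.arange(n_bins + 1)
    counts, _ = np.histogram(amps, bins=bin_edges)
    return DisplacementPdf(bin_edges=bin_edges, probabilities=counts / counts.sum())


def apply_motion_blur(
    volume: ImageVolume, pdf: DisplacementPdf, motion_axis: str = "z"
) -> ImageVolume:
    """Convolve the volume along the motion axis with the displacement pdf.

    The kernel is mean-subtracted so gating changes blur width but not the
    image position (image registration/alignment is out of scope).  Activity
    of interior structures is conserved.
    """
    if motion_axis not in _AXES:
        raise PhantomError("motion_axis must be one of 'x', 'y', 'z'")
    v = volume.voxel_size_mm
    offsets = (pdf.bin_centers - pdf.mean) / v  # voxel units, mean-zero
    max_off = int(np.ceil(np.max(np.abs(offsets)))) + 1 if len(offsets) else 1
    kernel = np.zeros(2 * max_off + 1)
    # distribute each bin's mass linearly between the two bracketing shifts
    for off, p in zip(offsets, pdf.probabilities):
        low = int(np.floor(off))
        frac = off - low
        kernel[low + max_off] += p * (1.0 - frac)
        kernel[low + 1 + max_off] += p * frac
    kernel = kernel / kernel.sum()
    data = convolve1d(volume.data, kernel, axis=_AXES[motion_axis], mode="constant")
    meta = dict(volume.meta)
    meta.update({"stage": "motion_blurred", "residual_sd_mm": pdf.sd})
    return ImageVolume(data=data, voxel_size_mm=v, origin_mm=volume.origin_mm, meta=meta)


def apply_count_noise(
    volume: ImageVolume,
    arm: ReconArmSpec,
    seed: int = 0,
    retained_fraction: float = 1.0,
) -> ImageVolume:
    """Poisson count noise at the arm's effective count level.

    Voxel activities are scaled to expected counts
    ``value x budget x retained_fraction x counts_per_unit``, Poisson
    sampled, and rescaled back to activity units (unbiased).  With
    ``counts_per_unit=None`` the volume is returned unchanged (noiseless
    limit).
    """
    if arm.counts_per_unit is None:
        return volume
    scale = arm.count_budget * retained_fraction * arm.counts_per_unit
    if scale <= 0:
        raise PhantomError("non-positive count scale")
    rng = np.random.default_rng(seed)
    expected = np.clip(volume.data, 0.0, None) * scale
    noisy = rng.poisson(expected).astype(float) / scale
    meta = dict(volume.meta)
    meta.update({"stage": "noisy", "count_scale": scale, "arm": arm.label})
    return ImageVolume(
        data=noisy, voxel_size_mm=volume.voxel_size_mm, origin_mm=volume.origin_mm, meta=meta
    )


def simulate_arm(
    spec: PhantomSpec,
    trace: RespiratoryTrace,
    events: EventStream,
    arm: ReconArmSpec,
    gate_mask: Optional[GateMask] = None,
    seed: int = 0,
    static: Optional[ImageVolume] = None,
) -> ImageVolume:
    """Full pipeline for one reconstruction arm.

    static phantom -> residual displacement pdf (per the arm's gate) ->
    motion blur -> Poisson count noise -> optional post-smoothing.  Pass a
    prebuilt ``static`` volume to amortise the geometry stage across arms.
    """
    if arm.gating is not None and gate_mask is None:
        raise PhantomError(f"arm '{arm.label}' requires a gate mask")
    if static is None:
        static = build_static_phantom(spec)
    mask = gate_mask if arm.gating is not None else None
    pdf = residual_displacement_pdf(trace, mask, voxel_size_mm=spec.voxel_size_mm)
    blurred = apply_motion_blur(static, pdf, spec.motion_axis)
    retained = mask.retained_fraction if mask is not None else 1.0
    out = apply_count_noise(blurred, arm, seed=seed, retained_fraction=retained)
    if arm.post_smooth_fwhm_mm > 0:
        sigma = arm.post_smooth_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_size_mm
        out = ImageVolume(
            data=gaussian_filter(out.data, sigma=sigma, mode="constant"),
            voxel_size_mm=out.voxel_size_mm,
            origin_mm=out.origin_mm,
            meta=dict(out.meta),
        )
    meta = dict(out.meta)
    meta.update(
        {
            "arm": arm.label,
            "gating": arm.gating,
            "count_budget": arm.count_budget,
            "retained_fraction": retained,
            "seed": seed,
        }
    )
    return ImageVolume(
        data=out.data, voxel_size_mm=out.voxel_size_mm, origin_mm=out.origin_mm, meta=meta
    )


def save_nifti(volume: ImageVolume, path: Union[str, Path]) -> None:
    """Write a volume as NIfTI with a diagonal mm affine."""
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def load_nifti(path: Union[str, Path]) -> ImageVolume:
    """Read a volume written by :func:`save_nifti`."""
    img = nib.load(str(path))
    affine = img.affine
    return ImageVolume(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size_mm=float(affine[0, 0]),
        origin_mm=tuple(float(v) for v in affine[:3, 3]),
    )
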