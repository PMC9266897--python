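"""Preprocessing of measured or synthetic CEST data.

Covers reference normalization of raw saturation frames, WASSR-based B0
offset mapping and spectral shift correction, optional non-local-means
denoising of image frames, and voxelwise T1 (inversion-recovery) and T2
(spin-echo) relaxometry.  All per-voxel operations are pure maps: the
result for one voxel never depends on any other voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from skimage.restoration import denoise_nl_means

__all__ = [
    "ZStack",
    "B0Map",
    "RelaxMaps",
    "normalize_reference",
    "wassr_b0_map",
    "correct_b0",
    "nlm_denoise",
    "fit_t1_ir",
    "fit_t2_se",
]


@dataclass
class ZStack:
    """Z-spectra indexed (voxel..., B1 level, offset).

    Sample-mode data has shape ``(n_B1, n_offsets)``; map-mode stacks carry
    leading voxel dimensions.  The offset axis is kept strictly ascending.
    """

    Z: np.ndarray
    offsets_ppm: np.ndarray
    B1_uT: np.ndarray
    normalized: bool = False
    flags: np.ndarray | None = None  # True where a voxel is unreliable

    def __post_init__(self):
        self.Z = np.asarray(self.Z, float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, float)
        self.B1_uT = np.atleast_1d(np.asarray(self.B1_uT, float))
        if self.Z.shape[-1] != self.offsets_ppm.size:
            raise ValueError("last axis of Z must match offsets")
        if self.Z.ndim < 2 or self.Z.shape[-2] != self.B1_uT.size:
            raise ValueError("second-to-last axis of Z must match B1 levels")
        order = np.argsort(self.offsets_ppm, kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            self.offsets_ppm = self.offsets_ppm[order]
            self.Z = self.Z[..., order]

    @property
    def voxel_shape(self) -> tuple:
        return self.Z.shape[:-2]

    def spectrum(self, b1_index: int, voxel: tuple = ()) -> tuple[np.ndarray, np.ndarray]:
        """(offsets, Z) for one B1 level of one voxel/sample."""
        return self.offsets_ppm, self.Z[voxel + (b1_index,)]


@dataclass
class B0Map:
    """Per-voxel water frequency shift in ppm from a WASSR sweep."""

    shift_ppm: np.ndarray
    unreliable: np.ndarray  # True where the minimum sat on the sweep boundary


@dataclass
class RelaxMaps:
    """Voxelwise relaxometry results."""

    T1_s: np.ndarray | None = None
    T2_s: np.ndarray | None = None
    S0: np.ndarray | None = None
    residual: np.ndarray | None = None
    failed: np.ndarray | None = None


def normalize_reference(
    stack: ZStack,
    reference_offset_ppm: float = 300.0,
    mask: np.ndarray | None = None,
) -> ZStack:
    """Divide by the far off-resonance reference frame and drop it.

    Voxels whose reference signal is not strictly positive (inside the mask,
    if given) are flagged rather than propagated as infinities.
    """
    offs = stack.offsets_ppm
    ref_idx = np.where(np.isclose(offs, reference_offset_ppm))[0]
    if ref_idx.size != 1:
        raise ValueError(
            f"stack must contain exactly one frame at {reference_offset_ppm} ppm"
        )
    ref_idx = int(ref_idx[0])
    keep = np.arange(offs.size) != ref_idx
    ref = stack.Z[..., ref_idx]
    bad = ~(ref > 0)
    if mask is not None:
        bad &= np.broadcast_to(mask[..., None], bad.shape)
    safe_ref = np.where(bad, 1.0, ref)
    Z = stack.Z[..., keep] / safe_ref[..., None]
    Z[np.broadcast_to(bad[..., None], Z.shape)] = np.nan
    flags = np.any(bad, axis=-1) if bad.ndim > 0 else bad
    return ZStack(Z, offs[keep], stack.B1_uT, normalized=True, flags=flags)


def wassr_b0_map(wassr: ZStack, grid_step_ppm: float = 0.001) -> B0Map:
    """Locate the direct-saturation minimum of each WASSR spectrum.

    A cubic spline through the sweep is minimized on a fine grid
    (default 0.001 ppm); the argmin is the voxel's B0 shift.  Minima on the
    sweep boundary are marked unreliable.
    """
    offs = wassr.offsets_ppm
    if offs.size < 8:
        raise ValueError("WASSR sweep needs at least 8 offsets")
    grid = np.arange(offs[0], offs[-1] + grid_step_ppm / 2, grid_step_ppm)
    # WASSR is acquired at one (low) B1; average levels if more were given.
    spectra = wassr.Z.mean(axis=-2)
    flat = spectra.reshape(-1, offs.size)
    shifts = np.empty(flat.shape[0])
    unreliable = np.zeros(flat.shape[0], bool)
    for i, y in enumerate(flat):
        spline = CubicSpline(offs, y)
        vals = spline(grid)
        j = int(np.argmin(vals))
        shifts[i] = grid[j]
        unreliable[i] = j == 0 or j == grid.size - 1
    shape = wassr.voxel_shape
    return B0Map(shifts.reshape(shape), unreliable.reshape(shape))


def correct_b0(stack: ZStack, b0: B0Map) -> ZStack:
    """Re-interpolate every spectrum onto the nominal offsets after removing
    its B0 shift.

    A spectrum acquired with shift ``s`` has its true frequency axis at
    ``nominal - s``; the corrected value at nominal offset ``d`` is the
    measured spectrum interpolated at ``d + s``.  End offsets are held at
    the edge value (no extrapolation) and voxels flagged unreliable by the
    B0 map pass through unchanged.
    """
    if not stack.normalized:
        raise ValueError("normalize the stack before B0 correction")
    offs = stack.offsets_ppm
    shifts = np.atleast_1d(np.asarray(b0.shift_ppm, float))
    unreliable = np.atleast_1d(np.asarray(b0.unreliable, bool))
    if shifts.shape != stack.voxel_shape and stack.voxel_shape != ():
        raise ValueError("B0 map shape must match the stack voxel shape")
    Z = np.array(stack.Z, copy=True)
    flat = Z.reshape(-1, stack.B1_uT.size, offs.size)
    fshift = shifts.reshape(-1)
    fbad = unreliable.reshape(-1)
    for v in range(flat.shape[0]):
        if fbad[v] or fshift[v] == 0.0:
            continue
        for b in range(flat.shape[1]):
            flat[v, b] = np.interp(offs + fshift[v], offs, flat[v, b])
    return replace(stack, Z=flat.reshape(stack.Z.shape), flags=unreliable)


def nlm_denoise(
    images: np.ndarray,
    patch_radius: int = 1,
    search_radius: int = 5,
    strength: float | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Non-local-means denoising of a frame or stack of 2D frames.

    ``strength`` is the filtering parameter h; when omitted it defaults to
    0.8 * sigma with sigma estimated by scikit-image unless given.  With
    ``strength=0`` the filter is the identity.
    """
    from skimage.restoration import estimate_sigma

    arr = np.asarray(images, float)
    frames = arr.reshape(-1, *arr.shape[-2:])
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        s = sigma if sigma is not None else float(estimate_sigma(frame))
        h = strength if strength is not None else 0.8 * s
        if h <= 0:
            out[i] = frame
            continue
        out[i] = denoise_nl_means(
            frame,
            patch_size=2 * patch_radius + 1,
            patch_distance=search_radius,
            h=h,
            sigma=s,
            fast_mode=True,
        )
    return out.reshape(arr.shape)


def _ir_signed(TI, S0, T1):
    return S0 * (1.0 - 2.0 * np.exp(-TI / T1))


def fit_t1_ir(
    signals,
    TIs_s,
    magnitude: bool = True,
) -> tuple[float, float, float]:
    """T1 from an inversion-recovery series, ``S(TI) = S0 (1 - 2 e^(-TI/T1))``.

    With ``magnitude=True`` (clinical magnitude images) the polarity of the
    early points is restored by trying every zero-crossing position and
    keeping the best signed fit.  Returns ``(T1_s, S0, rms_residual)``.
    """
    s = np.asarray(signals, float)
    TI = np.asarray(TIs_s, float)
    if s.size < 3:
        raise ValueError("need at least 3 inversion times")
    order = np.argsort(TI)
    TI, s = TI[order], s[order]
    S0_guess = float(np.max(np.abs(s)))
    T1_guess = float(np.median(TI)) or 1.0
    candidates = range(s.size + 1) if magnitude else [0]
    best = None
    for ncross in candidates:
        signed = s.copy()
        signed[:ncross] *= -1.0
        try:
            popt, _ = curve_fit(
                _ir_signed,
                TI,
                signed,
                p0=(S0_guess, T1_guess),
                bounds=([0.0, 1e-6], [np.inf, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean((signed - _ir_signed(TI, *popt)) ** 2)))
        if best is None or resid < best[2]:
            best = (float(popt[1]), float(popt[0]), resid)
    if best is None:
        raise ArithmeticError("inversion-recovery fit did not converge")
    T1, S0, resid = best
    return T1, S0, resid


def fit_t2_se(signals, TEs_s) -> tuple[float, float, float]:
    """T2 from a spin-echo decay series, ``S(TE) = S0 exp(-TE/T2)``.

    Seeded by the log-linear regression of the positive samples; returns
    ``(T2_s, S0, rms_residual)``.
    """
    s = np.asarray(signals, float)
    TE = np.asarray(TEs_s, float)
    if s.size < 3:
        raise ValueError("need at least 3 echo times")
    pos = s > 0
    if pos.sum() >= 2:
        slope, icpt = np.polyfit(TE[pos], np.log(s[pos]), 1)
        T2_guess = -1.0 / slope if slope < 0 else float(np.median(TE))
        S0_guess = float(np.exp(icpt))
    else:
        T2_guess, S0_guess = float(np.median(TE)), float(np.max(np.abs(s)))
    popt, _ = curve_fit(
        lambda TE, S0, T2: S0 * np.exp(-TE / T2),
        TE,
        s,
        p0=(S0_guess, max(T2_guess, 1e-6)),
        bounds=([0.0, 1e-6], [np.inf, np.inf]),
        maxfev=5000,
    )
    resid = float(np.sqrt(np.mean((s - popt[0] * np.exp(-TE / popt[1])) ** 2)))
    return float(popt[1]), float(popt[0]), resid
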