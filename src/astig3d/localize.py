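"""Spot detection, elliptical-Gaussian fitting and z assignment.

Each candidate focus is fitted with
``I(x, y) = B + A exp(-(x-x0)^2 / 2 sigma_x^2 - (y-y0)^2 / 2 sigma_y^2)``
over a local window, yielding a sub-pixel centroid with independent widths.
The width ratio sigma_x/sigma_y is converted to axial position through a
:class:`~astig3d.calibration.CalibrationCurve`; foci whose ratio falls
outside the invertible range are kept as 2D-only localizations.

Coordinates are 0-based with origin at the image's top-left corner and
x = column; the nm position of the centre of pixel column j is
(j + 0.5) * pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

from .calibration import CalibrationCurve, CalibrationRangeError

__all__ = [
    "Focus",
    "detect_candidates",
    "fit_gaussian_2d",
    "localization_precision",
    "assign_z",
    "localize_frame",
    "localize_stack",
]


@dataclass(frozen=True)
class Focus:
    """One fitted fluorescent focus."""

    frame: int
    x_nm: float
    y_nm: float
    sigma_x_nm: float
    sigma_y_nm: float
    intensity: float            # background-corrected integrated counts
    background: float           # local mean counts
    snr: float
    precision_xy_nm: float = float("nan")
    precision_x_nm: float = float("nan")
    precision_y_nm: float = float("nan")
    precision_z_nm: float = float("nan")
    z_nm: float | None = None
    z_ci_nm: float | None = None
    sigma_err_x_nm: float = float("nan")
    sigma_err_y_nm: float = float("nan")
    sigma_cov_xy_nm2: float = float("nan")
    flag: str = "ok"

    @property
    def ratio(self) -> float:
        return self.sigma_x_nm / self.sigma_y_nm

    @property
    def position_nm(self) -> np.ndarray:
        z = np.nan if self.z_nm is None else self.z_nm
        return np.array([self.x_nm, self.y_nm, z])


def robust_noise_sd(frame: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    med = np.median(frame)
    return 1.4826 * float(np.median(np.abs(frame - med)))


def detect_candidates(
    frame: np.ndarray,
    k: float = 5.0,
    min_separation_px: int = 4,
) -> list[tuple[int, int]]:
    """Find candidate foci as local maxima above background + k robust sd.

    Background is the frame median and the noise scale is MAD-based, so
    sparse bright spots do not perturb the threshold.  Maxima closer than
    ``min_separation_px`` (about one PSF width) are merged into the
    brightest one.  Returns (row, col) seeds; an empty list is valid.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite-valued")
    bg = float(np.median(frame))
    noise = robust_noise_sd(frame)
    thresh = bg + k * max(noise, 1e-12)
    peaks = peak_local_max(frame, min_distance=min_separation_px,
                           threshold_abs=thresh, exclude_border=False)
    return [tuple(p) for p in peaks]


def _gauss_model(params, cols, rows):
    """Pixel-integrated elliptical Gaussian: B plus N times the fraction of
    a unit Gaussian at (x0, y0) falling in each pixel (pixel j spans
    [j-0.5, j+0.5] in pixel-centre coordinates), matching the camera's
    integration over pixel area."""
    b, n, x0, y0, sx, sy = params
    fx = 0.5 * (erf((cols + 0.5 - x0) / (np.sqrt(2) * sx))
                - erf((cols - 0.5 - x0) / (np.sqrt(2) * sx)))
    fy = 0.5 * (erf((rows + 0.5 - y0) / (np.sqrt(2) * sy))
                - erf((rows - 0.5 - y0) / (np.sqrt(2) * sy)))
    return b + n * np.outer(fy, fx)


def fit_gaussian_2d(
    frame: np.ndarray,
    seed_rc: tuple[int, int],
    window: int = 16,
    pixel_size_nm: float = 93.0,
    frame_index: int = 0,
    max_sigma_px: float | None = None,
) -> Focus:
    """Fit an elliptical 2D Gaussian around a candidate pixel.

    Nonlinear least squares over a ``window`` x ``window`` region (truncated
    and flagged at frame edges).  The model is the elliptical Gaussian
    ``B + A exp(-(x-x0)^2/2 sigma_x^2 - (y-y0)^2/2 sigma_y^2)`` integrated
    over each pixel's area; the fitted scale is directly the integrated
    intensity (2 pi A sigma_x sigma_y) in counts.  Per-parameter
    uncertainties come from the Jacobian at the solution and feed the axial
    error model downstream.  Non-convergent fits or widths pinned at the
    bounds are returned with a rejection flag.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    r0 = int(seed_rc[0]) - window // 2
    c0 = int(seed_rc[1]) - window // 2
    flag = "ok"
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + window, h), min(c0 + window, w)
    if (rr0, cc0, rr1, cc1) != (r0, c0, r0 + window, c0 + window):
        flag = "window_truncated"
    sub = frame[rr0:rr1, cc0:cc1]
    rows = np.arange(rr0, rr1, dtype=float)
    cols = np.arange(cc0, cc1, dtype=float)

    b0 = float(np.median(sub))
    s0 = 1.8
    n0 = max((float(frame[seed_rc]) - b0) * 2 * np.pi * s0**2, 1e-3)
    if max_sigma_px is None:
        max_sigma_px = float(window)
    p0 = [b0, n0, float(seed_rc[1]), float(seed_rc[0]), s0, s0]
    lo = [-np.inf, 1e-6, cc0 - 1, rr0 - 1, 0.5, 0.5]
    hi = [np.inf, np.inf, cc1, rr1, max_sigma_px, max_sigma_px]

    def resid(p):
        return (_gauss_model(p, cols, rows) - sub).ravel()

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
    b, n_counts, x0, y0, sx, sy = sol.x
    if not sol.success:
        flag = "no_convergence"
    bound_tol = 1e-6
    if min(sx, sy) <= 0.5 + bound_tol or max(sx, sy) >= max_sigma_px - bound_tol:
        flag = "sigma_at_bounds"

    # parameter covariance from J'J, scaled by residual variance
    dof = max(sub.size - 6, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        err_sx, err_sy = np.sqrt(np.abs(np.diag(cov)[4:6]))
        cov_sxsy = cov[4, 5]
    except np.linalg.LinAlgError:
        err_sx = err_sy = cov_sxsy = np.nan

    noise = robust_noise_sd(frame)
    return Focus(
        frame=frame_index,
        x_nm=(x0 + 0.5) * pixel_size_nm,
        y_nm=(y0 + 0.5) * pixel_size_nm,
        sigma_x_nm=sx * pixel_size_nm,
        sigma_y_nm=sy * pixel_size_nm,
        intensity=n_counts,
        background=b,
        snr=n_counts / (2.0 * np.pi * sx * sy) / max(noise, 1e-12),
        sigma_err_x_nm=err_sx * pixel_size_nm,
        sigma_err_y_nm=err_sy * pixel_size_nm,
        sigma_cov_xy_nm2=cov_sxsy * pixel_size_nm**2,
        flag=flag,
    )


def localization_precision(
    n_photons: float,
    sigma_nm: float,
    pixel_size_nm: float = 93.0,
    background_sd_photons: float = 0.0,
) -> float:
    """Theoretical lateral localization precision (nm), Thompson form.

    sigma_loc^2 = s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)

    with s the mean fitted PSF width, a the pixel size, N the collected
    photon count and b the background noise sd in photons per pixel.
    """
    if n_photons <= 0:
        raise ValueError("photon count must be positive")
    s, a, n, b = sigma_nm, pixel_size_nm, n_photons, background_sd_photons
    var = s**2 / n + a**2 / (12.0 * n) + 8.0 * np.pi * s**4 * b**2 / (a**2 * n**2)
    return float(np.sqrt(var))


def focus_precision(focus: Focus, camera_gain: float = 1.0,
                    pixel_size_nm: float = 93.0, axis: str = "mean") -> float:
    """Per-focus lateral precision from its fitted intensity and widths.

    ``axis`` selects the PSF width entering the photon-count formula:
    ``"x"`` or ``"y"`` for the per-axis precision of an elliptical spot,
    ``"mean"`` for the average width.
    """
    n = focus.intensity / camera_gain
    s = {"x": focus.sigma_x_nm, "y": focus.sigma_y_nm,
         "mean": 0.5 * (focus.sigma_x_nm + focus.sigma_y_nm)}[axis]
    b = np.sqrt(max(focus.background, 0.0)) / camera_gain
    return localization_precision(n, s, pixel_size_nm, b)


def axial_precision(focus: Focus, curve: CalibrationCurve) -> float:
    """1-sigma axial measurement error (nm) from the width-fit covariance.

    The measured ratio's sd (first-order propagation of the per-focus width
    variances and their covariance) is divided by the local slope |dr/dz|
    of the calibration.
    """
    if focus.z_nm is None:
        return np.nan
    r = focus.ratio
    rel_var = (focus.sigma_err_x_nm**2 / focus.sigma_x_nm**2
               + focus.sigma_err_y_nm**2 / focus.sigma_y_nm**2)
    if np.isfinite(focus.sigma_cov_xy_nm2):
        rel_var -= (2.0 * focus.sigma_cov_xy_nm2
                    / (focus.sigma_x_nm * focus.sigma_y_nm))
    sd_r = r * np.sqrt(max(rel_var, 0.0))
    a, b, _ = curve.coeffs_ratio
    drdz = 2 * a * (focus.z_nm / 1000.0) + b
    return 1000.0 * sd_r / abs(drdz)


def assign_z(focus: Focus, curve: CalibrationCurve) -> Focus:
    """Attach an axial position (nm) inverted from the width ratio.

    Foci whose ratio lies outside the attainable range of the calibration
    are returned unchanged except for a ``2d_only`` flag.
    """
    try:
        z_um, ci_um = curve.ratio_to_z(focus.ratio)
    except CalibrationRangeError:
        return replace(focus, flag="2d_only")
    return replace(focus, z_nm=1000.0 * z_um, z_ci_nm=1000.0 * ci_um)


def localize_frame(
    frame: np.ndarray,
    frame_index: int = 0,
    curve: CalibrationCurve | None = None,
    pixel_size_nm: float = 93.0,
    k: float = 5.0,
    window: int = 16,
    min_snr: float = 2.0,
    min_separation_px: int = 4,
) -> list[Focus]:
    """Detect and fit all foci in one frame; optionally assign z.

    Candidates closer than two mean fitted widths after fitting are treated
    as overlapping and flagged rather than modelled as multi-emitter fits.
    """
    seeds = detect_candidates(frame, k=k,
                              min_separation_px=min_separation_px)
    foci = [fit_gaussian_2d(frame, s, window=window,
                            pixel_size_nm=pixel_size_nm,
                            frame_index=frame_index) for s in seeds]
    # flag overlapping pairs (closer than 2x mean width)
    for i in range(len(foci)):
        for j in range(i + 1, len(foci)):
            fi, fj = foci[i], foci[j]
            d = np.hypot(fi.x_nm - fj.x_nm, fi.y_nm - fj.y_nm)
            lim = (fi.sigma_x_nm + fi.sigma_y_nm
                   + fj.sigma_x_nm + fj.sigma_y_nm) / 2.0
            if d < lim:
                foci[i] = replace(fi, flag="overlap")
                foci[j] = replace(fj, flag="overlap")
    out = []
    for f in foci:
        if f.flag in ("no_convergence", "sigma_at_bounds", "overlap"):
            continue
        if f.snr < min_snr or f.intensity <= 0:
            continue
        f = replace(
            f,
            precision_xy_nm=focus_precision(f, pixel_size_nm=pixel_size_nm),
            precision_x_nm=focus_precision(f, pixel_size_nm=pixel_size_nm,
                                           axis="x"),
            precision_y_nm=focus_precision(f, pixel_size_nm=pixel_size_nm,
                                           axis="y"))
        if curve is not None:
            f = assign_z(f, curve)
            if f.z_nm is not None:
                f = replace(f, precision_z_nm=axial_precision(f, curve))
        out.append(f)
    return out


FOCI_COLUMNS = ["frame", "x_nm", "y_nm", "sigx_nm", "sigy_nm", "ratio",
                "z_nm", "z_ci_nm", "intensity", "background", "snr",
                "precision_xy_nm", "precision_x_nm", "precision_y_nm",
                "precision_z_nm", "flag"]


def localize_stack(
    stack: np.ndarray,
    curve: CalibrationCurve | None = None,
    pixel_size_nm: float = 93.0,
    k: float = 5.0,
    window: int = 16,
    min_snr: float = 2.0,
) -> pd.DataFrame:
    """Localize every frame of a movie into a tidy foci table."""
    rows = []
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    for i, frame in enumerate(stack):
        for f in localize_frame(frame, i, curve=curve,
                                pixel_size_nm=pixel_size_nm, k=k,
                                window=window, min_snr=min_snr):
            rows.append({
                "frame": f.frame, "x_nm": f.x_nm, "y_nm": f.y_nm,
                "sigx_nm": f.sigma_x_nm, "sigy_nm": f.sigma_y_nm,
                "ratio": f.ratio,
                "z_nm": np.nan if f.z_nm is None else f.z_nm,
                "z_ci_nm": np.nan if f.z_ci_nm is None else f.z_ci_nm,
                "intensity": f.intensity, "background": f.background,
                "snr": f.snr, "precision_xy_nm": f.precision_xy_nm,
                "precision_x_nm": f.precision_x_nm,
                "precision_y_nm": f.precision_y_nm,
                "precision_z_nm": f.precision_z_nm, "flag": f.flag,
            })
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


def measure_focus_levels(stacks_by_z, pixel_size_nm: float = 93.0,
                         k: float = 5.0, window: int = 16):
    """Summarize fitted widths of calibration bead/fluorophore stacks.

    ``stacks_by_z`` maps nominal axial offsets (um) to image stacks of
    immobilized emitters.  Every frame is localized in 2D; the accepted
    foci's widths are averaged into one
    :class:`~astig3d.calibration.FocusLevelSummary` per level, with
    standard errors of the means.  Levels with no accepted focus are
    dropped.
    """
    from .calibration import FocusLevelSummary

    levels = []
    for z_um in sorted(stacks_by_z):
        stack = np.asarray(stacks_by_z[z_um], dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
        sx, sy = [], []
        for i, frame in enumerate(stack):
            for f in localize_frame(frame, i, pixel_size_nm=pixel_size_nm,
                                    k=k, window=window):
                sx.append(f.sigma_x_nm)
                sy.append(f.sigma_y_nm)
        if not sx:
            continue
        n = len(sx)
        levels.append(FocusLevelSummary(
            z_um=float(z_um),
            mean_sigma_x=float(np.mean(sx)),
            mean_sigma_y=float(np.mean(sy)),
            se_sigma_x=float(np.std(sx, ddof=1) / np.sqrt(n)) if n > 1 else None,
            se_sigma_y=float(np.std(sy, ddof=1) / np.sqrt(n)) if n > 1 else None,
            n_spots=n))
    return levels
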