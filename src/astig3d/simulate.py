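"""Synthetic astigmatism movies with ground truth.

Generates 4D (x, y, z, t) Brownian trajectories, renders them as
z-dependent elliptical foci — either from an interpolated reference image
stack or from an analytic Gaussian model driven by a
:class:`~astig3d.calibration.CalibrationCurve` — and adds EMCCD-like noise:
a mean camera offset of 100 counts with Poisson-distributed noise at
93 nm/pixel magnification.  Also provides a simple two-channel cell/nucleus
image generator used to exercise the segmentation stage.

All simulator functions take an explicit seed (or Generator) so that the
same configuration reproduces bit-identical movies and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .calibration import CalibrationCurve

__all__ = [
    "CameraModel",
    "ReferenceStack",
    "Trajectory4D",
    "default_calibration",
    "build_reference_stack",
    "simulate_brownian_4d",
    "render_frames",
    "simulate_cell_image",
]

#: printed ratio-to-depth relation used as the simulator's ground truth
DEFAULT_RATIO_COEFFS = (2.4, 2.8, 1.2)
#: geometric-mean Gaussian width of the astigmatic PSF model (nm); chosen so
#: simulated spots reproduce the instrument's measured ~40 nm lateral and
#: 2-3x poorer axial precision at a single-GFP photon budget
DEFAULT_SIGMA0_NM = 250.0


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-like camera: counts = Poisson(photons * gain + offset).

    offset
        Mean dark-level in counts (default 100).
    pixel_size_nm
        Magnification at the sample, nm per pixel (default 93).
    counts_per_photon
        Effective gain converting expected photons to counts.
    """

    offset: float = 100.0
    pixel_size_nm: float = 93.0
    counts_per_photon: float = 1.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.pixel_size_nm <= 0 or self.counts_per_photon <= 0:
            raise ValueError("pixel size and gain must be positive")


@dataclass
class ReferenceStack:
    """Interpolated stack of mean foci images indexed by axial position (nm)."""

    images: np.ndarray          # (n_planes, h, w)
    z_values_nm: np.ndarray     # strictly increasing
    spacing_nm: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.z_values_nm = np.asarray(self.z_values_nm, dtype=float)
        if self.images.ndim != 3 or len(self.images) != len(self.z_values_nm):
            raise ValueError("one image per z value required")
        dz = np.diff(self.z_values_nm)
        if np.any(dz <= 0):
            raise ValueError("z_values must be strictly increasing")

    @property
    def z_span_nm(self) -> tuple[float, float]:
        return float(self.z_values_nm[0]), float(self.z_values_nm[-1])

    def nearest_plane(self, z_nm: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.z_values_nm - z_nm)))
        return self.images[idx]


@dataclass
class Trajectory4D:
    """One simulated molecule: positions (n, 3) in nm on a uniform time grid."""

    positions: np.ndarray
    times_ms: np.ndarray
    molecule_id: int
    photon_budget: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if len(self.times_ms) != len(self.positions):
            raise ValueError("times and positions must align")
        dt = np.diff(self.times_ms)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)


def default_calibration(sigma0_nm: float = DEFAULT_SIGMA0_NM,
                        z_range: tuple[float, float] = (-0.5, 0.5)
                        ) -> CalibrationCurve:
    """Ground-truth calibration used by the analytic PSF renderer.

    The ratio relation is the bench calibration r(z) = 2.4 z^2 + 2.8 z + 1.2
    (z in um).  Widths follow the constant-volume idealization
    sigma_x = sigma0 * sqrt(r), sigma_y = sigma0 / sqrt(r); the stored width
    polynomials are least-squares quadratics to those profiles, while
    rendering itself uses sigma_x = r(z) * sigma_y(z) so the rendered ratio
    matches r(z) identically.
    """
    a, b, c = DEFAULT_RATIO_COEFFS
    zg = np.linspace(z_range[0], z_range[1], 101)
    r = a * zg**2 + b * zg + c
    X = np.column_stack([zg**2, zg, np.ones_like(zg)])
    cx, *_ = np.linalg.lstsq(X, sigma0_nm * np.sqrt(r), rcond=None)
    cy, *_ = np.linalg.lstsq(X, sigma0_nm / np.sqrt(r), rcond=None)
    return CalibrationCurve(
        coeffs_ratio=np.array([a, b, c]), z_range=z_range,
        coeffs_sigma_x=cx, coeffs_sigma_y=cy)


def build_reference_stack(mean_images, z_values_nm,
                          spacing_nm: float = 93.0) -> ReferenceStack:
    """Linearly interpolate mean foci images onto a uniform axial grid.

    The measured mean images at each axial displacement are interpolated
    plane-by-plane at ``spacing_nm`` intervals (default one camera pixel,
    93 nm); the endpoint images are preserved exactly.
    """
    imgs = [np.asarray(im, dtype=float) for im in mean_images]
    if len(imgs) < 2:
        raise ValueError("need at least two mean images")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("mean images must share one shape")
    z = np.asarray(z_values_nm, dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError("z_values must be sorted strictly increasing")
    if spacing_nm <= 0:
        raise ValueError("spacing must be positive")
    n_out = int(np.floor((z[-1] - z[0]) / spacing_nm + 1e-9)) + 1
    z_out = z[0] + spacing_nm * np.arange(n_out)
    if z_out[-1] < z[-1] - 1e-9:
        z_out = np.append(z_out, z[-1])
    stack = np.stack(imgs)
    planes = np.empty((len(z_out),) + shape)
    idx = np.clip(np.searchsorted(z, z_out, side="right") - 1, 0, len(z) - 2)
    for k, (i, zq) in enumerate(zip(idx, z_out)):
        w = (zq - z[i]) / (z[i + 1] - z[i])
        planes[k] = (1 - w) * stack[i] + w * stack[i + 1]
    return ReferenceStack(images=planes, z_values_nm=z_out,
                          spacing_nm=float(spacing_nm))


def _as_box(box) -> np.ndarray:
    """Normalize a box spec to [[xmin,xmax],[ymin,ymax],[zmin,zmax]] (nm)."""
    arr = np.asarray(box, dtype=float)
    if arr.shape == (3,):
        arr = np.column_stack([np.zeros(3), arr])
    if arr.shape != (3, 2) or np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("box must be 3 extents or 3 (min, max) pairs in nm")
    return arr


def simulate_brownian_4d(
    D_um2_s: float,
    n_molecules: int,
    n_frames: int,
    dt_ms: float = 5.0,
    box=(6000.0, 6000.0, 1000.0),
    photon_budget: float = 1500.0,
    seed=None,
    bleach_mean_frames: float | None = None,
) -> list[Trajectory4D]:
    """Simulate isotropic Brownian trajectories on a uniform time grid.

    Displacements per axis and frame are i.i.d. N(0, 2 D dt); initial
    positions are uniform in ``box`` (nm).  Trajectories are not reflected
    at the box: molecules that wander out of the field or axial working
    range simply become undetectable downstream, like defocused molecules.
    With ``bleach_mean_frames`` set, each molecule's visible span is
    truncated at an exponentially distributed lifetime.
    """
    if D_um2_s < 0:
        raise ValueError("D must be >= 0")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if seed is None:
        raise ValueError("a seed (or numpy Generator) is required")
    rng = np.random.default_rng(seed)
    bounds = _as_box(box)
    # 1 um^2/s = 1000 nm^2/ms
    step_sd_nm = np.sqrt(2.0 * D_um2_s * 1000.0 * dt_ms)
    times = dt_ms * np.arange(n_frames)
    trajs = []
    for mid in range(n_molecules):
        n = n_frames
        if bleach_mean_frames is not None:
            n = max(2, min(n_frames,
                           int(np.ceil(rng.exponential(bleach_mean_frames)))))
        start = rng.uniform(bounds[:, 0], bounds[:, 1])
        steps = rng.normal(0.0, step_sd_nm, size=(n - 1, 3))
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        trajs.append(Trajectory4D(positions=pos, times_ms=times[:n],
                                  molecule_id=mid,
                                  photon_budget=photon_budget))
    return trajs


def _pixel_integrated_gaussian(x0, y0, sx, sy, cols, rows, px):
    """Expected fraction of photons per pixel for an emitter at (x0, y0) nm."""
    ex = 0.5 * (erf(((cols + 1) * px - x0) / (np.sqrt(2) * sx))
                - erf((cols * px - x0) / (np.sqrt(2) * sx)))
    ey = 0.5 * (erf(((rows + 1) * px - y0) / (np.sqrt(2) * sy))
                - erf((rows * px - y0) / (np.sqrt(2) * sy)))
    return np.outer(ey, ex)


def _add_template(canvas, template, x0, y0, px, photons):
    """Add a reference template (sum-normalized) centred at (x0, y0) nm."""
    t = template / template.sum() if template.sum() > 0 else template
    h, w = t.shape
    col = x0 / px - 0.5 - (w - 1) / 2
    row = y0 / px - 0.5 - (h - 1) / 2
    ci, cf = int(np.floor(col)), col - np.floor(col)
    ri, rf = int(np.floor(row)), row - np.floor(row)
    shifted = ndimage.shift(t, (rf, cf), order=1, mode="constant", cval=0.0,
                            prefilter=False)
    H, W = canvas.shape
    r0, r1 = max(ri, 0), min(ri + h, H)
    c0, c1 = max(ci, 0), min(ci + w, W)
    if r0 >= r1 or c0 >= c1:
        return
    canvas[r0:r1, c0:c1] += photons * shifted[r0 - ri:r1 - ri, c0 - ci:c1 - ci]


def render_frames(
    trajs: list[Trajectory4D],
    psf_source,
    camera: CameraModel = CameraModel(),
    field: tuple[int, int] = (64, 64),
    seed=None,
    add_noise: bool = True,
    background_photons: float = 0.0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render trajectories into a movie with camera noise.

    ``psf_source`` selects the PSF model: a :class:`CalibrationCurve` gives
    analytic elliptical Gaussians with widths (r(z)·sigma_y(z), sigma_y(z))
    integrated over pixel areas; a :class:`ReferenceStack` places the
    nearest interpolated template with a bilinear sub-pixel shift.
    Molecules whose z lies outside the PSF source's axial span are not
    rendered (defocus loss).  With noise enabled each pixel is drawn as
    Poisson(expected_photons * gain + offset); disabling noise returns the
    expectation itself (photon-conserving, useful for oracles).
    """
    if add_noise and seed is None:
        raise ValueError("a seed is required when noise is enabled")
    rng = np.random.default_rng(seed)
    ny, nx = field
    px = camera.pixel_size_nm
    if n_frames is None:
        n_frames = max((len(t) for t in trajs), default=1)
    analytic = isinstance(psf_source, CalibrationCurve)
    if analytic:
        z_lo, z_hi = (1000.0 * psf_source.z_range[0],
                      1000.0 * psf_source.z_range[1])
    else:
        z_lo, z_hi = psf_source.z_span_nm

    movie = np.empty((n_frames, ny, nx))
    for f in range(n_frames):
        photons = np.full((ny, nx), float(background_photons))
        for traj in trajs:
            if f >= len(traj):
                continue
            x0, y0, z0 = traj.positions[f]
            if not (z_lo <= z0 <= z_hi):
                continue
            if analytic:
                sx, sy = psf_source.render_widths(z0 / 1000.0)
                half = int(np.ceil(4.0 * max(sx, sy) / px)) + 1
                cc = int(round(x0 / px - 0.5))
                rc = int(round(y0 / px - 0.5))
                cols = np.arange(max(cc - half, 0), min(cc + half + 1, nx))
                rows = np.arange(max(rc - half, 0), min(rc + half + 1, ny))
                if cols.size == 0 or rows.size == 0:
                    continue
                patch = _pixel_integrated_gaussian(x0, y0, sx, sy,
                                                   cols, rows, px)
                photons[np.ix_(rows, cols)] += traj.photon_budget * patch
            else:
                _add_template(photons, psf_source.nearest_plane(z0),
                              x0, y0, px, traj.photon_budget)
        expected = photons * camera.counts_per_photon + camera.offset
        movie[f] = rng.poisson(expected) if add_noise else expected
    return movie


def _ellipse_mask(shape, cx, cy, rx, ry) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def simulate_cell_image(
    cell_ellipses,
    nucleus_ellipses,
    intensities: dict | None = None,
    camera: CameraModel = CameraModel(),
    seed=None,
    shape: tuple[int, int] = (192, 192),
    add_noise: bool = True,
):
    """Render a two-channel cell image plus ground-truth label masks.

    Channel 0 carries the cell body signal (GFP-like), channel 1 the nucleus
    signal (mCherry-like).  Ellipses are (cx, cy, rx, ry) in pixels; nucleus
    i is expected to lie inside cell i.  Returns
    ``(image (2, h, w), cell_labels, nucleus_labels)``.
    """
    if intensities is None:
        intensities = {"cell": 50.0, "nucleus": 80.0}
    if len(nucleus_ellipses) != len(cell_ellipses):
        raise ValueError("one nucleus per cell expected")
    cell_labels = np.zeros(shape, dtype=np.int32)
    for i, (cx, cy, rx, ry) in enumerate(cell_ellipses, start=1):
        cell_labels[_ellipse_mask(shape, cx, cy, rx, ry)] = i
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    any_cell = cell_labels > 0
    for i, (cx, cy, rx, ry) in enumerate(nucleus_ellipses, start=1):
        m = _ellipse_mask(shape, cx, cy, rx, ry)
        if np.any(m & ~any_cell):
            raise ValueError(f"nucleus {i} extends outside every cell")
        nucleus_labels[m] = i
    ch0 = intensities["cell"] * any_cell
    ch1 = intensities["nucleus"] * (nucleus_labels > 0)
    expected = (np.stack([ch0, ch1]) * camera.counts_per_photon
                + camera.offset)
    if add_noise:
        if seed is None:
            raise ValueError("a seed is required when noise is enabled")
        rng = np.random.default_rng(seed)
        image = rng.poisson(expected).astype(float)
    else:
        image = expected
    return image, cell_labels, nucleus_labels
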