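"""Astigmatic PSF width calibration and ratio-to-depth inversion.

A cylindrical lens in the emission path makes the image of a point emitter
elliptical, with the ratio of the fitted Gaussian widths r = sigma_x/sigma_y
depending on the emitter's axial position z.  This module fits the
z-dependence of the widths and of their ratio with second-order polynomials,
and inverts the ratio polynomial to recover z with a 1-sigma confidence
interval propagated from the fit covariance by the delta method.

Units: z in micrometres, widths in nanometres, ratio dimensionless.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FocusLevelSummary",
    "CalibrationCurve",
    "CalibrationError",
    "CalibrationRangeError",
    "fit_width_polynomials",
    "fit_ratio_polynomial",
    "predict_ratio",
    "ratio_to_z",
]


class CalibrationError(ValueError):
    """A calibration fit could not be performed (too few / degenerate levels)."""


class CalibrationRangeError(ValueError):
    """A width ratio lies outside the invertible range of the calibration."""


@dataclass(frozen=True)
class FocusLevelSummary:
    """Summary of the spots fitted at one nominal focal offset.

    Parameters
    ----------
    z_um : float
        Nominal axial offset of the stage (micrometres).
    mean_sigma_x, mean_sigma_y : float
        Mean fitted Gaussian widths over the spots at this level (nm).
    se_sigma_x, se_sigma_y : float or None
        Standard errors of the mean widths (nm); None when unknown.
    n_spots : int
        Number of spots analysed at this level.
    """

    z_um: float
    mean_sigma_x: float
    mean_sigma_y: float
    se_sigma_x: float | None = None
    se_sigma_y: float | None = None
    n_spots: int = 1

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.mean_sigma_x <= 0 or self.mean_sigma_y <= 0:
            raise ValueError("mean widths must be positive")
        for se in (self.se_sigma_x, self.se_sigma_y):
            if se is not None and se <= 0:
                raise ValueError("standard errors must be positive when given")

    @property
    def ratio(self) -> float:
        return self.mean_sigma_x / self.mean_sigma_y

    @property
    def se_ratio(self) -> float | None:
        """SE of the width ratio by first-order error propagation."""
        if self.se_sigma_x is None or self.se_sigma_y is None:
            return None
        rel = np.hypot(self.se_sigma_x / self.mean_sigma_x,
                       self.se_sigma_y / self.mean_sigma_y)
        return self.ratio * rel


def _quadratic_design(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z**2, z, np.ones_like(z)])


def _wls_quadratic(z: np.ndarray, y: np.ndarray,
                   se: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least-squares quadratic fit.

    Returns (coeffs (a,b,c), covariance 3x3, residuals).  With per-point
    standard errors the weights are 1/se^2 and the coefficient covariance is
    the exact GLS form (X' W X)^-1; without them the fit is unweighted and
    the covariance is scaled by the residual variance.
    """
    X = _quadratic_design(z)
    if se is not None:
        w = 1.0 / np.asarray(se, dtype=float) ** 2
        Xw = X * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)
        coeffs, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
    else:
        coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coeffs
        dof = max(len(y) - 3, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    residuals = y - X @ coeffs
    return coeffs, cov, residuals


def _check_levels(levels: list[FocusLevelSummary]) -> np.ndarray:
    z = np.array([lv.z_um for lv in levels], dtype=float)
    if len(levels) < 3:
        raise CalibrationError("need at least 3 focal levels for a quadratic fit")
    if len(np.unique(z)) < 3:
        raise CalibrationError("focal levels must include at least 3 distinct z values")
    return z


def fit_width_polynomials(
    levels: list[FocusLevelSummary],
) -> tuple[np.ndarray, np.ndarray]:
    """Fit sigma_x(z) and sigma_y(z) with second-order polynomials.

    Coefficients are returned highest power first, ``(a, b, c)`` for
    ``a z^2 + b z + c`` with z in micrometres and sigma in nm.  Levels with
    standard errors are weighted by 1/SE^2.
    """
    z = _check_levels(levels)
    out = []
    for attr, se_attr in (("mean_sigma_x", "se_sigma_x"),
                          ("mean_sigma_y", "se_sigma_y")):
        y = np.array([getattr(lv, attr) for lv in levels], dtype=float)
        ses = [getattr(lv, se_attr) for lv in levels]
        se = np.array(ses, dtype=float) if all(s is not None for s in ses) else None
        coeffs, _, _ = _wls_quadratic(z, y, se)
        out.append(coeffs)
    return out[0], out[1]


@dataclass
class CalibrationCurve:
    """Fitted ratio-to-depth calibration r(z) = a z^2 + b z + c.

    ``coeffs_ratio`` is (a, b, c) with z in micrometres; ``covariance_ratio``
    is the 3x3 coefficient covariance used for the delta-method confidence
    interval on inverted z positions.  A curve is ``invertible`` only when
    the derivative 2az + b keeps one sign over ``z_range``; non-monotonic
    fits remain usable for forward prediction but refuse inversion.
    """

    coeffs_ratio: np.ndarray
    z_range: tuple[float, float]
    covariance_ratio: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3)))
    r_squared: float = float("nan")
    coeffs_sigma_x: np.ndarray | None = None
    coeffs_sigma_y: np.ndarray | None = None
    invertible: bool = True

    def __post_init__(self) -> None:
        self.coeffs_ratio = np.asarray(self.coeffs_ratio, dtype=float)
        self.covariance_ratio = np.asarray(self.covariance_ratio, dtype=float)
        lo, hi = self.z_range
        if not lo < hi:
            raise ValueError("z_range must be a nonempty interval")
        self.z_range = (float(lo), float(hi))
        if self.invertible and not self._monotonic():
            self.invertible = False
        if self.invertible and (self.predict_ratio(lo) <= 0
                                or self.predict_ratio(hi) <= 0):
            self.invertible = False

    # -- forward ---------------------------------------------------------

    def _monotonic(self) -> bool:
        a, b, _ = self.coeffs_ratio
        lo, hi = self.z_range
        d_lo, d_hi = 2 * a * lo + b, 2 * a * hi + b
        return d_lo * d_hi > 0

    def predict_ratio(self, z_um: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted quadratic at axial position z (micrometres)."""
        z = np.asarray(z_um, dtype=float)
        lo, hi = self.z_range
        if np.any((z < lo) | (z > hi)):
            warnings.warn("z outside calibrated range; extrapolating",
                          stacklevel=2)
        a, b, c = self.coeffs_ratio
        out = a * z**2 + b * z + c
        return float(out) if np.isscalar(z_um) else out

    def _width(self, coeffs: np.ndarray | None, z: np.ndarray):
        if coeffs is None:
            raise CalibrationError("curve carries no width polynomial")
        a, b, c = coeffs
        return a * z**2 + b * z + c

    def sigma_x(self, z_um):
        """Predicted sigma_x (nm) at z from the fitted width polynomial."""
        return self._width(self.coeffs_sigma_x, np.asarray(z_um, dtype=float))

    def sigma_y(self, z_um):
        """Predicted sigma_y (nm) at z from the fitted width polynomial."""
        return self._width(self.coeffs_sigma_y, np.asarray(z_um, dtype=float))

    def render_widths(self, z_um):
        """Widths (sigma_x, sigma_y) in nm used to render a spot at depth z.

        sigma_y comes from its fitted polynomial; sigma_x is taken as
        r(z) * sigma_y(z) so that the rendered width ratio reproduces the
        ratio calibration exactly at every depth.
        """
        z = np.asarray(z_um, dtype=float)
        sy = self._width(self.coeffs_sigma_y, z)
        a, b, c = self.coeffs_ratio
        sx = (a * z**2 + b * z + c) * sy
        return sx, sy

    @property
    def ratio_range(self) -> tuple[float, float]:
        """Attainable ratio interval [r(z_min), r(z_max)] (sorted)."""
        lo, hi = self.z_range
        a, b, c = self.coeffs_ratio
        r_lo = a * lo**2 + b * lo + c
        r_hi = a * hi**2 + b * hi + c
        return (min(r_lo, r_hi), max(r_lo, r_hi))

    # -- inverse ---------------------------------------------------------

    def ratio_to_z(self, r: float) -> tuple[float, float]:
        """Invert a measured width ratio to axial position.

        Returns ``(z_um, ci_um)`` where ``ci_um`` is the 1-sigma confidence
        interval from the fit covariance by the delta method:
        var(z) = g . Sigma . g' / (dr/dz)^2 with g = (z^2, z, 1).

        Raises
        ------
        CalibrationRangeError
            If ``r`` is outside the attainable interval, or no quadratic
            root falls inside ``z_range``.
        """
        if not self.invertible:
            raise CalibrationError(
                "curve is not monotonic over z_range; inversion disabled")
        r = float(r)
        a, b, c = self.coeffs_ratio
        lo, hi = self.z_range
        r_min, r_max = self.ratio_range
        eps = 1e-12 * max(1.0, abs(r_max))
        if r < r_min - eps or r > r_max + eps:
            raise CalibrationRangeError(
                f"ratio {r:.4g} outside attainable range "
                f"[{r_min:.4g}, {r_max:.4g}]")
        if abs(a) < 1e-300:
            roots = np.array([(r - c) / b])
        else:
            disc = b * b - 4 * a * (c - r)
            if disc < 0:
                raise CalibrationRangeError(
                    f"ratio {r:.4g} is not attained by the calibration curve")
            sq = np.sqrt(disc)
            roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
        tol = 1e-9 * max(1.0, hi - lo)
        inside = roots[(roots >= lo - tol) & (roots <= hi + tol)]
        if inside.size == 0:
            raise CalibrationRangeError(
                f"no root of the calibration quadratic lies inside "
                f"[{lo}, {hi}] for ratio {r:.4g}")
        if inside.size > 1 and np.ptp(inside) > tol:
            raise CalibrationError(
                "both quadratic roots lie inside z_range; curve is ambiguous")
        z = float(np.clip(inside[0], lo, hi))
        g = np.array([z**2, z, 1.0])
        drdz = 2 * a * z + b
        var_z = float(g @ self.covariance_ratio @ g) / drdz**2
        return z, float(np.sqrt(max(var_z, 0.0)))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "coeffs_ratio": self.coeffs_ratio.tolist(),
            "z_range": list(self.z_range),
            "covariance_ratio": self.covariance_ratio.tolist(),
            "r_squared": self.r_squared,
            "invertible": self.invertible,
        }
        for name in ("coeffs_sigma_x", "coeffs_sigma_y"):
            v = getattr(self, name)
            d[name] = None if v is None else np.asarray(v).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            coeffs_ratio=np.array(d["coeffs_ratio"], dtype=float),
            z_range=tuple(d["z_range"]),
            covariance_ratio=np.array(d["covariance_ratio"], dtype=float),
            r_squared=d.get("r_squared", float("nan")),
            coeffs_sigma_x=(None if d.get("coeffs_sigma_x") is None
                            else np.array(d["coeffs_sigma_x"], dtype=float)),
            coeffs_sigma_y=(None if d.get("coeffs_sigma_y") is None
                            else np.array(d["coeffs_sigma_y"], dtype=float)),
            invertible=d.get("invertible", True),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ratio_polynomial(
    levels: list[FocusLevelSummary],
    z_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Fit the width-ratio calibration r(z) from per-level summaries.

    The per-level ratio is mean_sigma_x / mean_sigma_y; when both width SEs
    are available the fit is weighted by the propagated ratio SE.  The
    goodness of fit R^2 = 1 - SS_res/SS_tot is computed on the unweighted
    ratios.  A fit whose derivative changes sign over ``z_range`` is
    returned flagged non-invertible (forward prediction only).
    """
    z = _check_levels(levels)
    ratios = np.array([lv.ratio for lv in levels])
    ses = [lv.se_ratio for lv in levels]
    se = np.array(ses, dtype=float) if all(s is not None for s in ses) else None
    coeffs, cov, resid = _wls_quadratic(z, ratios, se)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ratios - ratios.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if z_range is None:
        z_range = (float(z.min()), float(z.max()))
    curve = CalibrationCurve(
        coeffs_ratio=coeffs, z_range=z_range, covariance_ratio=cov,
        r_squared=r2)
    if not curve.invertible:
        warnings.warn("fitted ratio curve is not monotonic over z_range; "
                      "flagged non-invertible", stacklevel=2)
    sx, sy = fit_width_polynomials(levels)
    curve.coeffs_sigma_x, curve.coeffs_sigma_y = sx, sy
    return curve


def predict_ratio(z_um, curve: CalibrationCurve):
    """Forward-evaluate the ratio calibration at z (micrometres)."""
    return curve.predict_ratio(z_um)


def ratio_to_z(r: float, curve: CalibrationCurve) -> tuple[float, float]:
    """Invert a width ratio to (z_um, 1-sigma CI) via the calibration."""
    return curve.ratio_to_z(r)
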