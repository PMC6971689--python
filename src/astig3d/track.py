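"""Trajectory linking, MSD analysis and diffusion-coefficient estimation.

Per-frame foci are linked by greedy nearest-neighbour assignment, MSDs are
computed separately in each spatial dimension, and apparent microscopic
diffusion coefficients come from a linear fit to the first four MSD points
with the intercept fixed at the theoretical localization precision.  Tracks
with D at or below 0.1 um^2/s are classified immobile (putatively
DNA-bound); the intensity-weighted centroid of an immobile track marks the
putative binding-site position.

Units: positions nm, lags ms, MSD um^2, D um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .localize import Focus

__all__ = [
    "Track",
    "MSDCurve",
    "DiffusionEstimate",
    "link_foci",
    "msd_per_dimension",
    "fit_diffusion",
    "classify_mobility",
    "track_centroid",
    "summarize_tracks",
]

#: diffusion threshold separating immobile (DNA-bound) from mobile tracks
IMMOBILE_THRESHOLD_UM2_S = 0.1
#: number of MSD lag points entering the diffusion fit
MSD_FIT_POINTS = 4
#: minimum localizations required for a 4-lag-point diffusion estimate
MIN_TRACK_LENGTH = 5


@dataclass
class Track:
    """A time-ordered sequence of localizations of one molecule."""

    localizations: list[Focus]
    dt_ms: float
    id: int = 0

    def __post_init__(self) -> None:
        if len(self.localizations) < 2:
            raise ValueError("a track needs at least 2 localizations")
        frames = [f.frame for f in self.localizations]
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.dt_ms <= 0:
            raise ValueError("frame interval must be positive")

    def __len__(self) -> int:
        return len(self.localizations)

    @property
    def frames(self) -> np.ndarray:
        return np.array([f.frame for f in self.localizations])

    @property
    def positions_nm(self) -> np.ndarray:
        return np.array([[f.x_nm, f.y_nm,
                          np.nan if f.z_nm is None else f.z_nm]
                         for f in self.localizations])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f.intensity for f in self.localizations])

    def mean_precision_nm(self) -> tuple[float, float]:
        """Per-track mean (lateral, axial) 1-sigma localization error in nm."""
        lat = np.array([f.precision_xy_nm for f in self.localizations])
        ax = np.array([f.precision_z_nm for f in self.localizations])
        lat_m = float(lat[np.isfinite(lat)].mean()) if np.isfinite(lat).any() else float("nan")
        ax_m = float(ax[np.isfinite(ax)].mean()) if np.isfinite(ax).any() else float("nan")
        return lat_m, ax_m


@dataclass
class MSDCurve:
    """Time-averaged mean square displacements per dimension."""

    lags_ms: np.ndarray
    msd_x: np.ndarray   # um^2
    msd_y: np.ndarray
    msd_z: np.ndarray
    msd_3d: np.ndarray
    n_pairs: np.ndarray

    def component(self, name: str) -> np.ndarray:
        return {"x": self.msd_x, "y": self.msd_y,
                "z": self.msd_z, "3d": self.msd_3d}[name]


@dataclass
class DiffusionEstimate:
    """Apparent microscopic diffusion coefficient from an MSD fit."""

    D: float                    # um^2/s
    intercept: float            # um^2, fixed from localization precision
    dimensionality: int
    fit_error: float            # um^2/s, sd of the slope estimate
    n_points_fit: int = MSD_FIT_POINTS
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2, 3):
            raise ValueError("dimensionality must be 1, 2 or 3")
        if self.intercept < 0:
            raise ValueError("intercept must be >= 0")


def link_foci(
    foci_by_frame: dict[int, list[Focus]],
    max_jump_nm: float,
    max_gap: int = 0,
    dt_ms: float = 5.0,
    use_z: bool = False,
) -> list[Track]:
    """Link per-frame foci into tracks by greedy nearest-neighbour matching.

    For each consecutive frame pair, candidate (track-head, focus) pairs
    within ``max_jump_nm`` lateral distance are sorted by (distance,
    track index, focus index) and assigned greedily, so each focus joins at
    most one track and equidistant candidates resolve to the lower focus
    index.  ``max_gap`` frames without a match are tolerated before a track
    is closed (default 0: no gap closing).
    """
    frames = sorted(foci_by_frame)
    open_tracks: list[dict] = []
    closed: list[list[Focus]] = []
    for fr in frames:
        foci = list(foci_by_frame[fr])
        # a track may bridge at most max_gap missing frames
        still_open = []
        for tr in open_tracks:
            if fr - tr["last_frame"] > max_gap + 1:
                closed.append(tr["foci"])
            else:
                still_open.append(tr)
        open_tracks = still_open
        pairs = []
        for ti, tr in enumerate(open_tracks):
            head = tr["foci"][-1]
            for fi, f in enumerate(foci):
                if use_z and head.z_nm is not None and f.z_nm is not None:
                    d = float(np.sqrt((head.x_nm - f.x_nm) ** 2
                                      + (head.y_nm - f.y_nm) ** 2
                                      + (head.z_nm - f.z_nm) ** 2))
                else:
                    d = float(np.hypot(head.x_nm - f.x_nm,
                                       head.y_nm - f.y_nm))
                if d <= max_jump_nm:
                    pairs.append((d, ti, fi))
        pairs.sort()
        used_t, used_f = set(), set()
        for d, ti, fi in pairs:
            if ti in used_t or fi in used_f:
                continue
            open_tracks[ti]["foci"].append(foci[fi])
            open_tracks[ti]["last_frame"] = fr
            used_t.add(ti)
            used_f.add(fi)
        for fi, f in enumerate(foci):
            if fi not in used_f:
                open_tracks.append({"foci": [f], "last_frame": fr})
    closed.extend(tr["foci"] for tr in open_tracks)
    tracks = []
    tid = 0
    for foci in closed:
        if len(foci) >= 2:
            tracks.append(Track(localizations=foci, dt_ms=dt_ms, id=tid))
            tid += 1
    return tracks


def msd_per_dimension(track: Track, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all ordered pairs at each lag, per dimension.

    Lag is counted in frames and converted to ms via the track's frame
    interval; for an unbroken track of N points lag k averages N - k
    displacement pairs.  Requesting lags beyond the track span truncates
    with a warning.
    """
    frames = track.frames
    pos_um = track.positions_nm / 1000.0
    span = int(frames[-1] - frames[0])
    if max_lag is None:
        max_lag = span
    if max_lag > span:
        import warnings
        warnings.warn("max_lag exceeds track span; truncating", stacklevel=2)
        max_lag = span
    lags = np.arange(1, max_lag + 1)
    by_frame = {int(f): i for i, f in enumerate(frames)}
    msd = np.zeros((len(lags), 4))
    n_pairs = np.zeros(len(lags), dtype=int)
    for li, k in enumerate(lags):
        sq = []
        for f0, i in by_frame.items():
            j = by_frame.get(f0 + int(k))
            if j is None:
                continue
            d = pos_um[j] - pos_um[i]
            sq.append(np.concatenate([d**2, [np.sum(d**2)]]))
        if sq:
            arr = np.array(sq)
            valid = np.isfinite(arr)
            with np.errstate(invalid="ignore"):
                msd[li] = np.where(valid.any(axis=0),
                                   np.nansum(np.where(valid, arr, 0.0), axis=0)
                                   / np.maximum(valid.sum(axis=0), 1),
                                   np.nan)
            n_pairs[li] = len(sq)
    return MSDCurve(lags_ms=lags * track.dt_ms,
                    msd_x=msd[:, 0], msd_y=msd[:, 1], msd_z=msd[:, 2],
                    msd_3d=msd[:, 3], n_pairs=n_pairs)


def fit_diffusion(
    msd: MSDCurve,
    precision_nm,
    dimensionality: int = 1,
    component: str | None = None,
    n_points: int = MSD_FIT_POINTS,
) -> DiffusionEstimate:
    """Fixed-intercept linear fit of the first MSD points.

    Fits MSD(tau) = 2 d D tau + C over the first ``n_points`` lags with the
    intercept fixed at the localization-error floor
    C = 2 * sum_axes(precision^2): 1D gives 2 sigma^2, 2D 4 sigma^2 (mean
    lateral), 3D 2 (sigma_x^2 + sigma_y^2 + sigma_z^2).  ``precision_nm``
    is a scalar (common per-axis sigma) or one value per axis.  The
    one-parameter least-squares slope is
    sum((MSD - C) tau) / sum(tau^2); a negative slope is reported as D <= 0
    and flagged (classified immobile downstream).
    """
    if component is None:
        component = {1: "x", 2: "x", 3: "3d"}[dimensionality]
    y = msd.component(component)
    flag = "ok"
    if len(y) < n_points:
        flag = "short_track"
        n_points = len(y)
    if n_points < 1:
        raise ValueError("no MSD points to fit")
    tau_s = msd.lags_ms[:n_points] / 1000.0
    y = np.asarray(y[:n_points], dtype=float)
    prec_um = np.atleast_1d(np.asarray(precision_nm, dtype=float)) / 1000.0
    if prec_um.size == 1:
        prec_um = np.repeat(prec_um, dimensionality)
    if prec_um.size != dimensionality:
        raise ValueError("precision must be scalar or one value per axis")
    if not np.all(np.isfinite(prec_um)):
        raise ValueError("precision must be finite")
    intercept = 2.0 * float(np.sum(prec_um**2))
    slope = float(np.sum((y - intercept) * tau_s) / np.sum(tau_s**2))
    resid = y - intercept - slope * tau_s
    dof = max(n_points - 1, 1)
    slope_sd = float(np.sqrt(np.sum(resid**2) / dof / np.sum(tau_s**2)))
    D = slope / (2.0 * dimensionality)
    if D <= 0:
        flag = "nonpositive_slope"
    return DiffusionEstimate(D=D, intercept=intercept,
                             dimensionality=dimensionality,
                             fit_error=slope_sd / (2.0 * dimensionality),
                             n_points_fit=n_points, flag=flag)


def classify_mobility(est: DiffusionEstimate,
                      threshold: float = IMMOBILE_THRESHOLD_UM2_S) -> str:
    """Immobile iff D at or below the threshold (default 0.1 um^2/s)."""
    return "immobile" if est.D <= threshold else "mobile"


def track_centroid(track: Track) -> np.ndarray:
    """Fluorescence intensity-weighted mean position (nm) of a track."""
    w = track.intensities
    if float(np.sum(w)) <= 0:
        raise ValueError("track has zero total intensity")
    pos = track.positions_nm
    out = []
    for k in range(3):
        ok = np.isfinite(pos[:, k])
        if not ok.any() or np.sum(w[ok]) <= 0:
            out.append(np.nan)
        else:
            out.append(float(np.sum(w[ok] * pos[ok, k]) / np.sum(w[ok])))
    return np.array(out)


def summarize_tracks(
    tracks: list[Track],
    threshold: float = IMMOBILE_THRESHOLD_UM2_S,
    min_length: int = MIN_TRACK_LENGTH,
) -> pd.DataFrame:
    """Per-track diffusion summary table.

    For each track of at least ``min_length`` localizations: per-dimension
    and 3D diffusion coefficients (4-point MSD fits with the intercept
    fixed at the track's mean theoretical localization precision, the
    photon-count form, applied per coordinate), mobility class from the 3D
    estimate, and the intensity centroid.
    """
    rows = []
    for tr in tracks:
        if len(tr) < min_length:
            continue
        msd = msd_per_dimension(tr)
        lat, _ = tr.mean_precision_nm()
        # elliptical spots localize differently well along x and y, so the
        # intercept uses the per-axis theoretical precision when available
        prec = {}
        for ax in ("x", "y"):
            vals = np.array([getattr(f, f"precision_{ax}_nm")
                             for f in tr.localizations])
            prec[ax] = (float(vals[np.isfinite(vals)].mean())
                        if np.isfinite(vals).any() else lat)
        # z and 3D estimates use fully 3D-localized tracks only: a 2D-only
        # localization (width ratio outside the calibration) marks a track
        # that brushed the edge of the axial working range, where the
        # surviving z values are censored toward the interior
        has_z = not np.isnan(tr.positions_nm[:, 2]).any()
        ests = {}
        for comp in ("x", "y"):
            ests[comp] = fit_diffusion(msd, prec[comp], 1, component=comp)
        if has_z:
            ests["z"] = fit_diffusion(msd, lat, 1, component="z")
            ests["3d"] = fit_diffusion(msd, [prec["x"], prec["y"], lat], 3,
                                       component="3d")
        cls_est = ests.get("3d", ests["x"])
        cen = track_centroid(tr)
        rows.append({
            "track_id": tr.id, "n_points": len(tr),
            "D_x": ests["x"].D, "D_y": ests["y"].D,
            "D_z": ests["z"].D if has_z else np.nan,
            "D_3d": ests["3d"].D if has_z else np.nan,
            "class": classify_mobility(cls_est, threshold),
            "centroid_x_nm": cen[0], "centroid_y_nm": cen[1],
            "centroid_z_nm": cen[2],
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "n_points", "D_x", "D_y", "D_z", "D_3d", "class",
        "centroid_x_nm", "centroid_y_nm", "centroid_z_nm"])
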