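"""File formats, configuration and the chained pipeline runner.

Interchange conventions: TIFF for images and label masks, tab-separated
tables with a header row for foci/tracks/sites/distances (nm for space,
ms for time, um^2/s for diffusion coefficients), JSON for calibrations and
summaries, YAML for configuration.  A single master seed is split into
independent per-stage streams so a fixed configuration reproduces its
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "PipelineConfig",
    "read_image_stack",
    "write_image_stack",
    "split_dual_view",
    "read_table",
    "write_table",
    "run_pipeline",
]

TABLE_SCHEMAS = {
    "foci": ["frame", "x_nm", "y_nm", "sigx_nm", "sigy_nm", "ratio",
             "z_nm", "z_ci_nm", "intensity", "background", "snr",
             "precision_xy_nm", "precision_x_nm", "precision_y_nm",
             "precision_z_nm", "flag"],
    "tracks": ["track_id", "frame", "x_nm", "y_nm", "z_nm", "intensity"],
    "track_summary": ["track_id", "n_points", "D_x", "D_y", "D_z", "D_3d",
                      "class", "centroid_x_nm", "centroid_y_nm",
                      "centroid_z_nm"],
    "sites": ["x_nm", "y_nm", "z_nm"],
    "truth": ["molecule_id", "frame", "x_nm", "y_nm", "z_nm", "photons"],
    "levels": ["z_um", "mean_sigma_x", "mean_sigma_y", "se_sigma_x",
               "se_sigma_y", "n_spots"],
    "model3c": ["chrom", "bp", "x_nm", "y_nm", "z_nm"],
}


# ---------------------------------------------------------------------------
# images

def read_image_stack(path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (frames, h, w) float array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt / not a TIFF
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


def write_image_stack(path, stack: np.ndarray, as_uint16: bool = False) -> None:
    """Write a (frames, h, w) array as a multi-page TIFF."""
    arr = np.asarray(stack)
    if as_uint16:
        arr = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max
                      ).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")


def split_dual_view(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a dual-view (left/right half-field) layout into two channels."""
    frame = np.asarray(frame)
    w = frame.shape[-1]
    return frame[..., : w // 2], frame[..., w // 2:]


# ---------------------------------------------------------------------------
# tables

def write_table(path, df: pd.DataFrame, schema: str | None = None) -> None:
    """Write a table as TSV with a header row (decimal separator '.')."""
    if schema is not None:
        _validate(df, schema)
    df.to_csv(path, sep="\t", index=False)


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV table, optionally validating against a named schema."""
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        _validate(df, schema)
    return df


def _validate(df: pd.DataFrame, schema: str) -> None:
    cols = TABLE_SCHEMAS.get(schema)
    if cols is None:
        raise KeyError(f"unknown table schema {schema!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """All tunable parameters of the acquisition/analysis chain.

    Defaults follow the instrument described in the package docs: 93 nm
    pixels, EMCCD offset 100 counts, ~5 ms frame interval, calibration over
    z in [-0.5, +0.5] um, four-point MSD fits and a 0.1 um^2/s immobile
    threshold, 1 um pairwise-distance working range.
    """

    camera_offset: float = 100.0
    camera_gain: float = 1.0
    pixel_size_nm: float = 93.0
    exposure_ms: float = 4.7
    frame_interval_ms: float = 5.0
    z_range_um: tuple[float, float] = (-0.5, 0.5)
    calibration_levels: tuple[float, ...] = (-0.5, -0.25, 0.0, 0.25, 0.5)
    max_jump_nm: float | None = None
    min_track_length: int = 5
    msd_points: int = 4
    d_threshold_um2_s: float = 0.1
    d_max_um2_s: float = 3.0
    max_range_nm: float = 1000.0
    photon_budget: float = 2500.0
    detection_k: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("camera_gain", "pixel_size_nm", "exposure_ms",
                     "frame_interval_ms", "d_threshold_um2_s",
                     "max_range_nm", "photon_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.camera_offset < 0:
            raise ValueError("camera_offset must be >= 0")
        if self.msd_points < 2:
            raise ValueError("msd_points must be >= 2")
        if self.max_jump_nm is None:
            # 5 standard deviations of the fastest expected per-frame jump
            step = np.sqrt(2.0 * self.d_max_um2_s * 1000.0
                           * self.frame_interval_ms)
            self.max_jump_nm = float(5.0 * step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["z_range_um"] = list(self.z_range_um)
        d["calibration_levels"] = list(self.calibration_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "z_range_um" in d:
            d["z_range_um"] = tuple(d["z_range_um"])
        if "calibration_levels" in d:
            d["calibration_levels"] = tuple(d["calibration_levels"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic random stream for a named stage."""
        h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, h]))


# ---------------------------------------------------------------------------
# pipeline runner

def run_pipeline(
    config: PipelineConfig,
    outdir,
    n_molecules: int = 20,
    n_frames: int = 50,
    D_um2_s: float = 1.0,
    field: tuple[int, int] = (64, 64),
) -> dict:
    """Run simulate -> localize -> track on a seeded config and write a
    manifest.

    Each output file is listed in ``manifest.json`` together with the
    config hash that produced it, so repeated runs with the same seed and
    parameters are bit-identical.  Returns the manifest dictionary.
    """
    from . import localize as _loc
    from . import simulate as _sim
    from . import track as _trk

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    camera = _sim.CameraModel(offset=config.camera_offset,
                              pixel_size_nm=config.pixel_size_nm,
                              counts_per_photon=config.camera_gain)
    curve = _sim.default_calibration(z_range=config.z_range_um)

    ny, nx = field
    box = ((0.0, nx * config.pixel_size_nm), (0.0, ny * config.pixel_size_nm),
           (1000.0 * config.z_range_um[0], 1000.0 * config.z_range_um[1]))
    trajs = _sim.simulate_brownian_4d(
        D_um2_s, n_molecules, n_frames, dt_ms=config.frame_interval_ms,
        box=box, photon_budget=config.photon_budget,
        seed=config.stage_rng("simulate"))
    movie = _sim.render_frames(trajs, curve, camera, field=field,
                               seed=config.stage_rng("render"))
    movie_path = outdir / "movie.tif"
    write_image_stack(movie_path, movie, as_uint16=True)
    truth = pd.DataFrame(
        [(t.molecule_id, f, *t.positions[f], t.photon_budget)
         for t in trajs for f in range(len(t))],
        columns=TABLE_SCHEMAS["truth"])
    write_table(outdir / "truth.tsv", truth, schema="truth")

    foci = _loc.localize_stack(movie, curve=curve,
                               pixel_size_nm=config.pixel_size_nm,
                               k=config.detection_k)
    write_table(outdir / "foci.tsv", foci, schema="foci")

    foci_by_frame = foci_table_to_frames(foci)
    tracks = _trk.link_foci(foci_by_frame, max_jump_nm=config.max_jump_nm,
                            dt_ms=config.frame_interval_ms)
    summary = _trk.summarize_tracks(tracks,
                                    threshold=config.d_threshold_um2_s,
                                    min_length=config.min_track_length)
    write_table(outdir / "track_summary.tsv", summary,
                schema="track_summary")
    rows = [(tr.id, f.frame, f.x_nm, f.y_nm,
             np.nan if f.z_nm is None else f.z_nm, f.intensity)
            for tr in tracks for f in tr.localizations]
    write_table(outdir / "tracks.tsv",
                pd.DataFrame(rows, columns=TABLE_SCHEMAS["tracks"]),
                schema="tracks")

    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {
            "movie": movie_path.name,
            "truth": "truth.tsv",
            "foci": "foci.tsv",
            "tracks": "tracks.tsv",
            "track_summary": "track_summary.tsv",
        },
        "n_tracks": len(tracks),
        "n_foci": int(len(foci)),
        "mean_D_x": (float(summary["D_x"].mean()) if len(summary) else None),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def foci_table_to_frames(foci: pd.DataFrame) -> dict:
    """Group a foci table into {frame: [Focus, ...]} for the linker."""
    from .localize import Focus

    out: dict[int, list] = {}
    for _, r in foci.iterrows():
        f = Focus(frame=int(r["frame"]), x_nm=r["x_nm"], y_nm=r["y_nm"],
                  sigma_x_nm=r["sigx_nm"], sigma_y_nm=r["sigy_nm"],
                  intensity=r["intensity"], background=r["background"],
                  snr=r["snr"], precision_xy_nm=r["precision_xy_nm"],
                  precision_x_nm=r.get("precision_x_nm", np.nan),
                  precision_y_nm=r.get("precision_y_nm", np.nan),
                  precision_z_nm=r.get("precision_z_nm", np.nan),
                  z_nm=None if pd.isna(r["z_nm"]) else r["z_nm"],
                  z_ci_nm=None if pd.isna(r["z_ci_nm"]) else r["z_ci_nm"],
                  flag=str(r.get("flag", "ok")))
        out.setdefault(f.frame, []).append(f)
    return out
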