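"""Diagnostic plots: calibration curves and pairwise-distance histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .calibration import CalibrationCurve, FocusLevelSummary  # noqa: E402
from .genome import PairwiseDistanceDistribution  # noqa: E402

__all__ = ["plot_calibration", "plot_distance_histogram"]


def plot_calibration(curve: CalibrationCurve,
                     levels: list[FocusLevelSummary] | None = None,
                     path=None):
    """Width ratio vs depth with the fitted quadratic and its 1-sigma band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    z = np.linspace(*curve.z_range, 200)
    a, b, c = curve.coeffs_ratio
    r = a * z**2 + b * z + c
    ax.plot(z, r, label=f"r(z) = {a:.2f}z² + {b:.2f}z + {c:.2f}")
    band = np.array([np.sqrt(max(np.array([zi**2, zi, 1.0])
                                 @ curve.covariance_ratio
                                 @ np.array([zi**2, zi, 1.0]), 0.0))
                     for zi in z])
    ax.fill_between(z, r - band, r + band, alpha=0.3)
    if levels:
        ax.errorbar([lv.z_um for lv in levels], [lv.ratio for lv in levels],
                    yerr=[lv.se_ratio or 0 for lv in levels], fmt="ks",
                    capsize=2)
    ax.set_xlabel("z (µm)")
    ax.set_ylabel("σx / σy")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_distance_histogram(observed: PairwiseDistanceDistribution,
                            predicted: PairwiseDistanceDistribution | None
                            = None,
                            bin_width_nm: float = 100.0,
                            path=None):
    """Histogram of pairwise site distances, observed vs model-predicted."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    top = max(observed.distances.max() if observed.n else 0.0,
              predicted.distances.max() if predicted is not None
              and predicted.n else 0.0, bin_width_nm)
    bins = np.arange(0, top + bin_width_nm, bin_width_nm)
    ax.hist(observed.distances, bins=bins, density=True, alpha=0.6,
            color="maroon",
            label=f"observed ({observed.mean:.0f} ± {observed.se:.0f} nm)")
    if predicted is not None and predicted.n:
        ax.hist(predicted.distances, bins=bins, density=True,
                histtype="step", color="black",
                label=f"predicted ({predicted.mean:.0f} ± "
                      f"{predicted.se:.0f} nm)")
    ax.set_xlabel("pairwise distance (nm)")
    ax.set_ylabel("probability density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
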