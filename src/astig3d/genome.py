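"""Pairwise-distance statistics for putative binding-site point sets.

The 3D intensity centroids of immobile (D <= 0.1 um^2/s) nuclear tracks are
treated as putative transcription-factor binding sites.  Their pairwise
distance distribution is compared against a predicted site set obtained by
scanning the genome for an IUPAC binding motif and mapping the hits onto a
chromosome-conformation-capture (3C) polymer model of the chromosomes.
Distances beyond the ~1 um axial working range of the astigmatism optics
can be excluded from the predicted distribution before comparison.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "SiteSet",
    "PairwiseDistanceDistribution",
    "DistributionComparison",
    "pairwise_distances",
    "truncate_range",
    "compare_distributions",
    "scan_iupac_motif",
    "map_sites_to_3c",
    "sites_from_track_summary",
]

#: astigmatism working range used to truncate predicted distances (nm)
WORKING_RANGE_NM = 1000.0

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class SiteSet:
    """A 3D point set of putative binding sites.

    ``points`` is (n, 3) in nm.  Observed sets carry per-point ``cell_ids``
    (pairing is then restricted within cells); model-predicted sets may
    carry ``chrom``/``bp`` provenance instead.
    """

    points: np.ndarray
    source: str = "observed"
    cell_ids: np.ndarray | None = None
    chrom: list[str] | None = None
    bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("site coordinates must be finite")
        if self.cell_ids is not None:
            self.cell_ids = np.asarray(self.cell_ids)
            if len(self.cell_ids) != len(self.points):
                raise ValueError("one cell id per point required")

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else len(self.points)


@dataclass
class PairwiseDistanceDistribution:
    """All unordered-pair 3D Euclidean distances of a site set (nm)."""

    distances: np.ndarray
    truncation_nm: float | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()

    @property
    def n(self) -> int:
        return len(self.distances)

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances)) if self.n else float("nan")

    @property
    def se(self) -> float:
        """Standard error of the mean, sd/sqrt(n)."""
        if self.n < 2:
            return float("nan")
        return float(np.std(self.distances, ddof=1) / np.sqrt(self.n))


def pairwise_distances(sites: SiteSet,
                       within_cell: bool = False) -> PairwiseDistanceDistribution:
    """All unordered-pair Euclidean distances of a site set.

    With ``within_cell`` pairs are restricted to points sharing a cell id
    (distances between sites in different nuclei are not physically
    meaningful); the total count is then sum_c m_c (m_c - 1) / 2.
    Fewer than two eligible points give an empty distribution.
    """
    if within_cell and sites.cell_ids is None:
        raise ValueError("within_cell pairing requires cell ids")
    if len(sites) < 2:
        return PairwiseDistanceDistribution(np.empty(0))
    if within_cell:
        chunks = []
        for c in np.unique(sites.cell_ids):
            pts = sites.points[sites.cell_ids == c]
            if len(pts) >= 2:
                chunks.append(pdist(pts))
        d = np.concatenate(chunks) if chunks else np.empty(0)
    else:
        d = pdist(sites.points)
    return PairwiseDistanceDistribution(d)


def truncate_range(dist: PairwiseDistanceDistribution,
                   max_range_nm: float = WORKING_RANGE_NM
                   ) -> PairwiseDistanceDistribution:
    """Drop distances beyond the instrument's working range (default 1 um)."""
    kept = dist.distances[dist.distances <= max_range_nm]
    return PairwiseDistanceDistribution(kept, truncation_nm=max_range_nm)


class DistributionComparison(NamedTuple):
    mean_obs: float
    se_obs: float
    mean_pred: float
    se_pred: float
    t_statistic: float
    p_value: float


def compare_distributions(
    obs: PairwiseDistanceDistribution,
    pred: PairwiseDistanceDistribution,
    equal_var: bool = True,
) -> DistributionComparison:
    """Two-sample Student's t-test on the two distance lists.

    The default is the classical equal-variance (pooled) form; ``equal_var
    = False`` gives the Welch variant.  Means are reported with sd/sqrt(n)
    standard errors.
    """
    if obs.n < 2 or pred.n < 2:
        raise ValueError("both distributions need at least 2 distances")
    if np.std(obs.distances) == 0 and np.std(pred.distances) == 0:
        if obs.mean == pred.mean:
            return DistributionComparison(obs.mean, obs.se, pred.mean,
                                          pred.se, 0.0, 1.0)
        raise ValueError("degenerate (zero-variance) distance distributions")
    t, p = stats.ttest_ind(obs.distances, pred.distances,
                           equal_var=equal_var)
    return DistributionComparison(obs.mean, obs.se, pred.mean, pred.se,
                                  float(t), float(p))


def _expand_iupac(motif: str) -> str:
    """Compile an IUPAC motif to a regex over A/C/G/T (N in a sequence
    never matches)."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif")
        opts = IUPAC_CODES[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def reverse_complement(motif: str) -> str:
    """IUPAC-aware reverse complement."""
    return motif.upper().translate(_COMPLEMENT)[::-1]


def scan_iupac_motif(genome, motif: str) -> list[tuple[str, int, str]]:
    """Scan both strands of a sequence collection for an IUPAC motif.

    ``genome`` maps sequence names to strings (a dict, or an iterable of
    Bio.SeqIO records).  Returns (chromosome, bp, strand) for every
    (possibly overlapping) match; bp is the 1-based start of the matched
    site in forward-strand coordinates for both strands.  Minus-strand hits
    are matches of the motif's reverse complement on the forward sequence.
    """
    if not isinstance(genome, dict):
        genome = {rec.id: str(rec.seq) for rec in genome}
    fwd = re.compile(f"(?=({_expand_iupac(motif)}))")
    rev = re.compile(f"(?=({_expand_iupac(reverse_complement(motif))}))")
    hits = []
    for name, seq in genome.items():
        s = str(seq).upper()
        for m in fwd.finditer(s):
            hits.append((name, m.start() + 1, "+"))
        for m in rev.finditer(s):
            hits.append((name, m.start() + 1, "-"))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def map_sites_to_3c(
    sites_bp: list[tuple[str, int]],
    model: pd.DataFrame,
) -> SiteSet:
    """Interpolate genomic sites onto a 3C polymer model.

    ``model`` is a table with columns ``chrom bp x_nm y_nm z_nm`` holding
    bp-anchored vertices of each chromosome's polyline (sorted or not).
    Each site's 3D position is linearly interpolated between the two
    anchors bracketing its bp; sites on unknown chromosomes or outside the
    anchored span are dropped with a warning.
    """
    required = {"chrom", "bp", "x_nm", "y_nm", "z_nm"}
    missing = required - set(model.columns)
    if missing:
        raise ValueError(f"3C model table lacks columns: {sorted(missing)}")
    by_chrom = {}
    for chrom, grp in model.groupby("chrom"):
        grp = grp.sort_values("bp")
        by_chrom[chrom] = (grp["bp"].to_numpy(dtype=float),
                           grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float))
    pts, chroms, bps, dropped = [], [], [], 0
    for chrom, bp in sites_bp:
        anchors = by_chrom.get(chrom)
        if anchors is None or not (anchors[0][0] <= bp <= anchors[0][-1]):
            dropped += 1
            continue
        abp, xyz = anchors
        pts.append([np.interp(bp, abp, xyz[:, k]) for k in range(3)])
        chroms.append(chrom)
        bps.append(bp)
    if dropped:
        warnings.warn(f"{dropped} site(s) outside the anchored 3C span "
                      "dropped", stacklevel=2)
    return SiteSet(points=np.array(pts).reshape(-1, 3), source="model",
                   chrom=chroms, bp=np.array(bps))


def sites_from_track_summary(summary: pd.DataFrame,
                             require_nucleus: bool = True) -> SiteSet:
    """Observed site set from immobile-track centroids in a summary table.

    Keeps tracks classified immobile; with ``require_nucleus`` (and a
    ``compartment`` column present) only nucleus-assigned tracks are used.
    """
    sel = summary[summary["class"] == "immobile"]
    if require_nucleus and "compartment" in summary.columns:
        sel = sel[sel["compartment"] == "nucleus"]
    pts = sel[["centroid_x_nm", "centroid_y_nm", "centroid_z_nm"]].to_numpy(
        dtype=float)
    cells = (sel["cell_id"].to_numpy()
             if "cell_id" in sel.columns else np.zeros(len(sel), dtype=int))
    return SiteSet(points=pts.reshape(-1, 3), source="observed",
                   cell_ids=cells)
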