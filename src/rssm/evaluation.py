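"""Decomposition-quality metrics.

Intensity profiles along a line segment (with bilinear interpolation) and
their Pearson correlation quantify how faithfully the estimated foreground
follows the true signal.  Detected point sets (soma centres, traced
skeleton samples) are scored against a manually annotated gold standard by
distance matching: a detected point counts as a true positive when its
nearest gold point lies strictly within the matching radius (6 um by
convention), judged per point against the full gold set rather than by
one-to-one assignment.  Precision, recall and the F1 score (their harmonic
mean) summarise the match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["PointSet", "MatchResult", "intensity_profile",
           "pearson_correlation", "match_points", "f1_from_pr",
           "round_half_away", "read_points", "write_points"]


@dataclass(frozen=True)
class PointSet:
    """Coordinates in micrometres (already scaled by voxel spacing)."""

    points: np.ndarray
    label: str = "detected"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ValueError(f"points must be N x 2 or N x 3, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def intensity_profile(img: np.ndarray, start, end, n_samples: int = 100
                      ) -> np.ndarray:
    """Bilinear samples at ``n_samples`` evenly spaced points on the segment
    from ``start`` to ``end`` (inclusive), coordinates as (row, col)."""
    img = np.asarray(img, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if img.ndim != 2 or start.shape != (2,) or end.shape != (2,):
        raise ValueError("expected a 2D image and 2D endpoints")
    hi = np.asarray(img.shape) - 1
    for p in (start, end):
        if np.any(p < 0) or np.any(p > hi):
            raise ValueError(f"endpoint {tuple(p)} outside image {img.shape}")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def pearson_correlation(a, b) -> float:
    """Pearson r; two constant inputs give 0 with a warning."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 and nb == 0:
        warnings.warn("both inputs constant; correlation undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(da, db) / (na * nb), -1.0, 1.0))


def match_points(detected: PointSet, gold: PointSet, radius_um: float = 6.0,
                 one_to_one: bool = False) -> MatchResult:
    """Distance matching of detected points against a gold standard.

    Default rule: each detected point is a TP iff its nearest gold point is
    strictly within ``radius_um`` (many detected points may match one gold
    point); a gold point is missed (FN) when no detected point lies within
    the radius.  ``one_to_one=True`` instead assigns greedily by increasing
    distance, each gold point consumed at most once — useful for counting
    somas, where duplicates would inflate precision.
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    if len(detected) and len(gold) and detected.dim != gold.dim:
        raise ValueError(f"dimensionality mismatch: {detected.dim} vs {gold.dim}")
    nd, ng = len(detected), len(gold)
    if nd == 0 or ng == 0:
        tp = 0
        fp, fn = nd, ng
    elif one_to_one:
        d2 = np.linalg.norm(
            detected.points[:, None, :] - gold.points[None, :, :], axis=-1)
        pairs = sorted(
            ((d2[i, j], i, j) for i in range(nd) for j in range(ng)
             if d2[i, j] < radius_um),
            key=lambda t: t[0])
        used_d, used_g = set(), set()
        for _, i, j in pairs:
            if i not in used_d and j not in used_g:
                used_d.add(i)
                used_g.add(j)
        tp = len(used_d)
        fp, fn = nd - tp, ng - tp
    else:
        tree = cKDTree(gold.points)
        dist, _ = tree.query(detected.points)
        tp = int(np.count_nonzero(dist < radius_um))
        fp = nd - tp
        dtree = cKDTree(detected.points)
        gdist, _ = dtree.query(gold.points)
        fn = int(np.count_nonzero(gdist >= radius_um))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    # recall is gold-sided: the fraction of gold points that were found.
    # Under the per-point rule tp counts detected points (many-to-one), so
    # tp/(tp+fn) would overstate recall when several detections share one
    # gold point.
    recall = (ng - fn) / ng if ng else 0.0
    return MatchResult(tp=tp, fp=fp, fn=fn, precision=precision,
                       recall=recall, f1=f1_from_pr(precision, recall))


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean ``2pr / (p + r)``; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    s = precision + recall
    return 2.0 * precision * recall / s if s > 0 else 0.0


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report-display convention)."""
    factor = 10 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def read_points(path) -> tuple[PointSet, tuple[float, ...]]:
    """Read a tab-separated point file: header ``# spacing: sx sy [sz]``
    then one ``x y [z]`` voxel-coordinate line per point.  Returns the set
    scaled to micrometres."""
    spacing: tuple[float, ...] | None = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "spacing:" in line:
                    spacing = tuple(
                        float(v) for v in line.split("spacing:")[1].split())
                continue
            rows.append([float(v) for v in line.split("\t")])
    pts = np.asarray(rows, dtype=float)
    if pts.size == 0:
        pts = pts.reshape(0, 2)
    if spacing is None:
        spacing = (1.0,) * pts.shape[1]
    return PointSet(points=pts * np.asarray(spacing)), spacing


def write_points(path, points: np.ndarray,
                 spacing: tuple[float, ...] = (1.0, 1.0)) -> None:
    """Write voxel-coordinate points with a spacing header."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    with open(path, "w") as fh:
        fh.write("# spacing: " + " ".join(str(s) for s in spacing) + "\n")
        for row in points:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
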