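"""Simulation box, membrane microdomains, and boundary handling.

The membrane plane is periodic in x and y; the cytosolic z coordinate is
reflective.  Microdomains are closed polygonal contours that transiently
confine receptors: a receptor whose Brownian jump crosses its contour from
the inside escapes with a fixed per-crossing probability (0.2 for pre-B
cells) and is otherwise reflected specularly back inside.  Entry from the
outside is unimpeded, and only receptors/aggregates observe domains — Lyn
and Syk diffuse freely.

Domain maps come from one of two sources: a synthetic generator
(:func:`generate_synthetic_domains`, non-overlapping disk-like polygons),
or reconstruction from single-particle-tracking (SPT) trajectories
(:func:`reconstruct_domains`): trajectory points are ranked slow/fast by
their jump sizes over a set of time lags, slow points are single-linkage
clustered with linking distance ``L``, and each sufficiently large cluster
is contoured by its convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
import shapely.geometry as sgeom
import shapely.wkt

from ._kernel import (
    N_COUNTERS,
    _confine_move,
    _find_domain,
    _fold,
    _point_in_poly,
)


class LandscapeError(ValueError):
    pass


@dataclass
class DomainMap:
    """A set of closed membrane contours sharing one exit probability.

    ``contours`` are (K, 2) vertex arrays in μm, counter-clockwise or
    clockwise, without a repeated closing vertex.
    """

    contours: list[np.ndarray] = field(default_factory=list)
    exit_probability: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.exit_probability <= 1.0:
            raise LandscapeError(
                f"exit_probability must be in [0, 1], got {self.exit_probability}"
            )
        self.contours = [np.asarray(c, dtype=float) for c in self.contours]
        for c in self.contours:
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise LandscapeError("each contour needs >= 3 (x, y) vertices")

    def __len__(self) -> int:
        return len(self.contours)

    def polygons(self) -> list[sgeom.Polygon]:
        return [sgeom.Polygon(c) for c in self.contours]

    def validate(self, box: tuple[float, float] | None = None) -> None:
        """Check contours are simple, pairwise disjoint, and inside the box."""
        polys = self.polygons()
        for i, p in enumerate(polys):
            if not p.is_valid or p.area <= 0:
                raise LandscapeError(f"contour {i} is not a simple polygon")
            if box is not None:
                minx, miny, maxx, maxy = p.bounds
                if minx < 0 or miny < 0 or maxx > box[0] or maxy > box[1]:
                    raise LandscapeError(f"contour {i} extends outside the box")
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersects(polys[j]):
                    raise LandscapeError(f"contours {i} and {j} overlap")

    def packed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flatten contours for the numba kernel:
        (vertex_x, vertex_y, offsets, bounding_boxes)."""
        if not self.contours:
            return (np.zeros(0), np.zeros(0), np.zeros(1, dtype=np.int64),
                    np.zeros((0, 4)))
        xs = np.concatenate([c[:, 0] for c in self.contours])
        ys = np.concatenate([c[:, 1] for c in self.contours])
        off = np.zeros(len(self.contours) + 1, dtype=np.int64)
        np.cumsum([len(c) for c in self.contours], out=off[1:])
        bb = np.array(
            [[c[:, 0].min(), c[:, 1].min(), c[:, 0].max(), c[:, 1].max()]
             for c in self.contours]
        )
        return xs, ys, off, bb

    def locate(self, x: float, y: float) -> int:
        """Index of the contour containing (x, y), or -1."""
        xs, ys, off, bb = self.packed()
        if len(self.contours) == 0:
            return -1
        return int(_find_domain(x, y, xs, ys, off, bb))

    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons()))

    # -- plain-text serialization: header + one WKT polygon per line -------

    def to_text(self) -> str:
        lines = [f"# exit_probability {self.exit_probability}"]
        for p in self.polygons():
            lines.append(shapely.wkt.dumps(p, rounding_precision=9))
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "DomainMap":
        exit_p = 0.2
        contours = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "exit_probability":
                    exit_p = float(parts[1])
                continue
            poly = shapely.wkt.loads(line)
            contours.append(np.asarray(poly.exterior.coords)[:-1])
        return cls(contours=contours, exit_probability=exit_p)

    @classmethod
    def load(cls, path: str | Path) -> "DomainMap":
        return cls.from_text(Path(path).read_text())


@dataclass
class SptTrajectorySet:
    """Tabular single-particle trajectories: track_id, t (s), x, y (μm).

    ``in_domain`` optionally carries per-point ground-truth membership for
    synthetic fixtures.
    """

    frame: pd.DataFrame
    in_domain: np.ndarray | None = None

    def __post_init__(self) -> None:
        req = {"track_id", "t", "x", "y"}
        if not req.issubset(self.frame.columns):
            raise LandscapeError(f"SPT table needs columns {sorted(req)}")
        for _, g in self.frame.groupby("track_id"):
            t = g["t"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise LandscapeError("frame times must strictly increase per track")

    def save(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SptTrajectorySet":
        df = pd.read_csv(path)
        if df.empty:
            raise LandscapeError(f"SPT file {path} is empty")
        return cls(frame=df)


# --------------------------------------------------------------------------
# Boundary operations
# --------------------------------------------------------------------------


def wrap_periodic(position: Sequence[float], box: Sequence[float]) -> np.ndarray:
    """Map coordinates into [0, box) by modular arithmetic (periodic edges)."""
    pos = np.asarray(position, dtype=float)
    b = np.asarray(box, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise LandscapeError("non-finite position")
    out = np.mod(pos, b)
    # tiny negative inputs can round the modulus up to the box length itself
    out[out >= b] = 0.0
    return out


def reflect_z(z: float, depth: float) -> float:
    """Mirror a z coordinate into [0, depth] (reflective boundary)."""
    if not np.isfinite(z):
        raise LandscapeError("non-finite z")
    return float(_fold(z, depth))


def confine_step(
    start: Sequence[float],
    jump: Sequence[float],
    domains: DomainMap,
    rng: np.random.Generator,
    box: tuple[float, float] = (1.5, 1.5),
) -> np.ndarray:
    """One confined Brownian jump for a receptor/aggregate point.

    If ``start`` lies inside a contour and the segment start -> start+jump
    crosses it, the jump is split at the crossing; with probability
    ``domains.exit_probability`` the remainder continues outside, otherwise
    it is reflected back inside.  Entry from outside is unimpeded.
    """
    x0, y0 = float(start[0]), float(start[1])
    if not (0 <= x0 <= box[0] and 0 <= y0 <= box[1]):
        raise LandscapeError(f"start {start} outside the box {box}")
    xs, ys, off, bb = domains.packed()
    counters = np.zeros(N_COUNTERS, dtype=np.int64)
    dom = domains.locate(x0, y0) if len(domains) else -1
    if dom >= 0:
        x1, y1, _nd = _confine_move(x0, y0, float(jump[0]), float(jump[1]),
                                    dom, xs, ys, off,
                                    domains.exit_probability, rng, counters)
    else:
        x1 = x0 + float(jump[0])
        y1 = y0 + float(jump[1])
    return wrap_periodic((x1, y1), box)


# --------------------------------------------------------------------------
# Synthetic landscape fixtures
# --------------------------------------------------------------------------


def generate_synthetic_domains(
    box: tuple[float, float],
    n_domains: int,
    radius_range: tuple[float, float],
    seed: int,
    n_vertices: int = 16,
    exit_probability: float = 0.2,
    max_tries: int = 2000,
) -> DomainMap:
    """Place non-overlapping regular polygons (disk approximations)
    uniformly at random inside the box.  Deterministic for a fixed seed."""
    if n_domains < 0:
        raise LandscapeError("n_domains must be >= 0")
    rmin, rmax = radius_range
    if rmin <= 0 or rmax < rmin:
        raise LandscapeError("invalid radius_range")
    if 2 * rmax >= min(box):
        raise LandscapeError("radii do not fit in the box")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float, float]] = []
    contours = []
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    tries = 0
    while len(contours) < n_domains:
        if tries >= max_tries:
            raise LandscapeError(
                f"could not place {n_domains} non-overlapping domains "
                f"after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(rmin, rmax)
        cx = rng.uniform(r, box[0] - r)
        cy = rng.uniform(r, box[1] - r)
        if any((cx - ox) ** 2 + (cy - oy) ** 2 < (r + orad) ** 2
               for ox, oy, orad in centers):
            continue
        centers.append((cx, cy, r))
        contours.append(
            np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        )
    return DomainMap(contours=contours, exit_probability=exit_probability)


def generate_synthetic_spt(
    domains: DomainMap,
    d_free: float,
    n_tracks: int,
    frames: int,
    frame_dt: float,
    seed: int,
    box: tuple[float, float] = (1.5, 1.5),
    n_substeps: int = 10,
) -> SptTrajectorySet:
    """Brownian SPT tracks obeying domain confinement, with ground truth.

    Each frame interval is integrated in ``n_substeps`` confined Brownian
    sub-steps.  The box boundary is reflective here (a microscope field of
    view is not periodic, and wrap-around jumps would corrupt the
    jump-size statistics the reconstruction relies on).  Per-point
    ground-truth domain membership is retained for recovery scoring.
    """
    if d_free <= 0 or n_tracks <= 0 or frames <= 0 or frame_dt <= 0:
        raise LandscapeError("generator parameters must be positive")
    rng = np.random.default_rng(seed)
    xs, ys, off, bb = domains.packed()
    n_poly = len(domains)
    counters = np.zeros(N_COUNTERS, dtype=np.int64)
    sub_dt = frame_dt / n_substeps
    rms = float(np.sqrt(2.0 * d_free * sub_dt))
    rows_track = np.repeat(np.arange(n_tracks), frames)
    rows_t = np.tile(np.arange(frames) * frame_dt, n_tracks)
    rows_x = np.empty(n_tracks * frames)
    rows_y = np.empty(n_tracks * frames)
    in_dom = np.empty(n_tracks * frames, dtype=np.int64)
    k = 0
    for _ in range(n_tracks):
        x = rng.uniform(0, box[0])
        y = rng.uniform(0, box[1])
        dom = int(_find_domain(x, y, xs, ys, off, bb)) if n_poly else -1
        for _f in range(frames):
            rows_x[k] = x
            rows_y[k] = y
            in_dom[k] = dom
            k += 1
            for _s in range(n_substeps):
                jx = rms * rng.standard_normal()
                jy = rms * rng.standard_normal()
                if dom >= 0:
                    x, y, nd = _confine_move(
                        x, y, jx, jy, dom, xs, ys, off,
                        domains.exit_probability, rng, counters)
                else:
                    x, y, nd = x + jx, y + jy, -2
                x = float(_fold(x, box[0]))
                y = float(_fold(y, box[1]))
                if nd == -2:
                    dom = int(_find_domain(x, y, xs, ys, off, bb)) if n_poly else -1
                else:
                    dom = nd
    df = pd.DataFrame(
        {"track_id": rows_track, "t": rows_t, "x": rows_x, "y": rows_y}
    )
    return SptTrajectorySet(frame=df, in_domain=in_dom)


# --------------------------------------------------------------------------
# Domain reconstruction from trajectories
# --------------------------------------------------------------------------


def reconstruct_domains(
    trajectories: SptTrajectorySet,
    L: float = 0.1,
    lag_set: Iterable[float] | None = None,
    slow_threshold: float = 0.5,
    min_cluster_size: int = 10,
    exit_probability: float = 0.2,
) -> DomainMap:
    """Reconstruct confining microdomains from SPT trajectories.

    Per trajectory point, the jump size over each lag in ``lag_set``
    (seconds) is computed; a point is labelled *slow* (confined) when its
    jump size falls below the ``slow_threshold`` quantile of all points for
    every lag.  Slow points are clustered by single linkage with linking
    distance ``L`` (μm) and each cluster of at least ``min_cluster_size``
    points with >= 3 distinct positions becomes a convex-hull contour.
    """
    df = trajectories.frame
    if df.empty:
        raise LandscapeError("empty trajectory set")
    if not 0 < slow_threshold <= 1:
        raise LandscapeError("slow_threshold must be a quantile in (0, 1]")

    pts = []
    jumps_per_lag: list[list[np.ndarray]] = []
    lag_frames = None
    for _, g in df.groupby("track_id"):
        g = g.sort_values("t")
        xy = g[["x", "y"]].to_numpy()
        t = g["t"].to_numpy()
        if len(t) < 2:
            continue
        frame_dt = float(np.median(np.diff(t)))
        if lag_set is None:
            lags = [1, 2, 3]
        else:
            lags = [max(1, int(round(lag / frame_dt))) for lag in lag_set]
        if lag_frames is None:
            lag_frames = lags
            jumps_per_lag = [[] for _ in lags]
        max_lag = max(lags)
        n_pts = len(t) - max_lag
        if n_pts < 1:
            continue
        pts.append(xy[:n_pts])
        for i, lf in enumerate(lags):
            d = np.linalg.norm(xy[lf:lf + n_pts] - xy[:n_pts], axis=1)
            jumps_per_lag[i].append(d)
    if not pts:
        raise LandscapeError(
            "no track is long enough for the requested lag set"
        )
    points = np.concatenate(pts)
    slow = np.ones(len(points), dtype=bool)
    for per_track in jumps_per_lag:
        jumps = np.concatenate(per_track)
        slow &= jumps < np.quantile(jumps, slow_threshold)

    slow_pts = points[slow]
    contours = []
    if len(slow_pts) >= max(min_cluster_size, 3):
        # single-linkage clustering with linking distance L
        if len(slow_pts) > 1:
            z = linkage(pdist(slow_pts), method="single")
            labels = fcluster(z, t=L, criterion="distance")
        else:
            labels = np.ones(1, dtype=int)
        for lbl in np.unique(labels):
            cluster = slow_pts[labels == lbl]
            if len(cluster) < min_cluster_size:
                continue
            distinct = np.unique(cluster, axis=0)
            if len(distinct) < 3:
                continue
            try:
                hull = ConvexHull(distinct)
            except Exception:
                continue  # collinear degenerate cluster
            contours.append(distinct[hull.vertices])
    return DomainMap(contours=contours, exit_probability=exit_probability)


def domain_recovery_score(
    reconstructed: DomainMap, truth: DomainMap
) -> list[float]:
    """Best-match Jaccard overlap (intersection over union of areas) of
    each ground-truth contour against the reconstructed contours."""
    rec_polys = reconstructed.polygons()
    scores = []
    for tp in truth.polygons():
        best = 0.0
        for rp in rec_polys:
            inter = tp.intersection(rp).area
            union = tp.union(rp).area
            if union > 0:
                best = max(best, inter / union)
        scores.append(best)
    return scores
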