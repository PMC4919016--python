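"""Synthetic plant point patterns and their spatial characterisation.

This module generates the three canonical stand structures used in
plotless-sampling studies — complete spatial randomness, cluster
aggregation and hard-core (sequential inhibition) regularity — inside a
rectangular window, quantifies them with the Clark–Evans
nearest-neighbour aggregation index, and reads/writes stem maps as plain
``x,y`` CSV files (coordinates in meters).

The population a generator returns is the "true" stand a virtual survey
is later run against: its density (stems per hectare) is known exactly,
which is what makes Monte Carlo accuracy assessment of the estimators
possible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import (
    InsufficientPointsError,
    InvalidSpecError,
    PackingFailureError,
    PatternCSVError,
)

__all__ = [
    "Window",
    "PointPattern",
    "PatternSpec",
    "generate",
    "generate_random",
    "generate_aggregated",
    "generate_regular",
    "clark_evans_index",
    "read_pattern_csv",
    "write_pattern_csv",
]

M2_PER_HECTARE = 10_000.0

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


@dataclasses.dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular survey window, closed on all sides (meters)."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise InvalidSpecError(
                f"window must have positive extent, got "
                f"[{self.xmin}, {self.xmax}] x [{self.ymin}, {self.ymax}]"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        """Area in square meters."""
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        return self.area / M2_PER_HECTARE

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) lying inside or on the boundary."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )

    def trimmed(self, fraction: float) -> "Window":
        """Shrink by ``fraction`` of each extent from *every* edge.

        ``fraction=0.10`` leaves the central 80% x 80% rectangle — the
        interior a survey restricts its sample points to so that
        quadrant distances are not truncated by the plot edge.
        """
        if not 0.0 <= fraction < 0.5:
            raise InvalidSpecError(
                f"boundary fraction must be in [0, 0.5), got {fraction}"
            )
        dx = fraction * self.width
        dy = fraction * self.height
        return Window(self.xmin + dx, self.xmax - dx, self.ymin + dy, self.ymax - dy)

    @classmethod
    def from_size(cls, width: float, height: float) -> "Window":
        return cls(0.0, float(width), 0.0, float(height))


@dataclasses.dataclass(frozen=True, eq=False)
class PointPattern:
    """A fixed set of tree positions in a window — the population surveyed.

    ``true_density`` is the exact stand density in stems per hectare,
    the quantity every estimator in this package tries to recover.
    """

    points: np.ndarray
    window: Window

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidSpecError(f"points must have shape (n, 2), got {pts.shape}")
        if not self.window.contains(pts).all():
            raise InvalidSpecError("some points lie outside the window")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def true_density(self) -> float:
        """Stems per hectare: count / area(m^2) x 10,000."""
        return self.n / self.window.area * M2_PER_HECTARE


@dataclasses.dataclass(frozen=True)
class PatternSpec:
    """Everything needed to generate one synthetic population.

    Parameters
    ----------
    kind : {'random', 'aggregated', 'regular'}
    n : int
        Exact number of trees to place.
    window : Window
    cluster_radius : float, aggregated only
        Disc radius (m) within which clustered offspring fall.
    intensity : float in [0, 1], aggregated only
        Fraction of the population that belongs to clusters; the rest is
        uniform background.
    repulsion : float >= 0, regular only
        Hard-core minimum distance (m) between any two trees.
    mean_cluster_size : float
        Expected trees per cluster; fixes the cluster count as
        ``max(1, round(intensity * n / mean_cluster_size))``.
    seed : int, SeedSequence, Generator or None
        Source of randomness; identical spec + seed reproduces the
        pattern bit-for-bit.
    """

    kind: str
    n: int
    window: Window
    cluster_radius: float | None = None
    intensity: float | None = None
    repulsion: float | None = None
    mean_cluster_size: float = 10.0
    seed: SeedLike = None

    def __post_init__(self):
        if self.kind not in ("random", "aggregated", "regular"):
            raise InvalidSpecError(f"unknown pattern kind {self.kind!r}")
        if self.n < 1:
            raise InvalidSpecError(f"n must be >= 1, got {self.n}")
        if self.kind == "aggregated":
            if self.cluster_radius is None or not self.cluster_radius > 0:
                raise InvalidSpecError(
                    f"aggregated pattern needs cluster_radius > 0, "
                    f"got {self.cluster_radius}"
                )
            if self.intensity is None or not 0.0 <= self.intensity <= 1.0:
                raise InvalidSpecError(
                    f"aggregation intensity must be in [0, 1], got {self.intensity}"
                )
            if not self.mean_cluster_size > 0:
                raise InvalidSpecError("mean_cluster_size must be > 0")
        if self.kind == "regular":
            if self.repulsion is None or self.repulsion < 0:
                raise InvalidSpecError(
                    f"regular pattern needs repulsion >= 0, got {self.repulsion}"
                )


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _uniform_in(window: Window, n: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    return np.column_stack([x, y])


def generate(spec: PatternSpec) -> PointPattern:
    """Dispatch to the generator matching ``spec.kind``."""
    return {
        "random": generate_random,
        "aggregated": generate_aggregated,
        "regular": generate_regular,
    }[spec.kind](spec)


def generate_random(spec: PatternSpec) -> PointPattern:
    """Binomial pattern: exactly n points i.i.d. uniform over the window."""
    if spec.kind != "random":
        raise InvalidSpecError(f"spec.kind is {spec.kind!r}, expected 'random'")
    rng = _rng(spec.seed)
    return PointPattern(_uniform_in(spec.window, spec.n, rng), spec.window)


def generate_aggregated(spec: PatternSpec) -> PointPattern:
    """Cluster pattern: a clustered fraction plus uniform background.

    ``round(intensity * n)`` points are attached to cluster centres that
    are themselves uniform in the window; each offspring is uniform on a
    disc of ``cluster_radius`` around its centre and is redrawn until it
    falls inside the window (no clipping, which would pile mass on the
    boundary). The remaining points are uniform background, so the total
    count is exactly n.
    """
    if spec.kind != "aggregated":
        raise InvalidSpecError(f"spec.kind is {spec.kind!r}, expected 'aggregated'")
    rng = _rng(spec.seed)
    w = spec.window
    n_clustered = int(round(spec.intensity * spec.n))
    n_background = spec.n - n_clustered

    parts = []
    if n_clustered > 0:
        n_clusters = max(1, int(round(n_clustered / spec.mean_cluster_size)))
        centres = _uniform_in(w, n_clusters, rng)
        assignment = rng.integers(0, n_clusters, n_clustered)
        pts = np.empty((n_clustered, 2))
        todo = np.arange(n_clustered)
        while todo.size:
            r = spec.cluster_radius * np.sqrt(rng.random(todo.size))
            theta = rng.uniform(0.0, 2.0 * math.pi, todo.size)
            cand = centres[assignment[todo]] + np.column_stack(
                [r * np.cos(theta), r * np.sin(theta)]
            )
            ok = w.contains(cand)
            pts[todo[ok]] = cand[ok]
            todo = todo[~ok]
        parts.append(pts)
    if n_background > 0:
        parts.append(_uniform_in(w, n_background, rng))
    points = np.concatenate(parts) if parts else np.empty((0, 2))
    return PointPattern(points, w)


# Consecutive rejected proposals tolerated per requested point before the
# sequential-inhibition generator declares the spec unpackable.
_SSI_ATTEMPTS_PER_POINT = 1000
_SSI_BATCH = 1024


def generate_regular(spec: PatternSpec) -> PointPattern:
    """Hard-core pattern by simple sequential inhibition.

    Uniform proposals are accepted only if they lie at least
    ``repulsion`` meters from every previously accepted point, so the
    minimum pairwise distance of the result is guaranteed. Acceptance is
    checked against a spatial hash grid (cell side = repulsion), keeping
    each test O(1). After ``1000 * n`` consecutive rejections the spec
    is declared infeasible.
    """
    if spec.kind != "regular":
        raise InvalidSpecError(f"spec.kind is {spec.kind!r}, expected 'regular'")
    rng = _rng(spec.seed)
    w = spec.window
    r = float(spec.repulsion)
    if r == 0.0:
        return PointPattern(_uniform_in(w, spec.n, rng), w)

    r2 = r * r
    inv_cell = 1.0 / r
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    accepted: list[tuple[float, float]] = []
    cap = _SSI_ATTEMPTS_PER_POINT * spec.n
    consecutive = 0
    attempts = 0

    while len(accepted) < spec.n:
        xs = rng.uniform(w.xmin, w.xmax, _SSI_BATCH)
        ys = rng.uniform(w.ymin, w.ymax, _SSI_BATCH)
        for x, y in zip(xs, ys):
            attempts += 1
            cx = int((x - w.xmin) * inv_cell)
            cy = int((y - w.ymin) * inv_cell)
            ok = True
            for gx in (cx - 1, cx, cx + 1):
                for gy in (cy - 1, cy, cy + 1):
                    for px, py in grid.get((gx, gy), ()):
                        if (x - px) ** 2 + (y - py) ** 2 < r2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                accepted.append((x, y))
                grid.setdefault((cx, cy), []).append((x, y))
                consecutive = 0
                if len(accepted) == spec.n:
                    break
            else:
                consecutive += 1
                if consecutive >= cap:
                    raise PackingFailureError(
                        f"could not place {spec.n} points with repulsion "
                        f"{r} m: {len(accepted)} placed after {attempts} "
                        f"proposals ({consecutive} consecutive rejections)",
                        attempts=attempts,
                        placed=len(accepted),
                    )
    return PointPattern(np.array(accepted), w)


def clark_evans_index(pattern: PointPattern) -> float:
    """Clark–Evans aggregation index R, without edge correction.

    R = (mean nearest-neighbour distance) / (0.5 / sqrt(lambda)), with
    lambda the observed intensity in points per m^2. Under complete
    spatial randomness R is about 1; R < 1 indicates aggregation and
    R > 1 regularity.
    """
    if pattern.n < 2:
        raise InsufficientPointsError(
            f"Clark-Evans index needs >= 2 points, got {pattern.n}"
        )
    tree = cKDTree(pattern.points)
    dist, _ = tree.query(pattern.points, k=2)
    mean_nn = dist[:, 1].mean()
    lam = pattern.n / pattern.window.area
    return mean_nn / (0.5 / math.sqrt(lam))


def write_pattern_csv(pattern: PointPattern, path) -> None:
    """Write a stem map as ``x,y`` CSV (meters), full double precision."""
    df = pd.DataFrame({"x": pattern.points[:, 0], "y": pattern.points[:, 1]})
    df.to_csv(path, index=False, float_format="%.17g")


def read_pattern_csv(path, window: Window) -> PointPattern:
    """Read a stem map CSV (header ``x,y``) into a PointPattern.

    Raises :class:`PatternCSVError` (with the offending 1-based file
    line where applicable) for missing columns, non-numeric cells,
    points outside the window, or an empty body.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise PatternCSVError(f"{path}: file is empty (no header)") from None
    missing = [c for c in ("x", "y") if c not in df.columns]
    if missing:
        raise PatternCSVError(f"{path}: missing column(s) {', '.join(missing)}", row=1)
    if len(df) == 0:
        raise PatternCSVError(f"{path}: header only, no points")
    coords = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise PatternCSVError(
            f"{path}: non-numeric coordinate at line {i + 2}", row=i + 2
        )
    xy = coords.to_numpy(dtype=float)
    inside = window.contains(xy)
    if not inside.all():
        i = int(np.flatnonzero(~inside)[0])
        raise PatternCSVError(
            f"{path}: point {tuple(xy[i])} at line {i + 2} lies outside "
            f"the window",
            row=i + 2,
        )
    return PointPattern(xy, window)
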