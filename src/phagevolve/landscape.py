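"""2-D genomic-space embedding and per-host fitness surfaces.

Populations are placed on a plane ("genomic space", axes GS1/GS2) from the
genotypic Euclidean distance matrix — by deterministic classical metric
scaling (PCoA) by default, or t-SNE behind a flag.  Per-host fitness of a
population is the reciprocal of its infectivity on that host at the high
virus-per-cell ratio (faster culture decline = higher fitness).  Fitness
values are interpolated over a regular grid spanning the embedding with
inverse-distance weighting (IDW), optionally followed by a thin-plate-style
penalized smoothing fit.  All hosts share one identical GS1~GS2 plane; the
surfaces differ only in Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenotype import InfectivityProfile
from .trees import DistanceMatrix

__all__ = [
    "EmbeddingResult",
    "FitnessLandscape",
    "embed_2d",
    "fitness_from_infectivity",
    "interpolate_surface",
    "landscape_report",
]


@dataclass
class EmbeddingResult:
    coords: dict[str, tuple[float, float]]   # population -> (GS1, GS2)
    method: str
    diagnostic: float       # explained-variance fraction (pcoa) or KL (tsne)
    seed: int | None = None

    def array(self, order: list[str] | None = None) -> np.ndarray:
        order = order or sorted(self.coords)
        return np.array([self.coords[k] for k in order])


def embed_2d(dm: DistanceMatrix, method: str = "pcoa", seed: int = 0,
             perplexity: float = 5.0) -> EmbeddingResult:
    """Embed populations on the GS1~GS2 plane from a distance matrix.

    ``pcoa``: classical metric scaling of the double-centered squared
    distances; deterministic, axes ordered by eigenvalue, each axis's sign
    fixed so its largest-magnitude loading is positive.  Exact for distance
    matrices realizable in the plane.  ``tsne``: stochastic neighbor
    embedding at the given seed and perplexity.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 populations to embed")
    if method == "pcoa":
        d2 = dm.d ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        evals, evecs = np.linalg.eigh(b)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        coords = np.zeros((n, 2))
        for ax in range(2):
            lam = max(evals[ax], 0.0)
            v = evecs[:, ax] * np.sqrt(lam)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, ax] = v
        pos = evals[evals > 0].sum()
        diag = float(evals[:2].clip(min=0).sum() / pos) if pos > 0 else 0.0
        return EmbeddingResult(
            {lab: (float(x), float(y)) for lab, (x, y) in zip(dm.labels, coords)},
            "pcoa", diag)
    if method == "tsne":
        from sklearn.manifold import TSNE
        ts = TSNE(n_components=2, metric="precomputed", init="random",
                  random_state=seed, perplexity=min(perplexity, (n - 1) / 3))
        xy = ts.fit_transform(dm.d)
        return EmbeddingResult(
            {lab: (float(x), float(y)) for lab, (x, y) in zip(dm.labels, xy)},
            "tsne", float(ts.kl_divergence_), seed=seed)
    raise ValueError(f"unknown embedding method {method!r}")


def fitness_from_infectivity(profile: InfectivityProfile, host: str,
                             vpc: float = 3.0) -> float:
    """Fitness Z = 1 / infectivity on ``host`` at the given ratio."""
    inf = profile.value_at(host, vpc)
    if inf <= 0:
        raise ValueError(
            f"infectivity 0 on host {host}: fitness diverges (complete lysis); "
            "cap the infectivity before calling")
    return 1.0 / inf


@dataclass
class FitnessLandscape:
    host_id: str
    grid_x: np.ndarray            # GS1 axis nodes
    grid_y: np.ndarray            # GS2 axis nodes
    z: np.ndarray                 # (len(grid_y), len(grid_x)) surface
    points: dict[str, tuple[float, float, float]]  # pop -> (GS1, GS2, Z)
    smoothed: bool = False
    smoothing_residual: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.z).all():
            raise ValueError("non-finite surface values")


def interpolate_surface(coords: dict[str, tuple[float, float]],
                        z_values: dict[str, float],
                        host_id: str = "",
                        grid_resolution: int = 50,
                        power: float = 2.0,
                        smooth: bool = False,
                        smoothing: float = 1e-3) -> FitnessLandscape:
    """IDW interpolation of point fitness values over a regular grid.

    The grid spans the bounding box of *all* supplied coordinates.  A grid
    node coinciding with a data point takes that point's Z exactly; other
    nodes take the 1/d^power weighted mean, which keeps the surface inside
    [min Z, max Z].  ``smooth=True`` replaces the surface with a thin-plate
    spline fitted to the points under a roughness penalty (the residual sum
    of squares at the data points is recorded); smoothing trades the IDW
    exactness property for a visually smoother mesh.
    """
    names = [k for k in coords if k in z_values]
    if len(names) < 3:
        raise ValueError("need at least 3 points with fitness values")
    pts = np.array([coords[k] for k in names])
    z = np.array([z_values[k] for k in names])
    uniq: dict[tuple[float, float], float] = {}
    for (x, y), zz in zip(map(tuple, pts), z):
        if (x, y) in uniq and not np.isclose(uniq[(x, y)], zz):
            raise ValueError("duplicate coordinates with different Z")
        uniq[(x, y)] = zz

    allpts = np.array(list(coords.values()))
    gx = np.linspace(allpts[:, 0].min(), allpts[:, 0].max(), grid_resolution)
    gy = np.linspace(allpts[:, 1].min(), allpts[:, 1].max(), grid_resolution)
    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    d = np.sqrt(((nodes[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    surf = np.empty(len(nodes))
    hit = d < 1e-12
    exact = hit.any(axis=1)
    surf[exact] = z[np.argmax(hit[exact], axis=1)]
    with np.errstate(divide="ignore"):
        w = 1.0 / d[~exact] ** power
    surf[~exact] = (w * z).sum(axis=1) / w.sum(axis=1)
    zz_grid = surf.reshape(xx.shape)

    residual = None
    if smooth:
        from scipy.interpolate import RBFInterpolator
        rbf = RBFInterpolator(pts, z, kernel="thin_plate_spline",
                              smoothing=smoothing)
        zz_grid = rbf(nodes).reshape(xx.shape)
        residual = float(((rbf(pts) - z) ** 2).sum())

    points = {k: (float(coords[k][0]), float(coords[k][1]), float(z_values[k]))
              for k in names}
    return FitnessLandscape(host_id, gx, gy, zz_grid, points,
                            smoothed=smooth, smoothing_residual=residual)


def landscape_report(embedding: EmbeddingResult,
                     profiles: dict[str, InfectivityProfile],
                     host_of: dict[str, str],
                     ancestral_id: str = "ancestral",
                     vpc: float = 3.0,
                     grid_resolution: int = 50,
                     power: float = 2.0,
                     smooth: bool = False) -> dict:
    """Serializable landscape bundle: one fitness grid per host on a shared
    GS1~GS2 plane.

    Every population appears on the plane; per host, the on-surface point
    list is restricted to the ancestral population plus the populations
    evolved on that host (the others are off-surface context).  The surface
    itself is interpolated from *all* populations' fitness on that host.
    """
    missing = set(profiles) - set(embedding.coords)
    if missing:
        raise ValueError(f"profiles without embedding coordinates: {sorted(missing)}")
    hosts = sorted({h for (h, _v) in next(iter(profiles.values())).conditions})
    bundle: dict = {
        "embedding": {
            "method": embedding.method,
            "diagnostic": embedding.diagnostic,
            "coords": {k: list(v) for k, v in embedding.coords.items()},
        },
        "hosts": {},
    }
    for host in hosts:
        zvals = {p: fitness_from_infectivity(prof, host, vpc)
                 for p, prof in profiles.items()}
        ls = interpolate_surface(embedding.coords, zvals, host_id=host,
                                 grid_resolution=grid_resolution, power=power,
                                 smooth=smooth)
        on_surface = sorted(
            p for p in profiles
            if p == ancestral_id or host_of.get(p) == host)
        bundle["hosts"][host] = {
            "grid_x": ls.grid_x.tolist(),
            "grid_y": ls.grid_y.tolist(),
            "z": ls.z.tolist(),
            "points": {p: list(ls.points[p]) for p in ls.points},
            "on_surface": on_surface,
            "smoothed": ls.smoothed,
            "smoothing_residual": ls.smoothing_residual,
        }
    return bundle
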