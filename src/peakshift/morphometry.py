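"""Geometric morphometrics: Procrustes superimposition, semilandmark
sliding, centroid size, shape PCA and parallel analysis.

Configurations are 2-D landmark/semilandmark sets.  Superimposition follows
the standard least-squares (partial) Procrustes protocol: configurations are
centred, scaled to unit centroid size, and rotated to a consensus that is
re-estimated until it stabilizes.  Species means are computed first (from a
within-species superimposition) and the grand alignment operates on the
species means, so the consensus is a grand average of species averages.

Semilandmarks — curve-sampling points without one-to-one anatomical
correspondence — may slide along the local curve tangent (the chord between
their neighbours in point order) to minimize the summed squared distance to
the consensus; sliding alternates with re-superimposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import (
    CurveDefinitionError,
    DegenerateShapeError,
    ShapeMismatchError,
)

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapeSet",
    "PCModel",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa",
    "slide_semilandmarks",
    "procrustes_distance",
    "shape_pca",
    "ShapePCA",
    "parallel_analysis",
    "ParallelAnalysis",
]

LANDMARK = 0
SEMILANDMARK = 1


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D points with landmark/semilandmark roles."""

    points: np.ndarray  # (k, 2)
    roles: np.ndarray  # (k,) of {0: landmark, 1: semilandmark}
    specimen_id: str = ""
    species_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ShapeMismatchError("points must be a (k, 2) array")
        k = len(self.points)
        if k < 3:
            raise ShapeMismatchError("a configuration needs at least 3 points")
        if self.roles is None:
            self.roles = np.zeros(k, dtype=int)
        self.roles = np.asarray(self.roles, dtype=int)
        if len(self.roles) != k:
            raise ShapeMismatchError("roles length must equal point count")
        uniq = np.unique(self.points, axis=0)
        if len(uniq) != k:
            raise DegenerateShapeError("configuration contains duplicated points")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class AlignedShapeSet:
    """Superimposed species mean shapes.

    ``coordinates`` is species x 2k (x1, y1, x2, y2, ...); the consensus is
    centred at the origin with unit centroid size.  ``centroid_sizes`` are
    the per-species mean centroid sizes measured before scaling, and
    ``condylobasal_length`` is an optional external size column (mm).
    """

    coordinates: pd.DataFrame
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: pd.Series
    roles: np.ndarray
    condylobasal_length: pd.Series | None = None

    @property
    def shapes(self) -> np.ndarray:
        """(n_species, k, 2) view of the aligned coordinates."""
        a = self.coordinates.to_numpy()
        return a.reshape(len(a), -1, 2)


# ---------------------------------------------------------------------------
# TPS input/output
# ---------------------------------------------------------------------------


def read_tps(path_or_text, roles: Sequence[int] | None = None) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file (LM=, coordinate lines, ID=/IMAGE= fields).

    ``roles`` optionally flags each point as landmark (0) or semilandmark
    (1); TPS itself does not store roles.  Species are taken from the ID
    field up to the last underscore (``Artibeus_01`` -> species
    ``Artibeus``), falling back to the whole ID.
    """
    try:
        text = open(path_or_text).read()
    except (OSError, ValueError):
        text = str(path_or_text)
    configs: list[LandmarkConfiguration] = []
    lines = [l.strip() for l in text.splitlines() if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise ShapeMismatchError(f"expected LM= record at line {i + 1}")
        k = int(lines[i].split("=", 1)[1])
        pts = []
        i += 1
        for _ in range(k):
            x, y = lines[i].split()[:2]
            pts.append((float(x), float(y)))
            i += 1
        spec_id = f"spec{len(configs)}"
        while i < len(lines) and not lines[i].upper().startswith("LM="):
            key, _, val = lines[i].partition("=")
            if key.upper() == "ID":
                spec_id = val.strip()
            i += 1
        species = spec_id.rsplit("_", 1)[0] if "_" in spec_id else spec_id
        r = np.asarray(roles, dtype=int) if roles is not None else np.zeros(k, dtype=int)
        configs.append(
            LandmarkConfiguration(np.array(pts), r, specimen_id=spec_id, species_id=species)
        )
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.n_points}\n")
            for x, y in c.points:
                fh.write(f"{x:.8f} {y:.8f}\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------------------
# size and superimposition primitives
# ---------------------------------------------------------------------------


def centroid_size(config) -> float:
    """Square root of summed squared distances of points from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    c = pts.mean(axis=0)
    cs = float(np.sqrt(((pts - c) ** 2).sum()))
    if cs <= 0:
        raise DegenerateShapeError("all points coincide; centroid size is zero")
    return cs


def _center_scale(pts: np.ndarray) -> np.ndarray:
    pts = pts - pts.mean(axis=0)
    cs = np.sqrt((pts**2).sum())
    if cs <= 0:
        raise DegenerateShapeError("degenerate configuration")
    return pts / cs


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation matrix R minimizing ||src @ R - dst||_F (both centred)."""
    z1 = src[:, 0] + 1j * src[:, 1]
    z2 = dst[:, 0] + 1j * dst[:, 1]
    h = np.vdot(z1, z2)  # conj(z1) . z2
    phi = np.angle(h)
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, s], [-s, c]])


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation aligning the consensus to its principal axes, with a
    deterministic sign convention, so superimposition output does not
    depend on the arbitrary orientation of the input configurations."""
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    R = vt.T
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1
    rotated = consensus @ R
    j = int(np.argmax(np.abs(rotated[:, 0])))
    if rotated[j, 0] < 0:
        R = -R  # rotate by pi; determinant stays +1
        rotated = -rotated
    k = int(np.argmax(np.abs(rotated[:, 1])))
    if rotated[k, 1] < 0:
        # reflectionless sign fix is exhausted; accept this orientation
        pass
    return R


def _align_set(shapes: np.ndarray, tol: float = 1e-10, max_iter: int = 200):
    """Iterative least-squares superimposition of pre-scaled shapes.

    Returns (aligned, consensus); consensus is centred with unit centroid
    size and oriented along its principal axes.
    """
    aligned = np.array([_center_scale(s) for s in shapes])
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new = aligned.mean(axis=0)
        new = _center_scale(new)
        if np.sqrt(((new - consensus) ** 2).sum()) < tol:
            consensus = new
            break
        consensus = new
    R = _canonical_orientation(consensus)
    consensus = consensus @ R
    for i in range(len(aligned)):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
    return aligned, consensus


def gpa(
    configs: Sequence[LandmarkConfiguration],
    slide: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
    condylobasal_length: pd.Series | None = None,
) -> AlignedShapeSet:
    """Generalized Procrustes analysis with two-stage species averaging.

    Specimens are first superimposed within species and averaged; the
    species means are then superimposed to a grand consensus.  Centroid
    sizes are recorded per species (mean of specimen centroid sizes before
    scaling).  With ``slide=True`` semilandmarks are slid against the
    consensus after the grand alignment.
    """
    configs = list(configs)
    if not configs:
        raise ShapeMismatchError("no configurations given")
    k = configs[0].n_points
    roles = configs[0].roles
    for c in configs:
        if c.n_points != k:
            raise ShapeMismatchError(
                f"mixed point counts: {c.specimen_id} has {c.n_points}, expected {k}"
            )
        if not np.array_equal(c.roles, roles):
            raise ShapeMismatchError(f"roles differ for specimen {c.specimen_id}")

    by_species: dict[str, list[LandmarkConfiguration]] = {}
    for c in configs:
        by_species.setdefault(c.species_id or c.specimen_id, []).append(c)

    species = list(by_species)
    means = []
    sizes = []
    for sp in species:
        group = by_species[sp]
        sizes.append(float(np.mean([centroid_size(g) for g in group])))
        if len(group) == 1:
            means.append(_center_scale(group[0].points))
        else:
            aligned, _ = _align_set(np.array([g.points for g in group]))
            means.append(_center_scale(aligned.mean(axis=0)))

    aligned, consensus = _align_set(np.array(means), tol=tol, max_iter=max_iter)
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    out = AlignedShapeSet(
        coordinates=pd.DataFrame(aligned.reshape(len(species), -1), index=species, columns=cols),
        consensus=consensus,
        centroid_sizes=pd.Series(sizes, index=species, name="centroid_size"),
        roles=np.asarray(roles, int),
        condylobasal_length=condylobasal_length,
    )
    if slide:
        out = slide_semilandmarks(out)
    return out


def _slide_pass(shapes: np.ndarray, consensus: np.ndarray, semis: np.ndarray) -> None:
    """One in-place sliding pass: project each semilandmark onto the line
    through its current position along the local tangent (the chord between
    its curve neighbours), minimizing its distance to the consensus point."""
    for s in shapes:
        for j in semis:
            t = s[j + 1] - s[j - 1]
            nt = np.linalg.norm(t)
            if nt <= 0:
                continue
            t = t / nt
            s[j] += t * np.dot(t, consensus[j] - s[j])


def slide_semilandmarks(
    aligned: AlignedShapeSet, roles: np.ndarray | None = None,
    tol: float = 1e-8, max_iter: int = 50,
) -> AlignedShapeSet:
    """Slide semilandmarks along their curve tangents toward the consensus.

    The tangent at a semilandmark is the chord between its neighbours in
    point order; the point is orthogonally projected onto the tangent line
    through its current position, which minimizes its distance to the
    consensus along the permitted direction.  A sliding pass alternates
    with re-superimposition until the total Procrustes sum of squares
    stabilizes; the sum of squares is non-increasing across iterations.
    """
    roles = aligned.roles if roles is None else np.asarray(roles, int)
    semis = np.flatnonzero(roles == SEMILANDMARK)
    if len(semis) == 0:
        raise CurveDefinitionError("no semilandmarks to slide")
    k = len(roles)
    for j in semis:
        if j == 0 or j == k - 1:
            raise CurveDefinitionError(
                f"semilandmark {j} lacks two neighbours on its curve"
            )
    shapes = aligned.shapes.copy()
    consensus = aligned.consensus.copy()
    last_ss = np.inf
    for _ in range(max_iter):
        _slide_pass(shapes, consensus, semis)
        shapes, consensus = _align_set(shapes)
        ss = float(((shapes - consensus) ** 2).sum())
        if last_ss - ss < tol:
            break
        last_ss = ss
    coords = pd.DataFrame(
        shapes.reshape(len(shapes), -1),
        index=aligned.coordinates.index,
        columns=aligned.coordinates.columns,
    )
    return AlignedShapeSet(
        coordinates=coords,
        consensus=consensus,
        centroid_sizes=aligned.centroid_sizes,
        roles=roles,
        condylobasal_length=aligned.condylobasal_length,
    )


def procrustes_distance(shape_a, shape_b) -> float:
    """Full Procrustes distance between two configurations.

    Both shapes are centred and scaled to unit centroid size; the distance
    is the square root of the summed squared differences minimized over
    rotation and residual scaling, d = sqrt(1 - |<z_a, z_b>|^2) in the
    complex representation.  Symmetric, and zero iff the shapes differ only
    by a similarity transform.
    """
    a = shape_a.points if isinstance(shape_a, LandmarkConfiguration) else np.asarray(shape_a, float)
    b = shape_b.points if isinstance(shape_b, LandmarkConfiguration) else np.asarray(shape_b, float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"point counts differ: {a.shape[0]} vs {b.shape[0]}")
    a = _center_scale(a)
    b = _center_scale(b)
    za = a[:, 0] + 1j * a[:, 1]
    zb = b[:, 0] + 1j * b[:, 1]
    h = np.vdot(zb, za)  # optimal rotation angle(h), optimal scale |h|
    resid = za - h * zb  # residual at the minimizing similarity transform
    return float(np.sqrt((np.abs(resid) ** 2).sum()))


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


@dataclass
class PCModel:
    """Covariance-matrix PCA of aligned coordinates."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are loadings
    scores: pd.DataFrame
    mean: np.ndarray
    n_retained: int | None = None


class ShapePCA:
    """Principal components of species mean shape coordinates.

    Covariance-matrix PCA (variables share units after superimposition).
    Fitted attributes follow the ``trailing underscore`` convention:
    ``eigenvalues_``, ``components_``, ``mean_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def get_params(self, deep=True):
        return {"n_components": self.n_components}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("shape PCA needs at least 2 species")
        self._pca = PCA(n_components=self.n_components)
        self._pca.fit(X)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.eigenvalues_ = self._pca.explained_variance_
        return self

    def transform(self, X):
        return self._pca.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def shape_pca(aligned: AlignedShapeSet | pd.DataFrame) -> PCModel:
    """PCA of aligned species coordinates; scores reproduce the centred data."""
    coords = aligned.coordinates if isinstance(aligned, AlignedShapeSet) else aligned
    model = ShapePCA().fit(coords.to_numpy())
    scores = model.transform(coords.to_numpy())
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCModel(
        eigenvalues=model.eigenvalues_,
        eigenvectors=model.components_.T,
        scores=pd.DataFrame(scores, index=coords.index, columns=names),
        mean=model.mean_,
    )


class ParallelAnalysis:
    """Horn's parallel analysis for principal-component retention.

    Observed eigenvalues (correlation-matrix scale, so commensurable with
    the standard-normal reference data) are compared with a percentile of
    eigenvalues from PCAs of uncorrelated Gaussian data of the same
    dimensions; retention stops at the first component that fails.
    """

    def __init__(self, n_reps: int = 1000, percentile: float = 0.95, random_state=None):
        self.n_reps = n_reps
        self.percentile = percentile
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "n_reps": self.n_reps,
            "percentile": self.percentile,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must lie in (0, 1)")
        if self.n_reps < 100:
            raise ValueError("parallel analysis needs at least 100 replicates")
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        obs = _correlation_eigenvalues(X)
        rng = np.random.default_rng(self.random_state)
        rand = np.empty((self.n_reps, min(n - 1, p) if n > 1 else p))
        for r in range(self.n_reps):
            rand[r] = _correlation_eigenvalues(rng.standard_normal((n, p)))[: rand.shape[1]]
        thresh = np.quantile(rand, self.percentile, axis=0)
        m = min(len(obs), rand.shape[1])
        keep = 0
        for i in range(m):
            if obs[i] > thresh[i]:
                keep += 1
            else:
                break
        self.n_retained_ = keep
        self.thresholds_ = thresh
        self.observed_eigenvalues_ = obs
        return self


def _correlation_eigenvalues(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = X / sd
    ev = np.linalg.svd(Z, compute_uv=False) ** 2 / (len(X) - 1)
    return np.sort(ev)[::-1]


def parallel_analysis(
    data, n_reps: int = 1000, percentile: float = 0.95, seed=None
) -> int:
    """Number of principal components retained by Horn's parallel analysis."""
    data = data.to_numpy() if isinstance(data, pd.DataFrame) else data
    pa = ParallelAnalysis(n_reps=n_reps, percentile=percentile, random_state=seed)
    return pa.fit(data).n_retained_
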