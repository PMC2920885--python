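"""Per-residue upstream predictions: secondary structure and dihedral clusters.

The predictor consumes, for every residue, a three-state secondary
structure label (H/E/C) and a seven-state dihedral-cluster label.  In
production these come from an external predictor's output files; for the
self-contained path this module provides a centroid-based clustering of
(phi, psi) space under the toroidal metric, so cluster labels can be
derived from true or simulated dihedrals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import UpstreamPrediction

__all__ = [
    "DihedralClusterModel",
    "DEFAULT_CLUSTER_MODEL",
    "fit_clusters",
    "assign_cluster",
    "assign_clusters",
    "load_upstream",
    "save_upstream",
    "load_cluster_model",
    "save_cluster_model",
]


def _wrap(deg):
    """Fold angle differences into [-180, 180)."""
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


def toroidal_sq_dist(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Squared toroidal distance between (n,2) points and (k,2) centroids -> (n,k)."""
    d = _wrap(points[:, None, :] - centroids[None, :, :])
    return (d ** 2).sum(axis=2)


@dataclass
class DihedralClusterModel:
    """Seven centroids on the (phi, psi) torus with their training populations."""

    centroids: np.ndarray
    seed: int
    training_size: int
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.populations = np.asarray(self.populations, dtype=int)
        if self.centroids.shape != (len(self.populations), 2):
            raise ValueError("centroids and populations disagree in size")
        d = toroidal_sq_dist(self.centroids, self.centroids)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-12:
            raise ValueError("cluster centroids must be pairwise distinct")

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def most_populous(self) -> int:
        return int(np.argmax(self.populations))


def _circular_mean(angles: np.ndarray) -> float:
    rad = np.radians(angles)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def fit_clusters(angles, k: int = 7, seed: int = 0,
                 max_iter: int = 100) -> DihedralClusterModel:
    """Partition (phi, psi) pairs into ``k`` clusters on the torus.

    Lloyd-style iteration with the toroidal squared distance,
    D^2-weighted greedy seeding and per-coordinate circular-mean
    centroid updates; converges to a local optimum and is deterministic
    given the seed.  An emptied cluster is re-seeded to the point
    farthest from all remaining centroids.  Requires at least ``k``
    distinct angle pairs.
    """
    pts = np.asarray(angles, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("angles must be an (n, 2) array of (phi, psi) pairs")
    distinct = np.unique(_wrap(pts), axis=0)
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct angle pairs, got {len(distinct)}")

    rng = np.random.default_rng(seed)
    # D^2 seeding on the distinct points: spread initial centroids out
    centroids = distinct[[rng.integers(len(distinct))]]
    while len(centroids) < k:
        d2 = toroidal_sq_dist(distinct, centroids).min(axis=1)
        if d2.sum() == 0:
            d2 = np.ones_like(d2)
        centroids = np.vstack([centroids,
                               distinct[rng.choice(len(distinct), p=d2 / d2.sum())]])

    assign = np.full(len(pts), -1)
    for _ in range(max_iter):
        new_assign = np.argmin(toroidal_sq_dist(pts, centroids), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = pts[assign == j]
            if len(members):
                centroids[j] = [_circular_mean(members[:, 0]),
                                _circular_mean(members[:, 1])]
            else:  # re-seed an emptied cluster to the farthest point
                far = int(np.argmax(toroidal_sq_dist(pts, centroids).min(axis=1)))
                centroids[j] = pts[far]
    populations = np.bincount(assign, minlength=k)
    return DihedralClusterModel(centroids=_wrap(centroids), seed=seed,
                                training_size=len(pts), populations=populations)


def assign_cluster(phi: float | None, psi: float | None,
                   model: DihedralClusterModel) -> int:
    """Index of the nearest centroid under the toroidal metric (ties: lowest).

    Undefined terminal angles (None) fall back to the model's most
    populous cluster, a neutral frequency-weighted default.
    """
    if phi is None or psi is None:
        return model.most_populous
    d = toroidal_sq_dist(np.array([[phi, psi]]), model.centroids)[0]
    return int(np.argmin(d))


def assign_clusters(angles, model: DihedralClusterModel) -> list[int]:
    """Vector form of :func:`assign_cluster` over (phi, psi) pairs (None allowed)."""
    return [assign_cluster(phi, psi, model) for phi, psi in angles]


#: A fixed partition of the Ramachandran torus into seven regions used by
#: the synthetic corpus: right-handed helix, extended strand, polyproline
#: II, the bridge region (turn-central conformations), left-handed helix,
#: the gamma-left region, and the epsilon region.  Populations reflect
#: the dominance of helix/strand conformations in globular proteins.
DEFAULT_CLUSTER_MODEL = DihedralClusterModel(
    centroids=np.array([
        [-63.0, -43.0],   # 0: alpha-R
        [-120.0, 130.0],  # 1: beta / extended
        [-75.0, 150.0],   # 2: PPII
        [-90.0, 0.0],     # 3: bridge (common at turn centres)
        [63.0, 43.0],     # 4: alpha-L
        [80.0, 0.0],      # 5: gamma-L
        [60.0, -130.0],   # 6: epsilon
    ]),
    seed=0,
    training_size=0,
    populations=np.array([35, 30, 12, 10, 6, 4, 3]),
)


def load_upstream(path) -> UpstreamPrediction:
    """Read a 3-column TSV (1-based index, ss, cluster) into a prediction.

    Rows may arrive in any order; indices must form the contiguous range
    1..L with no gaps or duplicates.
    """
    rows: list[tuple[int, str, int]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(toks)}")
        rows.append((int(toks[0]), toks[1], int(toks[2])))
    if not rows:
        raise ValueError(f"{path}: empty upstream prediction file")
    rows.sort(key=lambda r: r[0])
    indices = [r[0] for r in rows]
    if indices != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: residue indices must be 1..L without gaps "
                         "or duplicates")
    return UpstreamPrediction(ss="".join(r[1] for r in rows),
                              clusters=[r[2] for r in rows])


def save_upstream(pred: UpstreamPrediction, path) -> None:
    """Write a prediction as the 3-column TSV read by :func:`load_upstream`."""
    with open(path, "w") as fh:
        for i, (ss, cl) in enumerate(zip(pred.ss, pred.clusters), start=1):
            fh.write(f"{i}\t{ss}\t{cl}\n")


_MODEL_FORMAT_VERSION = 1


def save_cluster_model(model: DihedralClusterModel, path) -> None:
    """Persist a cluster model as a small versioned text file."""
    with open(path, "w") as fh:
        fh.write(f"# betaturn dihedral cluster model v{_MODEL_FORMAT_VERSION}\n")
        fh.write(f"seed\t{model.seed}\n")
        fh.write(f"training_size\t{model.training_size}\n")
        for (phi, psi), pop in zip(model.centroids, model.populations):
            fh.write(f"centroid\t{phi:.6f}\t{psi:.6f}\t{pop}\n")


def load_cluster_model(path) -> DihedralClusterModel:
    seed = training_size = 0
    cents: list[list[float]] = []
    pops: list[int] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        toks = line.split("\t")
        if toks[0] == "seed":
            seed = int(toks[1])
        elif toks[0] == "training_size":
            training_size = int(toks[1])
        elif toks[0] == "centroid":
            cents.append([float(toks[1]), float(toks[2])])
            pops.append(int(toks[3]))
    return DihedralClusterModel(centroids=np.array(cents), seed=seed,
                                training_size=training_size,
                                populations=np.array(pops))
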