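"""Representative docking-pose selection by PCA + k-means medoid clustering.

Docking typically returns tens of poses per ligand; only a few distinct
binding modes are worth simulating. Heavy-atom coordinates of all poses
(shared receptor frame, so no superposition by default) are reduced by PCA,
the scores are clustered with k-means, and the medoid of each cluster — the
member pose closest to all others in its cluster — is returned as a
representative binding mode (typically 2-3 per ligand).

Both the PCA dimensionality and the cluster count grow greedily under the
same rule: one more component / cluster is accepted only if it adds at least
5% of explained variance (of the coordinates, respectively of the scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

MIN_INCREMENT = 0.05
DEFAULT_SEED = 42


@dataclass(frozen=True)
class PoseSet:
    """Heavy-atom conformations of one ligand in a fixed atom order (nm)."""

    compound_id: str
    coordinates: np.ndarray  # (n_poses, n_atoms, 3)

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_poses, n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_poses(self) -> int:
        return self.coordinates.shape[0]

    def flattened(self) -> np.ndarray:
        return self.coordinates.reshape(self.n_poses, -1)


@dataclass
class ClusterResult:
    retained_components: int
    k: int
    assignments: np.ndarray
    medoid_indices: list[int]
    explained_fraction: float


def pose_pca(
    pose_set: PoseSet, min_increment: float = MIN_INCREMENT
) -> tuple[np.ndarray, int]:
    """PCA scores of the mean-centered pose-coordinate matrix.

    Components are retained in decreasing-eigenvalue order while each adds at
    least ``min_increment`` of the explained variance (at least one, unless
    the poses are all identical, in which case zero components are retained
    and the scores are empty).
    """
    X = pose_set.flattened()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 poses")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-24:  # degenerate: all poses identical
        return np.zeros((X.shape[0], 0)), 0
    ratios = var / total
    k = 1
    while k < len(ratios) and ratios[k] >= min_increment:
        k += 1
    return Xc @ vt[:k].T, k


def _medoid(points: np.ndarray, member_indices: np.ndarray) -> int:
    """Index (into the full pose list) of the member minimizing total distance."""
    pts = points[member_indices]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    totals = d.sum(axis=1)
    return int(member_indices[int(np.argmin(totals))])  # argmin breaks ties low


def select_k_and_cluster(
    scores: np.ndarray,
    min_increment: float = MIN_INCREMENT,
    seed: int = DEFAULT_SEED,
    n_restarts: int = 10,
    max_k: Optional[int] = None,
) -> ClusterResult:
    """Grow k-means cluster count under the 5%-increment rule; pick medoids.

    Starting from k=1, one extra cluster is accepted while it raises the
    between-cluster fraction of score variance by at least ``min_increment``.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n == 0:
        raise ValueError("no poses to cluster")
    if scores.size == 0 or n == 1:
        # degenerate geometry: everything is one cluster, lowest index medoid
        return ClusterResult(
            retained_components=scores.shape[1] if scores.ndim == 2 else 0,
            k=1,
            assignments=np.zeros(n, dtype=int),
            medoid_indices=[0],
            explained_fraction=0.0,
        )

    tss = float(((scores - scores.mean(axis=0)) ** 2).sum())
    max_k = min(max_k or n, n)

    best_assign = np.zeros(n, dtype=int)
    best_frac = 0.0
    k = 1
    while k + 1 <= max_k:
        km = KMeans(n_clusters=k + 1, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(scores)
        frac = 1.0 - km.inertia_ / tss if tss > 0 else 0.0
        if frac - best_frac >= min_increment:
            k += 1
            best_assign, best_frac = labels, frac
        else:
            break

    medoids = [
        _medoid(scores, np.flatnonzero(best_assign == c)) for c in range(k)
    ]
    return ClusterResult(
        retained_components=scores.shape[1],
        k=k,
        assignments=best_assign,
        medoid_indices=sorted(medoids),
        explained_fraction=best_frac,
    )


def representative_poses(
    pose_set: PoseSet,
    min_increment: float = MIN_INCREMENT,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, ClusterResult]:
    """Medoid conformations (original coordinates) and the clustering report."""
    if pose_set.n_poses == 1:
        result = ClusterResult(
            retained_components=0,
            k=1,
            assignments=np.zeros(1, dtype=int),
            medoid_indices=[0],
            explained_fraction=0.0,
        )
        return pose_set.coordinates.copy(), result
    scores, retained = pose_pca(pose_set, min_increment)
    result = select_k_and_cluster(scores, min_increment, seed)
    result.retained_components = retained
    coords = pose_set.coordinates[result.medoid_indices]
    return coords, result


# --- pose file readers ---------------------------------------------------------

_PDB_TO_NM = 0.1  # PDB coordinates are in angstrom


def read_poses_pdb(path, compound_id: Optional[str] = None) -> PoseSet:
    """Read a multi-model PDB of ligand poses; hydrogens are ignored.

    All models must contain the same heavy atoms in the same order.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("poses", str(path))
    models = []
    names = None
    for model in structure:
        atoms = [
            a
            for a in model.get_atoms()
            if (a.element or a.get_name()[:1]).upper() != "H"
        ]
        model_names = [a.get_name() for a in atoms]
        if names is None:
            names = model_names
        elif model_names != names:
            raise ValueError(f"{path}: models have inconsistent heavy atoms")
        models.append([a.coord for a in atoms])
    if not models:
        raise ValueError(f"{path}: no models found")
    coords = np.array(models, dtype=float) * _PDB_TO_NM
    return PoseSet(compound_id=compound_id or Path(str(path)).stem, coordinates=coords)


def read_poses_sdf(path, compound_id: Optional[str] = None) -> PoseSet:
    """Read a multi-record SDF of poses of one ligand; hydrogens are ignored."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=False)
    models = []
    n_atoms = None
    for mol in supplier:
        if mol is None:
            continue
        conf = mol.GetConformer()
        heavy = [i for i in range(mol.GetNumAtoms()) if mol.GetAtomWithIdx(i).GetAtomicNum() != 1]
        if n_atoms is None:
            n_atoms = len(heavy)
        elif len(heavy) != n_atoms:
            raise ValueError(f"{path}: records have different heavy-atom counts")
        models.append([list(conf.GetAtomPosition(i)) for i in heavy])
    if not models:
        raise ValueError(f"{path}: no molecules found")
    coords = np.array(models, dtype=float) * _PDB_TO_NM  # SDF is also angstrom
    return PoseSet(compound_id=compound_id or Path(str(path)).stem, coordinates=coords)


def read_poses(path, compound_id: Optional[str] = None) -> PoseSet:
    """Dispatch on extension: .pdb -> multi-model PDB, .sdf/.mol -> SDF."""
    suffix = Path(str(path)).suffix.lower()
    if suffix == ".pdb":
        return read_poses_pdb(path, compound_id)
    if suffix in (".sdf", ".mol"):
        return read_poses_sdf(path, compound_id)
    raise ValueError(f"unsupported pose file format: {suffix!r}")
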