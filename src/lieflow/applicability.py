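"""Applicability-domain (AD) assessment of LIE predictions.

An empirical binding free-energy model is only trustworthy for queries that
resemble its training set. Reliability is scored with five criteria, each
contributing one violation flag; their sum is the confidence index (CI),
ranging from 0 (no violation, high confidence) to 5 (all violated, low
confidence):

1. the predicted free energy falls inside the range of calculated training
   free energies (inclusive bounds);
2. the ligand's best Tanimoto similarity to the training set exceeds
   (strictly) a cutoff: the lowest nearest-neighbour similarity observed
   within the training set;
3. the Boltzmann-weighted interaction-energy pair (dV_vdw, dV_ele) lies
   within the empirical 95th percentile of training Mahalanobis distances
   from the training centroid;
4. the per-residue vdW energy decomposition, projected onto the training
   PCA space, has score and orthogonal distances within the training 95th
   percentiles;
5. as 4, for the electrostatic decomposition.

All thresholds are frozen into an :class:`ADReference` at training time, so
query scoring depends only on the reference and the query itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import LIEParameters, TrainingCompound
from .engine import predict, weighted_delta_interactions

#: minimum additional explained-variance fraction for a PCA component
PCA_MIN_INCREMENT = 0.05
PERCENTILE = 95.0
_COV_RIDGE = 1e-8


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a & b| / |a | b| of two equal-length bit-vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    return float(np.count_nonzero(a & b) / union)


def morgan_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint of a SMILES string as a bool array."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(bool)


@dataclass
class PCAReference:
    """Frozen PCA subspace of training decomposition vectors.

    ``components`` has one retained loading per row; ``eigenvalues`` are the
    training score variances used to scale score distances. ``sd_threshold``
    and ``od_threshold`` are empirical 95th percentiles of the training
    score and orthogonal distances.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    sd_threshold: float
    od_threshold: float

    def distances(self, x: np.ndarray) -> tuple[float, float]:
        """(score distance, orthogonal distance) of one query vector."""
        x = np.asarray(x, dtype=float)
        centered = x - self.mean
        scores = self.components @ centered
        lam = np.maximum(self.eigenvalues, 1e-12)
        sd = float(np.sqrt(np.sum(scores**2 / lam)))
        residual = centered - self.components.T @ scores
        od = float(np.linalg.norm(residual))
        return sd, od


@dataclass
class ADReference:
    """Frozen training-set statistics backing the five AD criteria."""

    dg_range: tuple[float, float]
    ts_cutoff: float
    fingerprints: np.ndarray  # (n_train, n_bits) bool
    energy_centroid: np.ndarray  # (2,)
    energy_covariance: np.ndarray  # (2, 2)
    mahalanobis_threshold: float
    pca_vdw: PCAReference
    pca_ele: PCAReference


@dataclass
class ADQuery:
    """Everything the five criteria need to know about a query compound."""

    compound_id: str
    dg_pred: float
    fingerprint: np.ndarray
    energy_pair: np.ndarray  # weighted (dV_vdw, dV_ele)
    decomposition_vdw: np.ndarray
    decomposition_ele: np.ndarray


@dataclass
class ConfidenceReport:
    """Per-criterion violation flags, diagnostics, and the total CI score."""

    compound_id: str
    flags: dict  # {"c1": 0/1, ...}
    diagnostics: dict = field(default_factory=dict)

    @property
    def ci_total(self) -> int:
        return int(sum(self.flags.values()))


def fit_pca_reference(matrix: np.ndarray, min_increment: float = PCA_MIN_INCREMENT) -> PCAReference:
    """PCA of training decomposition vectors with 5%-increment retention.

    Components are scanned in decreasing-eigenvalue order and retained while
    each adds at least ``min_increment`` of the total explained variance; at
    least one component is always kept.
    """
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(X.shape[0] - 1, 1)
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)
    k = 1
    while k < len(ratios) and ratios[k] >= min_increment:
        k += 1
    components = vt[:k]
    eigenvalues = var[:k]
    scores = Xc @ components.T
    lam = np.maximum(eigenvalues, 1e-12)
    sd = np.sqrt(np.sum(scores**2 / lam, axis=1))
    od = np.linalg.norm(Xc - scores @ components, axis=1)
    return PCAReference(
        mean=mean,
        components=components,
        eigenvalues=eigenvalues,
        sd_threshold=float(np.percentile(sd, PERCENTILE)),
        od_threshold=float(np.percentile(od, PERCENTILE)),
    )


def _regularized_covariance(X: np.ndarray) -> np.ndarray:
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.eigvalsh(cov).min() < _COV_RIDGE:
        cov = cov + _COV_RIDGE * np.eye(cov.shape[0])
    return cov


def mahalanobis_distance(x: np.ndarray, centroid: np.ndarray, covariance: np.ndarray) -> float:
    d = np.asarray(x, dtype=float) - np.asarray(centroid, dtype=float)
    return float(np.sqrt(d @ np.linalg.solve(covariance, d)))


def fit_energy_criterion(
    energies: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, regularized covariance, and empirical 95th-percentile
    Mahalanobis threshold of training (dV_vdw, dV_ele) pairs."""
    energies = np.asarray(energies, dtype=float)
    centroid = energies.mean(axis=0)
    cov = _regularized_covariance(energies)
    dists = np.array([mahalanobis_distance(e, centroid, cov) for e in energies])
    return centroid, cov, float(np.percentile(dists, PERCENTILE))


def build_ad_reference(
    training: Sequence[TrainingCompound],
    params: LIEParameters,
    min_increment: float = PCA_MIN_INCREMENT,
) -> ADReference:
    """Derive the frozen AD statistics from a trained model's training set."""
    training = list(training)
    if len(training) < 5:
        raise ValueError("AD reference needs at least 5 training compounds")
    missing = [
        c.compound_id
        for c in training
        if c.fingerprint is None
        or c.decomposition_vdw is None
        or c.decomposition_ele is None
    ]
    if missing:
        raise ValueError(
            f"training compounds missing fingerprints or decompositions: {missing}"
        )

    dg_calc = np.array([predict(params, c.energetics).dg_pred for c in training])
    fps = np.array([c.fingerprint for c in training], dtype=bool)

    # lowest nearest-neighbour Tanimoto within the training set
    nn_best = []
    for i in range(len(training)):
        best = max(tanimoto(fps[i], fps[j]) for j in range(len(training)) if j != i)
        nn_best.append(best)
    ts_cutoff = float(min(nn_best))

    energies = np.array(
        [weighted_delta_interactions(params, c.energetics) for c in training]
    )
    centroid, cov, maha_threshold = fit_energy_criterion(energies)

    return ADReference(
        dg_range=(float(dg_calc.min()), float(dg_calc.max())),
        ts_cutoff=ts_cutoff,
        fingerprints=fps,
        energy_centroid=centroid,
        energy_covariance=cov,
        mahalanobis_threshold=maha_threshold,
        pca_vdw=fit_pca_reference(
            np.array([c.decomposition_vdw for c in training]), min_increment
        ),
        pca_ele=fit_pca_reference(
            np.array([c.decomposition_ele for c in training]), min_increment
        ),
    )


# --- individual criteria (flag: 0 = satisfied, 1 = violated) ------------------

def criterion1_range(dg_pred: float, reference: ADReference) -> int:
    lo, hi = reference.dg_range
    return 0 if lo <= dg_pred <= hi else 1


def criterion2_similarity(fingerprint: np.ndarray, reference: ADReference) -> int:
    best = max(tanimoto(fingerprint, fp) for fp in reference.fingerprints)
    return 0 if best > reference.ts_cutoff else 1  # strictly greater


def criterion3_energy(energy_pair: np.ndarray, reference: ADReference) -> int:
    d = mahalanobis_distance(
        energy_pair, reference.energy_centroid, reference.energy_covariance
    )
    return 0 if d <= reference.mahalanobis_threshold else 1


def criterion45_decomposition(vector: np.ndarray, pca: PCAReference) -> int:
    sd, od = pca.distances(vector)
    return 0 if (sd <= pca.sd_threshold and od <= pca.od_threshold) else 1


def assess(query: ADQuery, reference: ADReference) -> ConfidenceReport:
    """Score one query against all five criteria and sum the CI."""
    best_ts = max(tanimoto(query.fingerprint, fp) for fp in reference.fingerprints)
    d3 = mahalanobis_distance(
        query.energy_pair, reference.energy_centroid, reference.energy_covariance
    )
    sd4, od4 = reference.pca_vdw.distances(query.decomposition_vdw)
    sd5, od5 = reference.pca_ele.distances(query.decomposition_ele)
    flags = {
        "c1": criterion1_range(query.dg_pred, reference),
        "c2": criterion2_similarity(query.fingerprint, reference),
        "c3": criterion3_energy(query.energy_pair, reference),
        "c4": criterion45_decomposition(query.decomposition_vdw, reference.pca_vdw),
        "c5": criterion45_decomposition(query.decomposition_ele, reference.pca_ele),
    }
    diagnostics = {
        "c1": {"dg_pred": query.dg_pred, "range": reference.dg_range},
        "c2": {"best_tanimoto": best_ts, "cutoff": reference.ts_cutoff},
        "c3": {"mahalanobis": d3, "threshold": reference.mahalanobis_threshold},
        "c4": {
            "score_distance": sd4,
            "orthogonal_distance": od4,
            "sd_threshold": reference.pca_vdw.sd_threshold,
            "od_threshold": reference.pca_vdw.od_threshold,
        },
        "c5": {
            "score_distance": sd5,
            "orthogonal_distance": od5,
            "sd_threshold": reference.pca_ele.sd_threshold,
            "od_threshold": reference.pca_ele.od_threshold,
        },
    }
    return ConfidenceReport(
        compound_id=query.compound_id, flags=flags, diagnostics=diagnostics
    )


def most_central_member(
    training: Sequence[TrainingCompound],
    reference: ADReference,
    params: LIEParameters,
) -> ADQuery:
    """The most typical training compound under the AD distance measures.

    Returns the member minimizing the largest of its threshold-normalized
    distances (Mahalanobis, PCA score and orthogonal for both energy types),
    i.e. the training compound farthest from every criterion boundary —
    useful as a self-consistency probe of a freshly built reference.
    """
    best_query, best_score = None, np.inf
    for compound in training:
        q = query_from_training_compound(compound, params)
        d3 = mahalanobis_distance(
            q.energy_pair, reference.energy_centroid, reference.energy_covariance
        )
        sd4, od4 = reference.pca_vdw.distances(q.decomposition_vdw)
        sd5, od5 = reference.pca_ele.distances(q.decomposition_ele)
        ratios = [
            d3 / max(reference.mahalanobis_threshold, 1e-12),
            sd4 / max(reference.pca_vdw.sd_threshold, 1e-12),
            od4 / max(reference.pca_vdw.od_threshold, 1e-12),
            sd5 / max(reference.pca_ele.sd_threshold, 1e-12),
            od5 / max(reference.pca_ele.od_threshold, 1e-12),
        ]
        score = max(ratios)
        if score < best_score:
            best_query, best_score = q, score
    return best_query


def query_from_training_compound(
    compound: TrainingCompound, params: LIEParameters
) -> ADQuery:
    """Build an ADQuery by running the LIE prediction on a compound's data."""
    return ADQuery(
        compound_id=compound.compound_id,
        dg_pred=predict(params, compound.energetics).dg_pred,
        fingerprint=compound.fingerprint,
        energy_pair=weighted_delta_interactions(params, compound.energetics),
        decomposition_vdw=compound.decomposition_vdw,
        decomposition_ele=compound.decomposition_ele,
    )


# --- (de)serialization for the model file -------------------------------------

def _pca_to_dict(p: PCAReference) -> dict:
    return {
        "mean": p.mean.tolist(),
        "components": p.components.tolist(),
        "eigenvalues": p.eigenvalues.tolist(),
        "sd_threshold": p.sd_threshold,
        "od_threshold": p.od_threshold,
    }


def _pca_from_dict(d: dict) -> PCAReference:
    return PCAReference(
        mean=np.array(d["mean"]),
        components=np.array(d["components"]),
        eigenvalues=np.array(d["eigenvalues"]),
        sd_threshold=float(d["sd_threshold"]),
        od_threshold=float(d["od_threshold"]),
    )


def ad_reference_to_dict(ref: ADReference) -> dict:
    return {
        "dg_range": list(ref.dg_range),
        "ts_cutoff": ref.ts_cutoff,
        "fingerprints": [np.flatnonzero(fp).tolist() for fp in ref.fingerprints],
        "n_bits": int(ref.fingerprints.shape[1]),
        "energy_centroid": ref.energy_centroid.tolist(),
        "energy_covariance": ref.energy_covariance.tolist(),
        "mahalanobis_threshold": ref.mahalanobis_threshold,
        "pca_vdw": _pca_to_dict(ref.pca_vdw),
        "pca_ele": _pca_to_dict(ref.pca_ele),
    }


def ad_reference_from_dict(d: dict) -> ADReference:
    n_bits = int(d["n_bits"])
    fps = np.zeros((len(d["fingerprints"]), n_bits), dtype=bool)
    for i, on_bits in enumerate(d["fingerprints"]):
        fps[i, on_bits] = True
    return ADReference(
        dg_range=tuple(d["dg_range"]),
        ts_cutoff=float(d["ts_cutoff"]),
        fingerprints=fps,
        energy_centroid=np.array(d["energy_centroid"]),
        energy_covariance=np.array(d["energy_covariance"]),
        mahalanobis_threshold=float(d["mahalanobis_threshold"]),
        pca_vdw=_pca_from_dict(d["pca_vdw"]),
        pca_ele=_pca_from_dict(d["pca_ele"]),
    )
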