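"""Synthetic generator for every input of the workflow, with known truth.

The generator emulates what docking + MD would produce for a congeneric
ligand series: per-simulation bound/unbound interaction-energy averages (and
frame-level traces consistent with them), observed affinities drawn from the
forward LIE model under known true parameters plus Gaussian noise,
low-rank per-residue energy decompositions whose rows sum to each compound's
total interaction energies, family-structured fingerprints, and Gaussian
pose clouds for the clustering stage.

Defaults mirror a small congeneric training campaign: 30 compounds, 3 poses
simulated in duplicate (2 replicates per pose), true parameters
alpha=0.33, beta=0.12, gamma=-13.0 at 300 K, interaction-energy scales of
roughly -60 kJ/mol (vdW) and -25 kJ/mol (electrostatic) with 2 kJ/mol
observation noise.

One global seed governs all draws; per-component generators are derived
deterministically from it so individual pieces can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .core import (
    CompoundEnergetics,
    EnergyTrace,
    LIEParameters,
    SimulationRecord,
    TrainingCompound,
    UnboundReference,
)
from .engine import predict, weighted_delta_interactions
from .poses import PoseSet


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic campaign."""

    n_compounds: int = 30
    n_poses: int = 3
    replicates: int = 2
    alpha: float = 0.33
    beta: float = 0.12
    gamma: float = -13.0
    temperature: float = DEFAULT_TEMPERATURE
    dv_mean: tuple = (-60.0, -25.0)
    dv_cov: tuple = ((144.0, 30.0), (30.0, 64.0))
    pose_sigma: float = 4.0  # between-pose spread of dV (kJ/mol)
    replicate_sigma: float = 0.8  # between-replicate spread (kJ/mol)
    noise_sigma: float = 2.0  # observation noise on dG_obs (kJ/mol)
    n_residues: int = 24
    decomposition_rank: int = 3
    decomposition_noise: float = 0.3
    fingerprint_bits: int = 128
    n_families: int = 3
    family_on_bits: int = 28
    flip_rate: float = 0.04
    seed: int = 0

    @property
    def true_parameters(self) -> LIEParameters:
        return LIEParameters(
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            temperature=self.temperature,
        )


def _rng(spec_seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the global seed."""
    name_key = sum(ord(c) * (i + 1) for i, c in enumerate(stream)) % (2**16)
    return np.random.default_rng(np.random.SeedSequence((spec_seed, name_key)))


def generate_energetics(spec: SyntheticSpec) -> list[CompoundEnergetics]:
    """Bound/unbound averaged energies for every compound and simulation."""
    rng = _rng(spec.seed, "energetics")
    out = []
    for c in range(spec.n_compounds):
        unbound = UnboundReference(
            mean_vdw=float(rng.normal(-35.0, 4.0)),
            mean_ele=float(rng.normal(-120.0, 10.0)),
        )
        dv_compound = rng.multivariate_normal(spec.dv_mean, np.asarray(spec.dv_cov))
        records = []
        for p in range(spec.n_poses):
            pose_offset = rng.normal(0.0, spec.pose_sigma, size=2)
            for r in range(spec.replicates):
                dv = dv_compound + pose_offset + rng.normal(0.0, spec.replicate_sigma, size=2)
                records.append(
                    SimulationRecord(
                        pose_id=f"pose{p}",
                        replicate_id=f"rep{r}",
                        mean_vdw=float(unbound.mean_vdw + dv[0]),
                        mean_ele=float(unbound.mean_ele + dv[1]),
                    )
                )
        out.append(
            CompoundEnergetics(
                compound_id=f"cpd{c:03d}", bound=tuple(records), unbound=unbound
            )
        )
    return out


def generate_fingerprints(spec: SyntheticSpec) -> np.ndarray:
    """Family-structured fingerprints: shared templates plus random bit flips."""
    rng = _rng(spec.seed, "fingerprints")
    templates = np.zeros((spec.n_families, spec.fingerprint_bits), dtype=bool)
    for f in range(spec.n_families):
        on = rng.choice(spec.fingerprint_bits, size=spec.family_on_bits, replace=False)
        templates[f, on] = True
    fps = np.zeros((spec.n_compounds, spec.fingerprint_bits), dtype=bool)
    for c in range(spec.n_compounds):
        fam = c % spec.n_families
        flips = rng.random(spec.fingerprint_bits) < spec.flip_rate
        fps[c] = templates[fam] ^ flips
        if not fps[c].any():  # degenerate all-zero fingerprint: keep one bit on
            fps[c, int(rng.integers(spec.fingerprint_bits))] = True
    return fps


def generate_decompositions(
    spec: SyntheticSpec, totals_vdw: np.ndarray, totals_ele: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank per-residue decomposition matrices consistent with totals.

    Row ``c`` of each matrix sums exactly to compound ``c``'s total weighted
    interaction energy for that energy type. The first structured direction
    is a base residue profile (summing to 1) scaled by the total; the
    remaining ``decomposition_rank - 1`` directions are zero-sum residue
    patterns with per-compound factors, so row sums are preserved. Additive
    noise is projected onto the zero-sum subspace for the same reason.
    """
    rng = _rng(spec.seed, "decompositions")
    p = spec.n_residues
    out = []
    for totals in (np.asarray(totals_vdw, float), np.asarray(totals_ele, float)):
        base = rng.dirichlet(np.full(p, 2.0))  # sums to 1
        M = np.outer(totals, base)
        factor_scale = 0.35 * np.std(totals) if np.std(totals) > 0 else 1.0
        for j in range(spec.decomposition_rank - 1):
            z = rng.normal(size=p)
            z -= z.mean()  # zero-sum residue pattern
            z /= np.linalg.norm(z)
            f = rng.normal(0.0, factor_scale / (j + 1), size=len(totals))
            M += np.outer(f, z)
        if spec.decomposition_noise > 0:
            noise = rng.normal(0.0, spec.decomposition_noise, size=M.shape)
            noise -= noise.mean(axis=1, keepdims=True)
            M += noise
        out.append(M)
    return out[0], out[1]


def generate_training_set(spec: SyntheticSpec) -> list[TrainingCompound]:
    """Full training compounds: energetics, affinities, fingerprints, decompositions."""
    rng = _rng(spec.seed, "observations")
    params = spec.true_parameters
    energetics = generate_energetics(spec)
    fps = generate_fingerprints(spec)
    weighted = np.array(
        [weighted_delta_interactions(params, e) for e in energetics]
    )
    dec_vdw, dec_ele = generate_decompositions(spec, weighted[:, 0], weighted[:, 1])
    out = []
    for i, e in enumerate(energetics):
        dg_true = predict(params, e).dg_pred
        dg_obs = dg_true + float(rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma > 0 else dg_true
        out.append(
            TrainingCompound(
                compound_id=e.compound_id,
                dg_obs=float(dg_obs),
                energetics=e,
                fingerprint=fps[i],
                decomposition_vdw=dec_vdw[i],
                decomposition_ele=dec_ele[i],
            )
        )
    return out


def trace_for_record(
    record_mean_vdw: float,
    record_mean_ele: float,
    n_frames: int = 100,
    cadence_ps: float = 10.0,
    jitter: float = 5.0,
    rng: Optional[np.random.Generator] = None,
) -> EnergyTrace:
    """Frame-level trace whose means equal the record means exactly.

    Frames are written every 10 ps by default, mirroring the interaction-
    energy write-out cadence of the simulations being emulated.
    """
    rng = rng or np.random.default_rng(0)
    times = cadence_ps * np.arange(1, n_frames + 1)
    vdw = rng.normal(0.0, jitter, n_frames)
    ele = rng.normal(0.0, jitter, n_frames)
    vdw += record_mean_vdw - vdw.mean()
    ele += record_mean_ele - ele.mean()
    return EnergyTrace(times=times, v_vdw=vdw, v_ele=ele)


def generate_pose_cloud(
    n_poses: int,
    k_true: int,
    separation: float,
    spread: float,
    seed: int,
    n_atoms: int = 12,
    compound_id: str = "synthetic",
) -> tuple[PoseSet, np.ndarray]:
    """Gaussian clusters of conformations around ``k_true`` templates (nm).

    Returns the pose set and the true cluster label of each pose. Templates
    are placed ``separation`` apart along distinct random directions; poses
    scatter isotropically with standard deviation ``spread`` per coordinate.
    """
    rng = _rng(seed, "poses")
    base = rng.normal(0.0, 0.3, size=(n_atoms, 3))
    templates = []
    for k in range(k_true):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        templates.append(base + k * separation * direction)
    labels = np.repeat(np.arange(k_true), int(np.ceil(n_poses / k_true)))[:n_poses]
    coords = np.array(
        [templates[l] + rng.normal(0.0, spread, size=(n_atoms, 3)) for l in labels]
    )
    return PoseSet(compound_id=compound_id, coordinates=coords), labels


# --- out-of-domain query construction -------------------------------------------

def out_of_domain_query(reference, spec: SyntheticSpec, compound_id: str = "ood"):
    """A query engineered to violate every applicability-domain criterion.

    Its predicted free energy sits far outside the training range; its
    fingerprint uses only bits unseen in training (best Tanimoto 0); its
    interaction-energy pair lies many covariance widths from the centroid;
    and both decomposition vectors carry a large component orthogonal to the
    retained PCA loadings plus an inflated score, exceeding both distance
    thresholds.
    """
    from .applicability import ADQuery

    rng = _rng(spec.seed, "ood-query")
    lo, hi = reference.dg_range
    dg_pred = hi + 10.0 * max(1.0, hi - lo)

    unused = np.flatnonzero(~reference.fingerprints.any(axis=0))
    fp = np.zeros(reference.fingerprints.shape[1], dtype=bool)
    if unused.size == 0:
        raise ValueError("training fingerprints cover every bit; cannot build novel query")
    fp[unused[: max(1, unused.size // 4)]] = True

    evals, evecs = np.linalg.eigh(reference.energy_covariance)
    energy_pair = reference.energy_centroid + 50.0 * np.sqrt(evals[-1]) * evecs[:, -1]

    def bad_vector(pca):
        v = rng.normal(size=pca.mean.size)
        v -= pca.components.T @ (pca.components @ v)  # orthogonal to loadings
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm * 50.0 * max(pca.od_threshold, 1.0)
        inflate = 50.0 * max(pca.sd_threshold, 1.0)
        return pca.mean + v + inflate * np.sqrt(np.maximum(pca.eigenvalues[0], 1e-6)) * pca.components[0]

    return ADQuery(
        compound_id=compound_id,
        dg_pred=float(dg_pred),
        fingerprint=fp,
        energy_pair=energy_pair,
        decomposition_vdw=bad_vector(reference.pca_vdw),
        decomposition_ele=bad_vector(reference.pca_ele),
    )
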