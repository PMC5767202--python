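"""Boltzmann-weighted multi-pose LIE prediction.

Each compound is simulated several times, starting from different docking
poses (and in replicate). Every simulation ``i`` yields interaction-energy
differences between bound and unbound states,

    dV_i^vdw = <V_lig-surr^vdw>_bound,i - <V_lig-surr^vdw>_unbound
    dV_i^ele = <V_lig-surr^ele>_bound,i - <V_lig-surr^ele>_unbound

and a per-simulation estimate dG_i = alpha*dV_i^vdw + beta*dV_i^ele + gamma.
Simulations are combined with Boltzmann weights

    W_i = exp(-dG_i / RT) / sum_j exp(-dG_j / RT)

so that poses predicting stronger binding dominate the ensemble estimate

    dG_pred = alpha * sum_i W_i dV_i^vdw + beta * sum_i W_i dV_i^ele + gamma
            = sum_i W_i dG_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import rt
from .core import CompoundEnergetics, LIEParameters


@dataclass(frozen=True)
class PerSimulationPrediction:
    index: int
    dv_vdw: float
    dv_ele: float
    dg_pred: float
    weight: float


@dataclass(frozen=True)
class Prediction:
    """Weighted binding free-energy estimate for one compound."""

    compound_id: str
    dg_pred: float
    per_simulation: tuple[PerSimulationPrediction, ...]

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.per_simulation])


def delta_interactions(energetics: CompoundEnergetics) -> np.ndarray:
    """Bound-minus-unbound (dV_vdw, dV_ele) pairs, one row per simulation."""
    ub = energetics.unbound
    return np.array(
        [[r.mean_vdw - ub.mean_vdw, r.mean_ele - ub.mean_ele] for r in energetics.bound]
    )


def per_simulation_dg(params: LIEParameters, dv_vdw, dv_ele):
    """LIE estimate for a single simulation's interaction-energy differences."""
    return params.alpha * np.asarray(dv_vdw) + params.beta * np.asarray(dv_ele) + params.gamma


def boltzmann_weights(dg: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized Boltzmann weights over per-simulation free energies.

    Exponents are shifted by their maximum before exponentiation so that
    arbitrarily negative dG values cannot overflow; weights are invariant
    under adding a constant to all dG values.
    """
    dg = np.asarray(dg, dtype=float)
    if dg.size == 0:
        raise ValueError("cannot weight an empty set of simulations")
    x = -dg / rt(temperature)
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def predict(params: LIEParameters, energetics: CompoundEnergetics) -> Prediction:
    """Boltzmann-weighted LIE prediction for one compound."""
    dv = delta_interactions(energetics)
    dg_i = per_simulation_dg(params, dv[:, 0], dv[:, 1])
    w = boltzmann_weights(dg_i, params.temperature)
    dg_pred = float(w @ dg_i)
    per_sim = tuple(
        PerSimulationPrediction(
            index=i,
            dv_vdw=float(dv[i, 0]),
            dv_ele=float(dv[i, 1]),
            dg_pred=float(dg_i[i]),
            weight=float(w[i]),
        )
        for i in range(len(dg_i))
    )
    return Prediction(
        compound_id=energetics.compound_id, dg_pred=dg_pred, per_simulation=per_sim
    )


def weighted_delta_interactions(
    params: LIEParameters, energetics: CompoundEnergetics
) -> np.ndarray:
    """Boltzmann-weighted (sum_i W_i dV_i^vdw, sum_i W_i dV_i^ele) pair.

    These are the regressors of the LIE model at the supplied parameters and
    the interaction-energy coordinates used by the applicability-domain
    energy criterion.
    """
    dv = delta_interactions(energetics)
    dg_i = per_simulation_dg(params, dv[:, 0], dv[:, 1])
    w = boltzmann_weights(dg_i, params.temperature)
    return w @ dv
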