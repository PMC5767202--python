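"""Iterative weighted-OLS calibration of LIE parameters and model metrics.

The LIE coefficients (alpha, beta, gamma) enter the model twice: linearly,
through the prediction equation, and nonlinearly, through the Boltzmann
weights that combine the per-simulation interaction energies. Calibration
therefore alternates between (a) computing weights and weighted design rows
under the current parameters and (b) an ordinary least-squares fit of the
parameters against observed binding free energies, starting from uniform
weights, until the parameters stop changing.

Observed affinities given as IC50 values are converted to free energies with
the Cheng-Prusoff estimate dG_obs = RT ln(IC50), IC50 in molar units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, rt
from .core import CompoundEnergetics, LIEParameters, TrainingCompound
from .engine import boltzmann_weights, delta_interactions, per_simulation_dg, predict


def cheng_prusoff_dg(ic50_molar: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Cheng-Prusoff estimate of the binding free energy from an IC50.

    dG_obs = RT ln(IC50) with IC50 in molar units; an IC50 of 1 M maps to 0.
    """
    if not ic50_molar > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_molar}")
    return rt(temperature) * math.log(ic50_molar)


@dataclass
class QualityMetrics:
    rmse: float
    sdep: float
    r_pearson: float
    rho_spearman: float


@dataclass
class CalibrationResult:
    """Fitted parameters plus training diagnostics."""

    parameters: LIEParameters
    compound_ids: list[str]
    dg_obs: np.ndarray
    dg_pred: np.ndarray
    rmse: float
    r_pearson: float
    rho_spearman: float
    n_iterations: int
    converged: bool
    sdep_loo: Optional[float] = None
    notes: list[str] = field(default_factory=list)


def design_row(params: LIEParameters, energetics: CompoundEnergetics) -> np.ndarray:
    """Boltzmann-weighted (sum W_i dV_vdw_i, sum W_i dV_ele_i) regressor pair."""
    dv = delta_interactions(energetics)
    dg_i = per_simulation_dg(params, dv[:, 0], dv[:, 1])
    w = boltzmann_weights(dg_i, params.temperature)
    return w @ dv


def fit_ols(
    rows: np.ndarray,
    dg_obs: np.ndarray,
    include_offset: bool = True,
    temperature: float = DEFAULT_TEMPERATURE,
) -> LIEParameters:
    """Least-squares fit of (alpha, beta[, gamma]) to observed free energies.

    ``rows`` is (n, 2): the weighted vdW and electrostatic regressors. With
    ``include_offset`` False, gamma is fixed to zero.
    """
    rows = np.asarray(rows, dtype=float)
    dg_obs = np.asarray(dg_obs, dtype=float)
    n_par = 3 if include_offset else 2
    if rows.shape[0] < n_par:
        raise ValueError(
            f"need at least {n_par} compounds to fit {n_par} parameters, got {rows.shape[0]}"
        )
    X = np.column_stack([rows, np.ones(rows.shape[0])]) if include_offset else rows
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ["vdw", "ele", "offset"][: X.shape[1]]
        # point at the column whose removal restores full column rank
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(X, dg_obs, rcond=None)
    gamma = float(coef[2]) if include_offset else 0.0
    return LIEParameters(
        alpha=float(coef[0]), beta=float(coef[1]), gamma=gamma, temperature=temperature
    )


def _sse(params: LIEParameters, training: Sequence[TrainingCompound]) -> float:
    res = [c.dg_obs - predict(params, c.energetics).dg_pred for c in training]
    return float(np.dot(res, res))


def calibrate_iterative(
    training: Sequence[TrainingCompound],
    temperature: float = DEFAULT_TEMPERATURE,
    include_offset: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
    compute_loo: bool = False,
) -> CalibrationResult:
    """Self-consistent calibration of the LIE parameters.

    Starts from uniform weights (an unweighted mean over simulations),
    alternates OLS fits with weight updates, and declares convergence when
    the largest parameter change falls below ``tol``. The update is a plain
    fixed-point step; if the parameter change grows between iterations
    (oscillation), the step is halved until the iteration contracts again.
    The self-consistent sum of squared residuals is tracked for diagnostics:
    near the fixed point it may rise by a sliver (the OLS step minimizes the
    residual at frozen weights, not the self-consistent one), but a net
    increase over the whole run is flagged.
    """
    training = list(training)
    dg_obs = np.array([c.dg_obs for c in training])
    ids = [c.compound_id for c in training]

    # uniform-weight design rows for the initial fit
    rows0 = np.array([delta_interactions(c.energetics).mean(axis=0) for c in training])
    params = fit_ols(rows0, dg_obs, include_offset, temperature)

    converged = False
    notes: list[str] = []
    n_iter = 0
    sse0 = _sse(params, training)
    prev_delta = np.inf
    scale = 1.0
    for n_iter in range(1, max_iter + 1):
        rows = np.array([design_row(params, c.energetics) for c in training])
        candidate = fit_ols(rows, dg_obs, include_offset, temperature)
        step = candidate.as_array() - params.as_array()
        delta = float(np.max(np.abs(scale * step)))
        if delta > prev_delta and scale > 1.0 / 1024:
            scale *= 0.5  # oscillating: damp subsequent updates
            notes.append(f"iteration {n_iter}: damped step (scale {scale})")
            delta = float(np.max(np.abs(scale * step)))
        params = LIEParameters(
            *(params.as_array() + scale * step), temperature=temperature
        )
        prev_delta = delta
        if delta < tol:
            converged = True
            break
    sse = _sse(params, training)
    if sse > sse0 * (1 + 1e-9):
        notes.append(
            f"objective increased over the run (start {sse0:.6g}, end {sse:.6g})"
        )

    preds = np.array([predict(params, c.energetics).dg_pred for c in training])
    m = quality_metrics(dg_obs, preds)
    result = CalibrationResult(
        parameters=params,
        compound_ids=ids,
        dg_obs=dg_obs,
        dg_pred=preds,
        rmse=m.rmse,
        r_pearson=m.r_pearson,
        rho_spearman=m.rho_spearman,
        n_iterations=n_iter,
        converged=converged,
        notes=notes,
    )
    if compute_loo:
        result.sdep_loo = loo_sdep(
            training,
            temperature=temperature,
            include_offset=include_offset,
            tol=tol,
            max_iter=max_iter,
        )
    return result


def loo_sdep(
    training: Sequence[TrainingCompound],
    temperature: float = DEFAULT_TEMPERATURE,
    include_offset: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Standard error of prediction under leave-one-out cross-validation.

    The full iterative calibration is re-run n times; the held-out compound
    never contributes to weights or parameters of the fold that predicts it.
    """
    training = list(training)
    n = len(training)
    if n < 4:
        raise ValueError(f"leave-one-out requires at least 4 compounds, got {n}")
    sq = []
    for i, held_out in enumerate(training):
        fold = training[:i] + training[i + 1 :]
        res = calibrate_iterative(
            fold,
            temperature=temperature,
            include_offset=include_offset,
            tol=tol,
            max_iter=max_iter,
        )
        pred = predict(res.parameters, held_out.energetics).dg_pred
        sq.append((held_out.dg_obs - pred) ** 2)
    return float(np.sqrt(np.mean(sq)))


def quality_metrics(obs, pred) -> QualityMetrics:
    """RMSE / SDEP and Pearson & Spearman correlations of predictions.

    RMSE and SDEP share the sqrt-mean-squared-deviation formula; the former
    names the training-set fit, the latter the error on held-out or test
    predictions. Correlations on a constant vector are undefined and
    reported as NaN. Spearman uses average ranks for ties.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be equal-length 1-D vectors")
    if obs.size < 2:
        raise ValueError("need at least two points")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r = rho = float("nan")
    else:
        r = float(stats.pearsonr(obs, pred).statistic)
        rho = float(stats.spearmanr(obs, pred).statistic)
    return QualityMetrics(rmse=rmse, sdep=rmse, r_pearson=r, rho_spearman=rho)
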