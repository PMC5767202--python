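"""Domain types and file I/O for interaction-energy data and trained models.

The central objects are :class:`CompoundEnergetics` — the ensemble-averaged
ligand–surrounding interaction energies of every bound-state simulation of a
compound plus its unbound (free in solution) reference — and
:class:`LIEParameters`, the empirical coefficients of the linear interaction
energy model.

Energy tables are long-form delimited text (comma or tab, autodetected) with
columns ``compound, pose, replicate, state, time_ps, v_vdw, v_ele`` where
``state`` is ``bound`` or ``unbound``. Trained models round-trip through a
versioned JSON schema.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE

MODEL_SCHEMA_VERSION = 1

ENERGY_TABLE_COLUMNS = [
    "compound",
    "pose",
    "replicate",
    "state",
    "time_ps",
    "v_vdw",
    "v_ele",
]


class ParseError(ValueError):
    """Malformed input table (missing column, bad value, duplicate row)."""


@dataclass(frozen=True)
class EnergyTrace:
    """Time series of ligand–surrounding interaction energies for one run.

    Parameters
    ----------
    times : array of frame times in ps, strictly increasing.
    v_vdw, v_ele : van der Waals / electrostatic energies per frame (kJ/mol).
    """

    times: np.ndarray
    v_vdw: np.ndarray
    v_ele: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        v_vdw = np.asarray(self.v_vdw, dtype=float)
        v_ele = np.asarray(self.v_ele, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "v_vdw", v_vdw)
        object.__setattr__(self, "v_ele", v_ele)
        if times.size == 0:
            raise ValueError("EnergyTrace needs at least one frame")
        if times.shape != v_vdw.shape or times.shape != v_ele.shape:
            raise ValueError("times and energies must have equal length")
        if not (np.all(np.isfinite(v_vdw)) and np.all(np.isfinite(v_ele))):
            raise ValueError("energies must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


def average_trace(trace: EnergyTrace, burn_in: float = 0.0) -> tuple[float, float]:
    """Ensemble-average (mean) vdW and electrostatic energies of a trace.

    Frames with time strictly greater than ``burn_in`` (ps) enter the mean;
    the default keeps every frame.
    """
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    mask = trace.times > burn_in
    if not mask.any():
        raise ValueError(
            f"no frames remain after burn-in {burn_in} ps "
            f"(trace ends at {trace.times[-1]} ps)"
        )
    return float(trace.v_vdw[mask].mean()), float(trace.v_ele[mask].mean())


@dataclass(frozen=True)
class SimulationRecord:
    """Averaged bound-state energies of one independent MD run of one pose."""

    pose_id: str
    replicate_id: str
    mean_vdw: float
    mean_ele: float

    def __post_init__(self):
        if not (math.isfinite(self.mean_vdw) and math.isfinite(self.mean_ele)):
            raise ValueError("simulation means must be finite")


@dataclass(frozen=True)
class UnboundReference:
    """Averaged energies of the solvated ligand free in solution."""

    mean_vdw: float
    mean_ele: float

    def __post_init__(self):
        if not (math.isfinite(self.mean_vdw) and math.isfinite(self.mean_ele)):
            raise ValueError("unbound means must be finite")


@dataclass(frozen=True)
class CompoundEnergetics:
    """All bound-state runs plus the unbound reference for one ligand."""

    compound_id: str
    bound: tuple[SimulationRecord, ...]
    unbound: UnboundReference

    def __post_init__(self):
        bound = tuple(self.bound)
        object.__setattr__(self, "bound", bound)
        if len(bound) < 1:
            raise ValueError(f"{self.compound_id}: at least one bound record required")
        keys = [(r.pose_id, r.replicate_id) for r in bound]
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"{self.compound_id}: duplicate (pose, replicate) bound records"
            )

    @property
    def n_simulations(self) -> int:
        return len(self.bound)


@dataclass(frozen=True)
class LIEParameters:
    """Empirical LIE coefficients: dG = alpha*dVvdw + beta*dVele + gamma."""

    alpha: float
    beta: float
    gamma: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "temperature"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


@dataclass(frozen=True)
class TrainingCompound:
    """A calibration compound: observed affinity plus simulation energetics.

    ``fingerprint`` is a boolean bit-vector; the decomposition vectors hold
    per-residue contributions to the total vdW / electrostatic interaction
    energies, on one residue index shared across the training set.
    """

    compound_id: str
    dg_obs: float
    energetics: CompoundEnergetics
    fingerprint: Optional[np.ndarray] = None
    decomposition_vdw: Optional[np.ndarray] = None
    decomposition_ele: Optional[np.ndarray] = None

    def __post_init__(self):
        if not math.isfinite(self.dg_obs):
            raise ValueError("dg_obs must be finite")
        for name in ("fingerprint", "decomposition_vdw", "decomposition_ele"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v)
                if name == "fingerprint":
                    arr = arr.astype(bool)
                else:
                    arr = arr.astype(float)
                object.__setattr__(self, name, arr)


@dataclass
class ModelFile:
    """Serializable trained model: parameters, training summary, provenance."""

    parameters: LIEParameters
    training_ids: list[str] = field(default_factory=list)
    dg_obs: list[float] = field(default_factory=list)
    dg_pred: list[float] = field(default_factory=list)
    ad_reference: Optional["object"] = None  # applicability.ADReference
    provenance: dict = field(default_factory=dict)


def read_energy_table(path) -> list[CompoundEnergetics]:
    """Read a long-form energy table into per-compound energetics.

    Each (compound, pose, replicate, state) group is averaged over its time
    frames; bound groups become :class:`SimulationRecord` entries, unbound
    rows (pose/replicate ignored for grouping identity) are pooled into the
    :class:`UnboundReference`.
    """
    df = _read_table(path)
    missing = [c for c in ENERGY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("time_ps", "v_vdw", "v_ele"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # header is row 1
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = vals
    bad_state = ~df["state"].isin(["bound", "unbound"])
    if bad_state.any():
        row = int(df.index[bad_state][0]) + 2
        raise ParseError(
            f"{path}: unknown state {df['state'][bad_state].iloc[0]!r} at row {row}"
        )

    out = []
    for cid, grp in df.groupby("compound", sort=True):
        bound_grp = grp[grp["state"] == "bound"]
        unbound_grp = grp[grp["state"] == "unbound"]
        if unbound_grp.empty:
            raise ParseError(f"{path}: compound {cid!r} has no unbound reference")
        if bound_grp.empty:
            raise ParseError(f"{path}: compound {cid!r} has no bound simulations")
        records = []
        for (pose, rep), sim in bound_grp.groupby(["pose", "replicate"], sort=True):
            if sim["time_ps"].duplicated().any():
                raise ParseError(
                    f"{path}: duplicate time frame for compound {cid!r} "
                    f"pose {pose!r} replicate {rep!r}"
                )
            records.append(
                SimulationRecord(
                    pose_id=str(pose),
                    replicate_id=str(rep),
                    mean_vdw=float(sim["v_vdw"].mean()),
                    mean_ele=float(sim["v_ele"].mean()),
                )
            )
        unbound = UnboundReference(
            mean_vdw=float(unbound_grp["v_vdw"].mean()),
            mean_ele=float(unbound_grp["v_ele"].mean()),
        )
        out.append(
            CompoundEnergetics(compound_id=str(cid), bound=tuple(records), unbound=unbound)
        )
    return out


def read_training_table(path) -> pd.DataFrame:
    """Read a training table with ``compound_id`` and one affinity column.

    Exactly one of ``ic50_molar`` or ``dg_obs_kjmol`` must be present.
    Returns the parsed DataFrame; conversion to dG is the caller's job.
    """
    df = _read_table(path)
    if "compound_id" not in df.columns:
        raise ParseError(f"{path}: missing column 'compound_id'")
    has_ic50 = "ic50_molar" in df.columns
    has_dg = "dg_obs_kjmol" in df.columns
    if has_ic50 == has_dg:
        raise ParseError(
            f"{path}: exactly one of 'ic50_molar' or 'dg_obs_kjmol' required"
        )
    col = "ic50_molar" if has_ic50 else "dg_obs_kjmol"
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        row = int(df.index[vals.isna()][0]) + 2
        raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
    df[col] = vals
    return df


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","  # comma or tab, autodetected
    return pd.read_csv(path, sep=sep)


# --- model (de)serialization -------------------------------------------------

def write_model(model: ModelFile, path) -> None:
    """Write a trained model to versioned JSON."""
    from . import applicability  # local import: avoid cycle at module load

    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "parameters": dataclasses.asdict(model.parameters),
        "training": {
            "ids": list(model.training_ids),
            "dg_obs": [float(x) for x in model.dg_obs],
            "dg_pred": [float(x) for x in model.dg_pred],
        },
        "ad_reference": (
            applicability.ad_reference_to_dict(model.ad_reference)
            if model.ad_reference is not None
            else None
        ),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> ModelFile:
    """Read a model written by :func:`write_model`."""
    from . import applicability

    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ParseError(
            f"{path}: unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    params = LIEParameters(**payload["parameters"])
    ad_ref = payload.get("ad_reference")
    return ModelFile(
        parameters=params,
        training_ids=list(payload["training"]["ids"]),
        dg_obs=[float(x) for x in payload["training"]["dg_obs"]],
        dg_pred=[float(x) for x in payload["training"]["dg_pred"]],
        ad_reference=(
            applicability.ad_reference_from_dict(ad_ref) if ad_ref is not None else None
        ),
        provenance=payload.get("provenance", {}),
    )
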