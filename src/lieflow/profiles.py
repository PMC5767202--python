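"""Rule-based protein–ligand interaction typing and frequency profiles.

Each MD frame is scanned for typed contacts between the ligand and every
protein residue under explicit geometric rules (defaults below, fully
configurable through a YAML rules file):

* hydrogen bond — donor-heavy-atom to acceptor distance <= 0.35 nm and a
  donor-H...acceptor angle >= 120 degrees;
* hydrophobic contact — two apolar carbons within 0.40 nm.

A residue scores at most once per interaction type per frame; a profile is
the per-residue, per-type fraction of frames in which the contact occurs.
Because hydrophobic contacts are far more abundant than directional ones,
display tables conventionally divide the hydrophobic column by 10 before
plotting stacked bars.

Donor/acceptor/hydrophobe roles are input metadata supplied alongside the
structures (an annotation sidecar), not perceived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ROLE_VOCABULARY = frozenset({"donor", "acceptor", "hydrophobe", "none"})
INTERACTION_TYPES = ("hbond", "hydrophobic")


@dataclass
class RuleSet:
    """Geometric thresholds for contact typing (distances nm, angles deg)."""

    hbond_distance: float = 0.35
    hbond_angle: float = 120.0
    hydrophobic_distance: float = 0.40

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {"hbond_distance", "hbond_angle", "hydrophobic_distance"}
        if unknown:
            raise ValueError(f"unknown rule keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class Atom:
    """One annotated heavy atom; ``h_coords`` holds attached hydrogens."""

    name: str
    element: str
    coords: np.ndarray  # (3,) nm
    roles: frozenset = frozenset()
    h_coords: tuple = ()

    def __post_init__(self):
        bad = set(self.roles) - ROLE_VOCABULARY
        if bad:
            raise ValueError(f"unknown atom roles: {sorted(bad)}")
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(
            self, "h_coords", tuple(np.asarray(h, dtype=float) for h in self.h_coords)
        )


@dataclass
class FrameGeometry:
    """Ligand atoms and protein atoms grouped by residue for one frame."""

    ligand: list
    residues: dict  # residue id -> list[Atom]


def _is_hbond(donor: Atom, acceptor: Atom, rules: RuleSet) -> bool:
    d = float(np.linalg.norm(donor.coords - acceptor.coords))
    if d > rules.hbond_distance:
        return False
    for h in donor.h_coords:
        v1 = donor.coords - h
        v2 = acceptor.coords - h
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        cosang = np.clip(v1 @ v2 / denom, -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) >= rules.hbond_angle:
            return True
    return False


def _is_hydrophobic(a: Atom, b: Atom, rules: RuleSet) -> bool:
    if a.element.upper() != "C" or b.element.upper() != "C":
        return False
    if "hydrophobe" not in a.roles or "hydrophobe" not in b.roles:
        return False
    return float(np.linalg.norm(a.coords - b.coords)) <= rules.hydrophobic_distance


def classify_frame(frame: FrameGeometry, rules: Optional[RuleSet] = None) -> dict:
    """Typed ligand contacts per residue: {residue: {"hbond", ...}}.

    Hydrogen bonds are checked in both directions (ligand donor to protein
    acceptor and vice versa); each residue records a type at most once.
    """
    rules = rules or RuleSet()
    contacts: dict = {}
    for res_id, res_atoms in frame.residues.items():
        found = set()
        for la in frame.ligand:
            for pa in res_atoms:
                if "hbond" not in found:
                    if ("donor" in la.roles and "acceptor" in pa.roles and _is_hbond(la, pa, rules)) or (
                        "donor" in pa.roles and "acceptor" in la.roles and _is_hbond(pa, la, rules)
                    ):
                        found.add("hbond")
                if "hydrophobic" not in found and _is_hydrophobic(la, pa, rules):
                    found.add("hydrophobic")
            if found == set(INTERACTION_TYPES):
                break
        if found:
            contacts[res_id] = found
    return contacts


def profile(frames: Sequence[FrameGeometry], rules: Optional[RuleSet] = None) -> pd.DataFrame:
    """Per-residue, per-type fraction of frames with at least one contact."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to profile")
    rules = rules or RuleSet()
    residues = sorted({r for f in frames for r in f.residues})
    counts = pd.DataFrame(0.0, index=residues, columns=list(INTERACTION_TYPES))
    for f in frames:
        for res, types in classify_frame(f, rules).items():
            for t in types:
                counts.loc[res, t] += 1
    return counts / len(frames)


def display_table(freq: pd.DataFrame, hydrophobic_divisor: float = 10.0) -> pd.DataFrame:
    """Scale the hydrophobic column down for display alongside rarer types."""
    out = freq.copy()
    if "hydrophobic" in out.columns:
        out["hydrophobic"] = out["hydrophobic"] / hydrophobic_divisor
    return out


# --- trajectory + annotation input ---------------------------------------------

_PDB_TO_NM = 0.1
_H_ATTACH_CUTOFF_NM = 0.125  # hydrogens within this distance belong to a donor


def read_annotations(path) -> dict:
    """Annotation sidecar CSV with columns ``atom_serial, role``.

    An atom may appear on several rows (one per role); role ``none`` marks
    an atom with no special role.
    """
    df = pd.read_csv(path)
    for col in ("atom_serial", "role"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ann: dict = {}
    for _, row in df.iterrows():
        role = str(row["role"]).strip()
        if role not in ROLE_VOCABULARY:
            raise ValueError(f"{path}: unknown role {role!r}")
        ann.setdefault(int(row["atom_serial"]), set()).add(role)
    return {k: frozenset(v - {"none"}) for k, v in ann.items()}


def read_frames_pdb(path, annotations: dict, ligand_resname: str = "LIG") -> list:
    """Read a multi-model PDB trajectory into annotated frames.

    Hydrogens are attached to the nearest annotated donor within 0.125 nm;
    every heavy atom must appear in the annotation sidecar.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    for model in structure:
        heavy, hydrogens = [], []
        for chain in model:
            for residue in chain:
                res_name = residue.get_resname().strip()
                res_id = f"{res_name}{residue.get_id()[1]}"
                for atom in residue:
                    elem = (atom.element or atom.get_name()[:1]).strip().upper()
                    entry = (atom.get_serial_number(), atom.get_name(), elem,
                             np.array(atom.coord, dtype=float) * _PDB_TO_NM,
                             res_name, res_id)
                    (hydrogens if elem == "H" else heavy).append(entry)
        missing = [e[0] for e in heavy if e[0] not in annotations]
        if missing:
            raise ValueError(f"{path}: atoms without annotations: {missing[:10]}")

        atoms = []
        for serial, name, elem, coords, res_name, res_id in heavy:
            roles = annotations[serial]
            h_coords = []
            if "donor" in roles:
                h_coords = [
                    h[3] for h in hydrogens
                    if np.linalg.norm(h[3] - coords) <= _H_ATTACH_CUTOFF_NM
                ]
            atoms.append(
                (res_name, res_id, Atom(name=name, element=elem, coords=coords,
                                        roles=roles, h_coords=tuple(h_coords)))
            )
        ligand = [a for rn, _, a in atoms if rn == ligand_resname]
        residues: dict = {}
        for rn, rid, a in atoms:
            if rn != ligand_resname:
                residues.setdefault(rid, []).append(a)
        if not ligand:
            raise ValueError(f"{path}: no ligand residue {ligand_resname!r} found")
        frames.append(FrameGeometry(ligand=ligand, residues=residues))
    if not frames:
        raise ValueError(f"{path}: no models found")
    return frames
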