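"""Per-frame, per-residue amide environment features.

Two counts drive the phenomenological protection-factor model: N_C, the
number of heavy atoms near the backbone amide nitrogen (local packing),
and N_H, the number of oxygen acceptors hydrogen-bonded to the amide
hydrogen.  Defaults follow the Best-Vendruscolo parameterization: a
6.5 A heavy-atom cutoff around the amide N with residues i-2..i+2
excluded, and a 2.4 A H...O cutoff for hydrogen bonds.

Prolines and the protein's N-terminal residue carry no exchange-relevant
amide and are excluded everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FeatureError, StructureError
from .types import StructuralEnsemble

AMIDE_H_NAMES = ("H", "HN", "D", "DN")
AMIDE_BOND_LENGTH = 1.01  # angstrom, N-H


@dataclass(frozen=True)
class FeatureParams:
    """Cutoffs and switches for the feature stage."""

    contact_cutoff_A: float = 6.5
    hbond_cutoff_A: float = 2.4
    exclusion_window: int = 2
    reconstruct_H: bool = True
    include_waters: bool = False


class _Frame:
    """Annotated coordinates of one frame, indexed for neighbor queries."""

    def __init__(self, coords: np.ndarray, atoms: pd.DataFrame, include_waters=False):
        self.coords = np.asarray(coords, dtype=float)
        self.atom_name = atoms["atom_name"].to_numpy(dtype=str)
        self.res_id = atoms["res_id"].to_numpy(dtype=int)
        self.res_name = atoms["res_name"].to_numpy(dtype=str)
        self.element = atoms["element"].to_numpy(dtype=str)
        if not include_waters:
            keep = ~np.isin(self.res_name, ("HOH", "WAT", "SOL", "TIP3"))
            if not keep.all():
                self._mask(keep)
        self.heavy = self.element != "H"
        self.is_oxygen = self.element == "O"
        self._heavy_tree = None
        self._oxy_tree = None

    def _mask(self, keep):
        self.coords = self.coords[keep]
        self.atom_name = self.atom_name[keep]
        self.res_id = self.res_id[keep]
        self.res_name = self.res_name[keep]
        self.element = self.element[keep]

    @property
    def heavy_tree(self):
        if self._heavy_tree is None:
            self._heavy_tree = cKDTree(self.coords[self.heavy])
        return self._heavy_tree

    @property
    def oxy_tree(self):
        if self._oxy_tree is None:
            self._oxy_tree = cKDTree(self.coords[self.is_oxygen])
        return self._oxy_tree

    def atom_index(self, residue: int, names) -> int | None:
        sel = (self.res_id == residue) & np.isin(self.atom_name, names)
        idx = np.flatnonzero(sel)
        return int(idx[0]) if idx.size else None

    def first_residue(self) -> int:
        return int(self.res_id.min())

    def residue_name(self, residue: int) -> str:
        idx = np.flatnonzero(self.res_id == residue)
        if idx.size == 0:
            raise StructureError(f"residue {residue} absent from frame")
        return str(self.res_name[idx[0]])


def _check_applicable(frame: _Frame, residue: int) -> None:
    if frame.residue_name(residue) == "PRO":
        raise FeatureError(f"residue {residue} is proline: no exchangeable amide")
    if residue == frame.first_residue():
        raise FeatureError(f"residue {residue} is the N-terminus: no amide modelled")


def amide_hydrogen_position(frame: _Frame, residue: int, reconstruct: bool = True):
    """Coordinates of the amide hydrogen; reconstructed when absent.

    Reconstruction places H 1.01 A from N along the direction opposite the
    bisector of the two heavy atoms bonded to N (CA of the residue and C
    of the preceding residue) -- the standard trans-amide geometry.
    """
    h_idx = frame.atom_index(residue, AMIDE_H_NAMES)
    if h_idx is not None:
        return frame.coords[h_idx]
    if not reconstruct:
        raise FeatureError(f"residue {residue}: amide H missing and reconstruction off")
    n_idx = frame.atom_index(residue, ("N",))
    ca_idx = frame.atom_index(residue, ("CA",))
    cprev_idx = frame.atom_index(residue - 1, ("C",))
    if n_idx is None:
        raise StructureError(f"residue {residue}: no amide N")
    if ca_idx is None or cprev_idx is None:
        raise FeatureError(
            f"residue {residue}: cannot reconstruct amide H (missing CA or C(i-1))"
        )
    n = frame.coords[n_idx]
    u1 = frame.coords[ca_idx] - n
    u2 = frame.coords[cprev_idx] - n
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    d /= np.linalg.norm(d)
    return n + AMIDE_BOND_LENGTH * d


def compute_contacts(
    frame: _Frame,
    residue: int,
    cutoff: float = 6.5,
    exclusion_window: int = 2,
) -> int:
    """Heavy atoms within ``cutoff`` of the amide N, excluding atoms of
    residues i-window..i+window (the residue itself included)."""
    _check_applicable(frame, residue)
    n_idx = frame.atom_index(residue, ("N",))
    if n_idx is None:
        raise StructureError(f"residue {residue}: no amide N")
    neighbors = frame.heavy_tree.query_ball_point(frame.coords[n_idx], cutoff)
    heavy_res = frame.res_id[frame.heavy]
    count = 0
    for j in neighbors:
        if abs(int(heavy_res[j]) - residue) > exclusion_window:
            count += 1
    return count


def compute_hbonds(frame: _Frame, residue: int, h_cutoff: float = 2.4,
                   reconstruct_H: bool = True) -> int:
    """Oxygen acceptors within ``h_cutoff`` of the amide H, excluding the
    residue's own atoms."""
    _check_applicable(frame, residue)
    h_pos = amide_hydrogen_position(frame, residue, reconstruct=reconstruct_H)
    neighbors = frame.oxy_tree.query_ball_point(h_pos, h_cutoff)
    oxy_res = frame.res_id[frame.is_oxygen]
    return sum(1 for j in neighbors if int(oxy_res[j]) != residue)


def exchange_competent_residues(frame: _Frame) -> list[int]:
    """All residues with a modelled amide: everything except prolines and
    the first residue."""
    first = frame.first_residue()
    out = []
    for res in np.unique(frame.res_id):
        res = int(res)
        if res == first:
            continue
        if frame.residue_name(res) == "PRO":
            continue
        out.append(res)
    return out


def featurize_ensemble(
    ensemble: StructuralEnsemble, params: FeatureParams | None = None
) -> pd.DataFrame:
    """Compute the (frame, residue) -> (N_C, N_H) table for an ensemble.

    Ensembles that already carry precomputed features are passed through
    unchanged.  Output is deterministic: rows ordered by frame then
    residue.
    """
    if ensemble.has_features:
        return ensemble.features
    if ensemble.coords is None:
        raise StructureError("ensemble has neither coordinates nor features")
    params = params or FeatureParams()

    rows = []
    residues = None
    for i, frame_id in enumerate(ensemble.frame_ids):
        frame = _Frame(
            ensemble.coords[i], ensemble.atoms, include_waters=params.include_waters
        )
        frame_residues = exchange_competent_residues(frame)
        if residues is None:
            residues = frame_residues
        elif frame_residues != residues:
            raise StructureError(
                f"frame {frame_id}: residue set differs from first frame"
            )
        for res in frame_residues:
            n_c = compute_contacts(
                frame, res, cutoff=params.contact_cutoff_A,
                exclusion_window=params.exclusion_window,
            )
            n_h = compute_hbonds(
                frame, res, h_cutoff=params.hbond_cutoff_A,
                reconstruct_H=params.reconstruct_H,
            )
            rows.append((frame_id, res, n_c, n_h))
    return pd.DataFrame(rows, columns=["frame_id", "residue", "N_C", "N_H"])


def make_frame(coords: np.ndarray, atoms: pd.DataFrame, **kwargs) -> _Frame:
    """Public constructor for a single annotated frame."""
    return _Frame(coords, atoms, **kwargs)
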