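"""Readers and writers for ensembles, uptake tables, peptide maps and weights.

All CSV files are comma-separated UTF-8 with '.' decimals.  Uptake tables
carry a leading metadata comment line ``# units: Da`` or ``# units:
fraction`` so that raw and MaxD-normalized tables round-trip with their
unit flag intact; files without the comment are assumed raw (Da).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, StructureError, ValidationError
from .types import UPTAKE_COLUMNS, PeptideSegment, StructuralEnsemble, UptakeTable

log = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _prescan_pdb(path: Path) -> None:
    """Fail early with a line number on malformed ATOM coordinate fields."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: truncated ATOM record at line {lineno}")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed ATOM coordinates at line {lineno}"
                ) from exc


def read_ensemble_pdb(path, state_label: str) -> StructuralEnsemble:
    """Read a multi-model PDB file into a :class:`StructuralEnsemble`.

    One frame per MODEL record (a file without MODEL records yields one
    frame).  Heteroatoms and alternate locations beyond the first are
    dropped with a warning; insertion codes are rejected.  Initial
    weights are the uniform prior.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    _prescan_pdb(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureError(f"{path}: inconsistent models ({exc})") from exc

    if np.any(stack.ins_code != ""):
        raise StructureError(f"{path}: insertion codes are not supported")
    if stack.hetero.any():
        n_het = int(stack.hetero.sum())
        log.warning("%s: dropping %d heteroatoms", path, n_het)
        stack = stack[..., ~stack.hetero]
    if stack.array_length() == 0:
        raise StructureError(f"{path}: no protein atoms")

    atoms = pd.DataFrame(
        {
            "atom_name": stack.atom_name,
            "res_id": stack.res_id.astype(int),
            "res_name": stack.res_name,
            "element": np.char.upper(stack.element.astype(str)),
        }
    )
    n_frames = stack.stack_depth()
    return StructuralEnsemble(
        frame_ids=[f"{state_label}_{i}" for i in range(n_frames)],
        state_labels=[state_label] * n_frames,
        coords=stack.coord.copy(),
        atoms=atoms,
    )


def ensemble_sequence(ensemble: StructuralEnsemble) -> dict[int, str]:
    """Map residue id -> one-letter code from the atom annotation table."""
    if ensemble.atoms is None:
        raise ValidationError("ensemble carries no atom annotations")
    seq = {}
    for res_id, res_name in (
        ensemble.atoms[["res_id", "res_name"]].drop_duplicates().itertuples(index=False)
    ):
        try:
            seq[int(res_id)] = _THREE_TO_ONE[str(res_name)]
        except KeyError as exc:
            raise ValidationError(f"unknown residue name {res_name!r}") from exc
    return seq


# ---------------------------------------------------------------------------
# uptake tables


def read_uptake_csv(path) -> UptakeTable:
    """Read a replicate uptake table; returns the table (peptide segments
    are available as ``table.peptides``)."""
    path = Path(path)
    is_normalized = False
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "fraction" in first:
            is_normalized = True
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    table = UptakeTable(df, is_normalized=is_normalized)
    for seg in table.peptides:  # validates spans/sequences
        pass
    return table


def write_uptake_csv(table: UptakeTable, path) -> None:
    units = "fraction" if table.is_normalized else "Da"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {units}\n")
        table.data.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# peptide maps


def read_peptide_map(path) -> list[PeptideSegment]:
    df = pd.read_csv(path)
    required = ["peptide_id", "start", "end", "sequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        PeptideSegment(str(r.peptide_id), int(r.start), int(r.end), str(r.sequence))
        for r in df.itertuples(index=False)
    ]


def write_peptide_map(peptides: list[PeptideSegment], path) -> None:
    pd.DataFrame(
        {
            "peptide_id": [p.peptide_id for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "sequence": [p.sequence for p in peptides],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# weights


def write_weights(result, path) -> None:
    """Write per-frame weights; full float repr so read-back is bit-exact."""
    df = pd.DataFrame(
        {
            "frame_id": result.frame_ids,
            "state_label": result.state_labels,
            "initial_weight": result.initial_weights,
            "final_weight": result.final_weights,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["frame_id", "state_label", "initial_weight", "final_weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) and not np.isclose(df["final_weight"].sum(), 1.0, rtol=1e-9, atol=1e-9):
        raise ValidationError(f"{path}: final weights do not sum to 1")
    return df


# ---------------------------------------------------------------------------
# feature tables


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["frame_id", "residue", "N_C", "N_H"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df[["N_C", "N_H"]] < 0).any().any():
        raise ValidationError(f"{path}: negative feature counts")
    return df
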