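"""PDB input/output: Cα trace extraction and superposed-coordinate output.

Internal residue indexing is 0-based and dense over observed Cα atoms:
gaps in author numbering do not create index gaps.  All fragment indices
used by the alignment engine refer to these internal indices; output files
report both the internal index and the author residue number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, TYPE_CHECKING

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

if TYPE_CHECKING:  # pragma: no cover
    from .chaining import Alignment

__all__ = [
    "CaTrace",
    "ChainNotFoundError",
    "EmptyTraceError",
    "load_ca_trace",
    "write_ca_pdb",
    "write_superposed_pdb",
]


class ChainNotFoundError(KeyError):
    """Requested chain is absent from the model."""


class EmptyTraceError(ValueError):
    """The requested chain contains no Cα atoms."""


@dataclass
class CaTrace:
    """One chain's ordered Cα trace.

    ``residue_labels[k]`` is ``(author_resnum, insertion_code, resname)`` for
    the residue whose Cα is ``coords[k]``.
    """

    structure_id: str
    chain_id: str
    residue_labels: List[Tuple[int, str, str]]
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.residue_labels) != self.coords.shape[0]:
            raise ValueError("residue_labels and coords lengths differ")
        if self.coords.shape[0] < 1:
            raise EmptyTraceError("empty trace")

    def __len__(self) -> int:
        return self.coords.shape[0]


def _pick_altloc(atom):
    """Resolve a possibly-disordered atom to a single Cα.

    Highest occupancy wins; occupancy ties prefer a blank altloc or 'A'.
    """
    if not isinstance(atom, DisorderedAtom):
        return atom
    children = atom.disordered_get_list()

    def key(a):
        occ = a.get_occupancy()
        occ = 0.0 if occ is None else occ
        preferred = a.get_altloc() in (" ", "", "A")
        return (occ, preferred)

    return max(children, key=key)


def load_ca_trace(path, chain: str, model: int = 0) -> CaTrace:
    """Read a PDB file and extract one chain's Cα trace.

    Parameters
    ----------
    path : str or Path
        PDB file to read.
    chain : str
        Author chain identifier (required; no guessing).
    model : int
        0-based model index; defaults to the first model.

    Residues without a Cα atom are skipped.  Hetero residues that carry a Cα
    (e.g. MSE within the polymer) are kept; waters are not.  Disordered Cα
    atoms are resolved to the highest-occupancy altloc.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such PDB file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise EmptyTraceError(f"no models in {path}")
    if model >= len(models):
        raise ValueError(f"model index {model} out of range ({len(models)} models)")
    mdl = models[model]
    chain_ids = [c.id for c in mdl]
    if chain not in chain_ids:
        raise ChainNotFoundError(
            f"chain {chain!r} not found in {path}; available chains: {chain_ids}"
        )
    labels: List[Tuple[int, str, str]] = []
    coords: List[np.ndarray] = []
    for residue in mdl[chain]:
        hetflag, resnum, icode = residue.id
        if hetflag == "W":
            continue
        if "CA" not in residue:
            continue
        ca = _pick_altloc(residue["CA"])
        labels.append((int(resnum), icode.strip(), residue.get_resname().strip()))
        coords.append(np.asarray(ca.get_coord(), dtype=float))
    if not coords:
        raise EmptyTraceError(f"empty trace: chain {chain!r} of {path} has no CA atoms")
    return CaTrace(
        structure_id=path.stem,
        chain_id=chain,
        residue_labels=labels,
        coords=np.vstack(coords),
    )


def _atom_line(serial: int, resname: str, chain: str, resnum: int, icode: str,
               xyz, occupancy: float = 1.0, bfactor: float = 0.0) -> str:
    icode = icode or " "
    return (
        f"ATOM  {serial:5d}  CA  {resname:>3s} {chain}{resnum:4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {'C':>2s}"
    )


def write_ca_pdb(trace: CaTrace, out, chain_id: str | None = None) -> None:
    """Write a Cα-only PDB file for a single trace."""
    chain = chain_id or trace.chain_id
    lines = []
    for k, (resnum, icode, resname) in enumerate(trace.residue_labels):
        lines.append(_atom_line(k + 1, resname, chain, resnum, icode, trace.coords[k]))
    lines.append("END")
    Path(out).write_text("\n".join(lines) + "\n")


def write_superposed_pdb(trace_a: CaTrace, trace_b: CaTrace,
                         alignment: "Alignment", out) -> None:
    """Write the flexible superposition as a multi-MODEL PDB file.

    Each rigid region gets its own MODEL record: chain A is repeated
    unchanged, and the B residues belonging to that region are written after
    applying the region's superposition.  The region id (1-based) is stored
    in the B-factor column.  One MODEL per region is used because a flexible
    alignment has no single global transform.
    """
    lines = []
    regions = alignment.regions
    if not regions:
        raise ValueError("cannot write superposed output for an empty alignment")
    for ridx, region in enumerate(regions, start=1):
        sup = region.superposition
        lines.append(f"MODEL     {ridx:4d}")
        serial = 1
        for k, (resnum, icode, resname) in enumerate(trace_a.residue_labels):
            lines.append(_atom_line(serial, resname, "A", resnum, icode,
                                    trace_a.coords[k], bfactor=0.0))
            serial += 1
        b_indices = sorted({jb for (_, jb) in region.pairs()})
        moved = sup.apply(trace_b.coords[b_indices]) if b_indices else np.zeros((0, 3))
        for pos, jb in enumerate(b_indices):
            resnum, icode, resname = trace_b.residue_labels[jb]
            lines.append(_atom_line(serial, resname, "B", resnum, icode,
                                    moved[pos], bfactor=float(ridx)))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(out).write_text("\n".join(lines) + "\n")
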