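"""PDB reading/writing for repeat models (via biotite).

Repeat boundaries, anchors and linker ranges are not expressible in
plain ATOM records, so they are carried in ``REMARK  99`` lines of the
form::

    REMARK  99 REPEAT <id> <chain> <first> <last> <anchor_n> <anchor_c> <lnk_lo> <lnk_hi>

(``-`` for an absent linker).  Files written here round-trip exactly to
the 3-decimal coordinate precision of the PDB format.  Foreign PDB
files without the remarks are read as one repeat per chain with the
first/last residues taken as anchors.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .repeats import RepeatStructure

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_ONE = {v: k for k, v in _THREE.items()}
_ATOM_NAMES = ("N", "CA", "C")


class PDBParseError(ValueError):
    pass


def _to_atom_array(repeats: list[RepeatStructure]) -> struc.AtomArray:
    n_atoms = sum(3 * r.n_res for r in repeats)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for rep in repeats:
        for j, res_id in enumerate(rep.res_ids):
            for k, name in enumerate(_ATOM_NAMES):
                arr.coord[i] = rep.coords[j, k]
                arr.chain_id[i] = rep.chain_label
                arr.res_id[i] = res_id
                arr.res_name[i] = _THREE.get(rep.sequence[j], "ALA")
                arr.atom_name[i] = name
                arr.element[i] = name[0]
                arr.hetero[i] = False
                i += 1
    return arr


def _remark_lines(repeats: list[RepeatStructure]) -> list[str]:
    lines = []
    for rep in repeats:
        lnk = (
            f"{rep.linker_range[0]} {rep.linker_range[1]}"
            if rep.linker_range is not None
            else "- -"
        )
        lines.append(
            f"REMARK  99 REPEAT {rep.repeat_id} {rep.chain_label} "
            f"{rep.res_ids[0]} {rep.res_ids[-1]} {rep.anchor_n} {rep.anchor_c} {lnk}"
        )
    return lines


def write_model_pdb(model, path: str | Path) -> None:
    """Write repeats (or several models of them) to a PDB file.

    ``model`` is a list of :class:`RepeatStructure` for a single-model
    file, or a list of such lists for a multi-model (trajectory) file;
    all models of a trajectory must share the same topology.
    """
    path = Path(path)
    multi = bool(model) and isinstance(model[0], list)
    first = model[0] if multi else model
    pdb = PDBFile()
    if multi:
        arrays = [_to_atom_array(m) for m in model]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(first))
    pdb.lines = _remark_lines(first) + pdb.lines
    pdb.write(str(path))


def _validate_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: truncated ATOM record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate field in ATOM record"
                    ) from None


def read_repeats_pdb(path: str | Path, model: int | None = None) -> list[RepeatStructure]:
    """Read a PDB file written by :func:`write_model_pdb` back into repeats.

    For multi-model files ``model`` selects the (1-based) model; by
    default the first model is returned.
    """
    path = Path(path)
    _validate_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=model or 1)
    except Exception as exc:  # pragma: no cover - biotite error paths vary
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    specs = []
    for line in pdb.lines:
        if line.startswith("REMARK  99 REPEAT"):
            parts = line.split()[3:]
            rid, chain, first, last, a_n, a_c, l_lo, l_hi = parts
            specs.append(
                (rid, chain, int(first), int(last), int(a_n), int(a_c),
                 None if l_lo == "-" else (int(l_lo), int(l_hi)))
            )
    if not specs:
        specs = [
            (f"chain_{cid}", cid,
             int(arr.res_id[arr.chain_id == cid].min()),
             int(arr.res_id[arr.chain_id == cid].max()),
             int(arr.res_id[arr.chain_id == cid].min()),
             int(arr.res_id[arr.chain_id == cid].max()), None)
            for cid in np.unique(arr.chain_id)
        ]

    repeats = []
    for rid, chain, first, last, a_n, a_c, linker in specs:
        mask = (arr.chain_id == chain) & (arr.res_id >= first) & (arr.res_id <= last)
        sub = arr[mask]
        res_ids = np.unique(sub.res_id)
        coords = np.empty((len(res_ids), 3, 3))
        seq = []
        for j, res_id in enumerate(res_ids):
            res = sub[sub.res_id == res_id]
            for k, name in enumerate(_ATOM_NAMES):
                sel = res[res.atom_name == name]
                if len(sel) != 1:
                    raise PDBParseError(
                        f"residue {chain}:{res_id} is missing backbone atom {name}"
                    )
                coords[j, k] = sel.coord[0]
            seq.append(_ONE.get(res.res_name[0], "A"))
        repeats.append(
            RepeatStructure(
                repeat_id=rid,
                res_ids=res_ids,
                sequence="".join(seq),
                coords=coords,
                anchor_n=a_n,
                anchor_c=a_c,
                linker_range=linker,
                chain_label=chain,
            )
        )
    return repeats


def read_image_grid(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited numeric grid as a 2-D image array."""
    grid = np.loadtxt(path)
    if grid.ndim != 2:
        raise ValueError(f"{path} is not a 2-D numeric grid")
    return grid


def write_image_grid(path: str | Path, pixels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(pixels, dtype=float), fmt="%.6g")
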