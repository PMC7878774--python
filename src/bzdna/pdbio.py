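"""Multi-model PDB reading and writing (PDB v3.3 fixed columns).

Only ATOM/HETATM/MODEL/ENDMDL/TER/END records are interpreted; HETATM
water and ion records are skipped by default. Prime characters in atom
names are accepted as both the typographic prime and the ASCII apostrophe
on read and normalised to the apostrophe; files are written with the
apostrophe. Coordinates round-trip at PDB precision (3 decimals).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .geometry import Atom, Frame

__all__ = ["PDBFormatError", "read_multimodel_pdb", "write_multimodel_pdb"]

_SOLVENT_RESNAMES = {"HOH", "WAT", "NA", "CL", "MG", "K", "NA+", "CL-"}


class PDBFormatError(ValueError):
    """Malformed or internally inconsistent PDB content."""


def _normalise_name(raw: str) -> str:
    return raw.strip().replace("′", "'").replace("*", "'")


def read_multimodel_pdb(
    path, *, skip_solvent: bool = True, chain_default: str = "A"
) -> list[Frame]:
    """Read a (possibly multi-model) PDB file into a list of Frames.

    One Frame per MODEL block; a file without MODEL records yields a single
    Frame. All models must contain the same atoms in the same order.

    Raises
    ------
    PDBFormatError
        On a malformed ATOM/HETATM record (the message names the line
        number) or on inconsistent atom identity/count across models (the
        message names the model).
    """
    frames: list[Frame] = []
    atoms: list[Atom] = []
    model_index = 1
    in_model = False
    saw_model_record = False

    def flush(midx: int):
        nonlocal atoms
        frames.append(Frame(atoms, model_index=midx))
        atoms = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                if in_model:
                    raise PDBFormatError(
                        f"line {lineno}: MODEL record inside an open model"
                    )
                in_model = True
                try:
                    model_index = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_index = len(frames) + 1
            elif rec == "ENDMDL":
                if not in_model:
                    raise PDBFormatError(f"line {lineno}: ENDMDL without MODEL")
                flush(model_index)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = _normalise_name(line[12:16])
                    resname = line[17:20].strip()
                    chain = line[21].strip() or chain_default
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise PDBFormatError(
                        f"line {lineno}: malformed {rec.strip()} record: {exc}"
                    ) from None
                if rec == "HETATM" and skip_solvent and resname in _SOLVENT_RESNAMES:
                    continue
                atoms.append(Atom(name, resnum, resname, chain, (x, y, z)))

    if in_model:
        raise PDBFormatError(f"model {model_index}: missing ENDMDL at end of file")
    if atoms:
        if saw_model_record and frames:
            raise PDBFormatError("ATOM records outside MODEL blocks in multi-model file")
        flush(model_index if saw_model_record else 1)
    if not frames:
        raise PDBFormatError(f"no ATOM records found in {path}")

    ref_keys = [(f_.chain_ids[i], int(f_.residue_indices[i]), f_.names[i])
                for f_ in frames[:1] for i in range(len(f_))]
    for f in frames[1:]:
        keys = [(f.chain_ids[i], int(f.residue_indices[i]), f.names[i])
                for i in range(len(f))]
        if keys != ref_keys:
            raise PDBFormatError(
                f"model {f.model_index}: atom list differs from model "
                f"{frames[0].model_index} ({len(f)} vs {len(frames[0])} atoms)"
            )
    return frames


def _format_atom_name(name: str) -> str:
    # element-aligned 4-char field: 1/2-letter organic names start in col 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_multimodel_pdb(path, frames: Frame | Iterable[Frame]) -> None:
    """Write one or more Frames as a (multi-)model PDB file."""
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    multi = len(frames) > 1
    lines: list[str] = []
    for f in frames:
        if multi:
            lines.append(f"MODEL     {f.model_index:4d}")
        serial = 0
        for a in f:
            serial += 1
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(a.name)} {a.residue_name:<3s} "
                f"{a.chain_id:1s}{a.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.name[0]:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
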