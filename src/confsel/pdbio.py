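"""Multi-model PDB input/output.

One ensemble = one PDB file, one frame per MODEL/ENDMDL block (a file
without MODEL records is a one-frame ensemble).  Reading is fixed-column
per the PDB dialect (ATOM/HETATM name cols 13-16, resName 18-20, resSeq
23-26, x/y/z 31-54) so that a malformed record can be reported with its
line number.  Writing uses %8.3f coordinates, occupancy 1.00, B 0.00.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from .errors import PDBFormatError
from .frames import ConformationFrame

__all__ = ["read_multimodel_pdb", "write_multimodel_pdb"]


def _parse_atom_line(line: str, lineno: int, names, resnames, resids, xyz) -> None:
    if len(line.rstrip("\n")) < 54:
        raise PDBFormatError("ATOM/HETATM record shorter than coordinate columns", lineno)
    try:
        names.append(line[12:16].strip())
        resnames.append(line[17:20].strip())
        resids.append(int(line[22:26]))
        xyz.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    except ValueError as exc:
        raise PDBFormatError(f"unparseable ATOM/HETATM fields ({exc})", lineno) from None


def read_multimodel_pdb(path: str | os.PathLike) -> list[ConformationFrame]:
    """Read a (multi-)model PDB file into a list of frames."""
    frames: list[ConformationFrame] = []
    names: list = []
    resnames: list = []
    resids: list = []
    xyz: list = []
    in_model = False
    saw_model = False

    def flush() -> None:
        if names:
            frames.append(ConformationFrame(list(names), list(resnames), list(resids), list(xyz)))
        names.clear(), resnames.clear(), resids.clear(), xyz.clear()

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model = True
                flush()
                in_model = True
            elif record == "ENDMDL":
                flush()
                in_model = False
            elif record in ("ATOM", "HETATM"):
                _parse_atom_line(line, lineno, names, resnames, resids, xyz)
    flush()
    if saw_model and in_model:
        raise PDBFormatError("file ends inside an unterminated MODEL block")
    return frames


def write_multimodel_pdb(frames: Sequence[ConformationFrame] | Iterable[ConformationFrame],
                         path: str | os.PathLike) -> None:
    """Write frames as MODEL/ENDMDL blocks (always, even for one frame)."""
    frames = list(frames)
    with open(path, "w") as handle:
        for model_no, frame in enumerate(frames, start=1):
            handle.write(f"MODEL {model_no:>8}\n")
            for serial in range(frame.n_atoms):
                name = str(frame.atom_names[serial])
                # standard alignment: 4-char names start in col 13, shorter in col 14
                name_field = name.ljust(4) if len(name) == 4 else f" {name:<3}"
                x, y, z = frame.coords[serial]
                handle.write(
                    "ATOM  {serial:>5} {name}{alt}{res:<3} {chain}{resid:>4}{icode}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}\n".format(
                        serial=serial + 1,
                        name=name_field,
                        alt=" ",
                        res=str(frame.res_names[serial])[:3],
                        chain="A",
                        resid=int(frame.res_ids[serial]),
                        icode=" ",
                        x=x, y=y, z=z, occ=1.00, b=0.00,
                    )
                )
            handle.write("ENDMDL\n")
        handle.write("END\n")
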