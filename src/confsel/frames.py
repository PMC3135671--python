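"""Lightweight container for one ensemble member's atom records.

A :class:`ConformationFrame` is a flat, array-backed structure: parallel
arrays of atom names, residue names, residue numbers and Cartesian
coordinates (Å).  It deliberately stores nothing else — occupancies,
elements and chains are irrelevant to the analysis and are synthesized on
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError

__all__ = ["ConformationFrame", "AtomDescriptor"]

#: (residue name, residue number, atom name) — resolves one atom per frame.
AtomDescriptor = tuple[str, int, str]


@dataclass
class ConformationFrame:
    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.res_names) == len(self.res_ids) == n and self.coords.shape == (n, 3)):
            raise ValueError("frame arrays must share one length; coords must be (n, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def copy(self) -> "ConformationFrame":
        return ConformationFrame(
            self.atom_names.copy(), self.res_names.copy(),
            self.res_ids.copy(), self.coords.copy(),
        )

    # -- selection ---------------------------------------------------------

    def atom_index(self, descriptor: AtomDescriptor) -> int:
        """Resolve a (res_name, res_id, atom_name) descriptor to one index."""
        res_name, res_id, atom_name = descriptor
        mask = (
            (self.res_names == res_name)
            & (self.res_ids == int(res_id))
            & (self.atom_names == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise SelectionError(
                f"descriptor {descriptor!r} resolved to {idx.size} atoms (need exactly 1)"
            )
        return int(idx[0])

    def atom_coord(self, descriptor: AtomDescriptor) -> np.ndarray:
        return self.coords[self.atom_index(descriptor)]

    def residue_mask(self, res_name: str) -> np.ndarray:
        return np.asarray(self.res_names == res_name)

    # -- rigid motion ------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ConformationFrame":
        """Return a copy with coordinates mapped through x ↦ R·x + t."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        return out
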