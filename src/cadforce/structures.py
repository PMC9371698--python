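"""Atomic structures, trajectories, and atom selections.

``Structure`` is a column-oriented container (one numpy array per atom
attribute) similar in spirit to an ``AtomArray``; ``Trajectory`` pairs a
topology with a stack of coordinate frames.  Selections can be built
programmatically (:class:`Selection`) or from a small query string such as
``"chain A and resid 1-100 and name CA"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES, BONDI_RADII


@dataclass
class Structure:
    """A set of typed atoms with coordinates in Å.

    Attributes
    ----------
    element, atom_name, res_name, chain_id : str arrays, one entry per atom
    res_id : int array
        Residue numbers, 1-based author numbering.
    coords : (n_atoms, 3) float array, Å
    radius : float array, Å
        Van der Waals radii; NaN where the element is unknown.
    """

    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    radius: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.element = np.asarray(self.element, dtype="U4")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.res_name = np.asarray(self.res_name, dtype="U6")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.element)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for arr, name in (
            (self.atom_name, "atom_name"),
            (self.res_name, "res_name"),
            (self.res_id, "res_id"),
            (self.chain_id, "chain_id"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.radius is None:
            self.radius = np.array(
                [BONDI_RADII.get(e.upper(), np.nan) for e in self.element]
            )
        else:
            self.radius = np.asarray(self.radius, dtype=float)
            if len(self.radius) != n:
                raise ValueError("radius length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    def masses(self) -> np.ndarray:
        """Atomic masses in Da; raises if an element is unknown."""
        masses = np.empty(self.n_atoms)
        for i, e in enumerate(self.element):
            try:
                masses[i] = ATOMIC_MASSES[e.upper()]
            except KeyError:
                raise KeyError(
                    f"unknown element {e!r} for atom "
                    f"{self.chain_id[i]}/{self.res_id[i]}/{self.atom_name[i]}"
                ) from None
        return masses

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """(chain, residue, atom name) identifier per atom."""
        return list(
            zip(self.chain_id.tolist(), self.res_id.tolist(), self.atom_name.tolist())
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        indices = np.asarray(indices)
        return Structure(
            element=self.element[indices],
            atom_name=self.atom_name[indices],
            res_name=self.res_name[indices],
            res_id=self.res_id[indices],
            chain_id=self.chain_id[indices],
            coords=self.coords[indices],
            radius=self.radius[indices],
        )

    def translated(self, shift: Sequence[float]) -> "Structure":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))

    def select(self, selection: "Selection | str") -> np.ndarray:
        """Resolve a selection to atom indices (ascending)."""
        if isinstance(selection, str):
            selection = Selection.parse(selection)
        return selection.resolve(self)


def concatenate(structures: Iterable[Structure]) -> Structure:
    parts = list(structures)
    return Structure(
        element=np.concatenate([s.element for s in parts]),
        atom_name=np.concatenate([s.atom_name for s in parts]),
        res_name=np.concatenate([s.res_name for s in parts]),
        res_id=np.concatenate([s.res_id for s in parts]),
        chain_id=np.concatenate([s.chain_id for s in parts]),
        coords=np.concatenate([s.coords for s in parts]),
        radius=np.concatenate([s.radius for s in parts]),
    )


@dataclass
class Selection:
    """Atom filter by chain, residue ranges, and atom names.

    ``residue_ranges`` is a list of inclusive ``(lo, hi)`` pairs; ``None``
    fields match everything.
    """

    chain: str | None = None
    residue_ranges: list[tuple[int, int]] | None = None
    atom_names: tuple[str, ...] | None = None

    @classmethod
    def parse(cls, query: str) -> "Selection":
        """Parse a query like ``"chain A and resid 1-100 and name CA"``."""
        sel = cls()
        for clause in query.split(" and "):
            tokens = clause.split()
            if not tokens:
                continue
            kind, args = tokens[0].lower(), tokens[1:]
            if kind == "chain":
                if len(args) != 1:
                    raise ValueError(f"bad chain clause: {clause!r}")
                sel.chain = args[0]
            elif kind == "resid":
                ranges = []
                for a in args:
                    if "-" in a[1:]:
                        lo, hi = a.split("-", 1)
                        ranges.append((int(lo), int(hi)))
                    else:
                        ranges.append((int(a), int(a)))
                sel.residue_ranges = ranges
            elif kind == "name":
                if not args:
                    raise ValueError(f"bad name clause: {clause!r}")
                sel.atom_names = tuple(args)
            else:
                raise ValueError(f"unknown selection keyword {kind!r}")
        return sel

    def resolve(self, structure: Structure) -> np.ndarray:
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chain is not None:
            mask &= structure.chain_id == self.chain
        if self.residue_ranges is not None:
            rmask = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in self.residue_ranges:
                rmask |= (structure.res_id >= lo) & (structure.res_id <= hi)
            mask &= rmask
        if self.atom_names is not None:
            mask &= np.isin(structure.atom_name, self.atom_names)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"selection {self} matches no atoms")
        return idx


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) over a fixed topology."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    timestep: float = 1.0  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]
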