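"""Lightweight heavy-atom structure container shared by the ring-current and
elastic-network analyses.

A :class:`StructureModel` is a flat table of heavy atoms (chain, residue
number, residue name, atom name, element, Cartesian coordinates in Å). It is
deliberately simpler than a full hierarchy parser: all analyses here operate
on selections of atoms identified by ``(chain, resnum, atom_name)`` keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StructureModel"]


@dataclass
class StructureModel:
    """Heavy-atom coordinates with residue/atom naming.

    Attributes
    ----------
    chain, resnum, resname, atom_name, element : arrays of length n_atoms
    coords : (n_atoms, 3) float array, Å
    source : free-text provenance label (file name, generator name, ...)
    """

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=object)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = self.atom_keys()
        if len(set(keys)) != n:
            seen: set = set()
            dup = [k for k in keys if k in seen or seen.add(k)]  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate atom keys, e.g. {dup[:3]}")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def atom_keys(self) -> list[tuple]:
        """Unique per-atom keys ``(chain, resnum, atom_name)``."""
        return list(zip(self.chain, self.resnum, self.atom_name))

    def subset(self, mask: np.ndarray, source: str | None = None) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            chain=self.chain[mask],
            resnum=self.resnum[mask],
            resname=self.resname[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            coords=self.coords[mask],
            source=source or self.source,
        )

    def select_chain(self, chain: str) -> "StructureModel":
        available = sorted(set(self.chain))
        if chain not in available:
            raise ValueError(f"chain {chain!r} not present; available: {available}")
        return self.subset(self.chain == np.asarray(chain, dtype=object))

    def select_atoms(
        self,
        atom_names: list[str] | None = None,
        resnums: list[int] | None = None,
    ) -> "StructureModel":
        """Subset by atom name and/or residue number (either may be None)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            mask &= np.isin(np.asarray(self.atom_name, dtype=str), atom_names)
        if resnums is not None:
            mask &= np.isin(self.resnum, resnums)
        return self.subset(mask)

    def with_coords(self, coords: np.ndarray, source: str | None = None) -> "StructureModel":
        """Copy of the model with replaced coordinates (same atoms/ordering)."""
        out = StructureModel(
            chain=self.chain.copy(),
            resnum=self.resnum.copy(),
            resname=self.resname.copy(),
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            coords=np.asarray(coords, dtype=float),
            source=source or self.source,
        )
        return out

    def match(self, other: "StructureModel") -> tuple[np.ndarray, np.ndarray, list[tuple]]:
        """Atom correspondence by key with *other*.

        Returns (index_self, index_other, unmatched_keys); the index arrays
        select matched atoms in identical order in both structures.
        """
        keys_a = self.atom_keys()
        keys_b = other.atom_keys()
        pos_b = {k: i for i, k in enumerate(keys_b)}
        idx_a, idx_b = [], []
        unmatched = []
        for i, k in enumerate(keys_a):
            j = pos_b.get(k)
            if j is None:
                unmatched.append(k)
            else:
                idx_a.append(i)
                idx_b.append(j)
        unmatched.extend(k for k in keys_b if k not in set(keys_a))
        return np.asarray(idx_a, dtype=int), np.asarray(idx_b, dtype=int), unmatched
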