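"""Atom topology and conformational-ensemble containers.

A :class:`Topology` describes the fixed atom content of a protein model
(atom names, residue assignment, chains, optional domain labels); a
:class:`ConformationalEnsemble` binds an ``F x A x 3`` coordinate array in
Angstrom to a topology, with one frame per snapshot and strictly increasing
frame times in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology", "ConformationalEnsemble"]


@dataclass
class Topology:
    """Per-atom annotation of a structure.

    Parameters
    ----------
    atom_names
        PDB-style atom names, e.g. ``"CA"``.
    elements
        Element symbols, e.g. ``"C"``.
    residue_indices
        1-based residue sequence numbers, nondecreasing within a chain.
    residue_names
        Three-letter residue names.
    chain_ids
        Single-character chain identifiers.
    domain_labels
        Optional per-atom domain tag (e.g. ``"domainA"``); empty string if
        unassigned.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    domain_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype="U4")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U2")
        if self.domain_labels is not None:
            self.domain_labels = np.asarray(self.domain_labels, dtype="U16")
        n = self.n_atoms
        if n < 1:
            raise ValueError("topology must contain at least one atom")
        for arr, name in [
            (self.elements, "elements"),
            (self.residue_indices, "residue_indices"),
            (self.residue_names, "residue_names"),
            (self.chain_ids, "chain_ids"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != atom count {n}")
        if self.domain_labels is not None and len(self.domain_labels) != n:
            raise ValueError("domain_labels length mismatch")
        # residue indices must be nondecreasing within each chain
        for cid in np.unique(self.chain_ids):
            resi = self.residue_indices[self.chain_ids == cid]
            if np.any(np.diff(resi) < 0):
                raise ValueError(f"residue indices decrease within chain {cid!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue indices in order of first appearance."""
        _, first = np.unique(self.residue_indices, return_index=True)
        return self.residue_indices[np.sort(first)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def atoms_of_residue(self, residue_index: int) -> np.ndarray:
        """Atom indices belonging to one residue (1-based residue index)."""
        idx = np.flatnonzero(self.residue_indices == residue_index)
        if idx.size == 0:
            raise KeyError(f"residue {residue_index} not in topology")
        return idx

    def select(
        self,
        residues: np.ndarray | list[int] | None = None,
        atom_names: list[str] | None = None,
        domain: str | None = None,
    ) -> np.ndarray:
        """Atom indices matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            mask &= np.isin(self.residue_indices, np.asarray(residues))
        if atom_names is not None:
            mask &= np.isin(self.atom_names, np.asarray(atom_names))
        if domain is not None:
            if self.domain_labels is None:
                raise ValueError("topology has no domain labels")
            mask &= self.domain_labels == domain
        return np.flatnonzero(mask)

    def ca_indices(self, residues=None) -> np.ndarray:
        """Indices of Cα atoms, optionally restricted to given residues."""
        return self.select(residues=residues, atom_names=["CA"])

    def residue_of_atom(self, atom_index: int) -> int:
        return int(self.residue_indices[atom_index])


@dataclass
class ConformationalEnsemble:
    """Frames of one trajectory (or concatenated trajectories).

    Coordinates are in Angstrom, shaped ``(n_frames, n_atoms, 3)``; frame
    times are in picoseconds and strictly increasing.
    """

    coords: np.ndarray
    times: np.ndarray
    topology: Topology
    state: str | None = None
    trajectory_id: int = 0
    frame_interval: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (F, A, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_interval is None and len(self.times) > 1:
            self.frame_interval = float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset(self, frame_indices: np.ndarray) -> "ConformationalEnsemble":
        frame_indices = np.asarray(frame_indices)
        return ConformationalEnsemble(
            coords=self.coords[frame_indices],
            times=self.times[frame_indices],
            topology=self.topology,
            state=self.state,
            trajectory_id=self.trajectory_id,
            frame_interval=None,
        )

    @staticmethod
    def concatenate(parts: list["ConformationalEnsemble"]) -> "ConformationalEnsemble":
        """Join trajectories end to end, offsetting times to stay increasing."""
        if not parts:
            raise ValueError("nothing to concatenate")
        topo = parts[0].topology
        coords = np.concatenate([p.coords for p in parts], axis=0)
        times = []
        offset = 0.0
        for p in parts:
            times.append(p.times + offset)
            offset = times[-1][-1] + (p.frame_interval or 1.0)
        return ConformationalEnsemble(
            coords=coords,
            times=np.concatenate(times),
            topology=topo,
            state=parts[0].state if len({p.state for p in parts}) == 1 else None,
        )
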