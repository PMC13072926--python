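"""Ensemble I/O, frame extraction and rigid-body superposition.

Multi-model PDB files (one MODEL/ENDMDL block per frame) are the on-disk
trajectory format; reading strips solvent, ions and other non-protein
records.  Superposition is least-squares optimal (Kabsch), proper rotations
only.
"""

from __future__ import annotations

import warnings

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .topology import ConformationalEnsemble, Topology

__all__ = [
    "read_multimodel_pdb",
    "read_single_pdb",
    "write_ensemble",
    "extract_frames",
    "kabsch_superpose",
    "align_ensemble",
]


def _stack_from_ensemble(ens: ConformationalEnsemble) -> struc.AtomArrayStack:
    topo = ens.topology
    stack = struc.AtomArrayStack(ens.n_frames, ens.n_atoms)
    stack.coord = np.asarray(ens.coords, dtype=np.float32)
    stack.atom_name = topo.atom_names
    stack.element = topo.elements
    stack.res_id = topo.residue_indices
    stack.res_name = topo.residue_names
    stack.chain_id = topo.chain_ids
    stack.hetero = np.zeros(ens.n_atoms, dtype=bool)
    return stack


def write_ensemble(ens: ConformationalEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (coordinates ``%8.3f``)."""
    if ens.n_frames == 0:
        raise ValueError("refusing to write an empty ensemble")
    f = pdbio.PDBFile()
    f.set_structure(_stack_from_ensemble(ens))
    f.write(str(path))


_ION_NAMES = {
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD",
    "SOD", "CLA", "POT",
}


def _protein_mask(atoms) -> np.ndarray:
    mask = struc.filter_amino_acids(atoms)
    mask &= ~atoms.hetero
    mask &= ~np.isin(atoms.res_name, ("HOH", "WAT", "TIP3", "SOL"))
    # an ion mis-labelled as ATOM: single-atom residue with an ion name
    mask &= ~(np.isin(atoms.res_name, tuple(_ION_NAMES)))
    return mask


def read_multimodel_pdb(
    path,
    frame_interval: float = 1.0,
    state: str | None = None,
) -> tuple[Topology, ConformationalEnsemble]:
    """Read a multi-model PDB into a topology + ensemble.

    Non-protein records (waters, ions, HETATM solvent) are removed.  Models
    with inconsistent atom counts raise ``ValueError``.  Frame times are
    assigned as ``frame_interval, 2*frame_interval, ...`` (ps) since PDB
    carries no time axis.
    """
    f = pdbio.PDBFile.read(str(path))
    n_models = f.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no MODEL records / coordinates found")
    try:
        stack = f.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise ValueError(f"{path}: inconsistent or malformed models: {exc}") from exc
    mask = _protein_mask(stack)
    if not mask.any():
        raise ValueError(f"{path}: no protein atoms after filtering")
    stack = stack[..., mask]
    topo = Topology(
        atom_names=stack.atom_name,
        elements=stack.element,
        residue_indices=stack.res_id,
        residue_names=stack.res_name,
        chain_ids=stack.chain_id,
    )
    coords = np.asarray(stack.coord, dtype=np.float64)
    times = frame_interval * np.arange(1, coords.shape[0] + 1)
    ens = ConformationalEnsemble(
        coords=coords, times=times, topology=topo, state=state,
        frame_interval=frame_interval,
    )
    return topo, ens


def read_single_pdb(path) -> tuple[Topology, np.ndarray]:
    """Read the first model of a PDB file (e.g. a crystal structure)."""
    topo, ens = read_multimodel_pdb(path)
    return topo, ens.coords[0]


def extract_frames(ens: ConformationalEnsemble, stride: float) -> ConformationalEnsemble:
    """Keep frames at times ``stride, 2*stride, ..., T`` (t=0 excluded).

    ``stride`` (ps) must be a positive multiple of the ensemble's frame
    interval; the resulting frame count is ``floor(T / stride)``.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    interval = ens.frame_interval
    if interval is None:
        raise ValueError("ensemble has no defined frame interval")
    ratio = stride / interval
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"stride {stride} ps is not a multiple of the frame interval {interval} ps"
        )
    t = ens.times
    k = np.rint(t / stride)
    keep = (np.abs(t - k * stride) <= 1e-6 * stride) & (k >= 1)
    return ens.subset(np.flatnonzero(keep))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation (det = +1) and translation over the atom
    ``selection`` are applied to *all* atoms of ``mobile``; the returned
    RMSD is the minimized value over the selection.  A degenerate
    (collinear) selection is flagged with a warning; the result is still
    the least-squares optimum.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = np.asarray(selection)
    if selection.size < 3:
        raise ValueError("selection must contain at least 3 atoms")
    m = mobile[selection]
    r = reference[selection]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    m0 = m - mc
    r0 = r - rc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        warnings.warn("collinear selection: rotation is not uniquely determined")
    h = m0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transformed = (mobile - mc) @ rot.T + rc
    diff = transformed[selection] - r
    rmsd = float(np.sqrt((diff ** 2).sum() / selection.size))
    return transformed, rmsd


def align_ensemble(
    ens: ConformationalEnsemble,
    reference: np.ndarray | int = 0,
    selection: np.ndarray | None = None,
) -> ConformationalEnsemble:
    """Superpose every frame onto a reference over the given selection.

    ``reference`` is either a coordinate array or a frame index.  Rigid
    transforms preserve all intra-frame distances; aligning an already
    aligned ensemble is a no-op up to numerical noise.
    """
    ref = ens.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference)
    out = np.empty_like(ens.coords)
    for i in range(ens.n_frames):
        out[i], _ = kabsch_superpose(ens.coords[i], ref, selection)
    return ConformationalEnsemble(
        coords=out, times=ens.times.copy(), topology=ens.topology,
        state=ens.state, trajectory_id=ens.trajectory_id,
        frame_interval=ens.frame_interval,
    )
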