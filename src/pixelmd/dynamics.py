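"""Distance, RMSD, contact, cross-correlation and collective-mode analyses.

These are the classical trajectory observables used to characterize a
two-state conformational ensemble:

* per-frame RMSD against a reference (overall or per domain),
* residue-pair distance time series (Calpha-Calpha or closest heavy atom)
  with a contact criterion (default < 4.5 A),
* the dynamic cross-correlation matrix
  ``C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)`` of Calpha
  displacement fluctuations about the time-mean position,
* essential-dynamics PCA of the coordinate covariance, with per-residue
  displacement vectors along the dominant mode,
* a 2D density over (RMSD, interdomain distance) reaction coordinates, and
* the displacement of a residue between two superposed crystal structures.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .topology import ConformationalEnsemble, Topology
from .trajio import kabsch_superpose

__all__ = [
    "DistanceSeries",
    "DCCMatrix",
    "PCAResult",
    "rmsd_series",
    "pair_distance_series",
    "contact_fraction",
    "dccm",
    "pca_modes",
    "state_space_projection",
    "crystal_pair_displacement",
]

CONTACT_THRESHOLD = 4.5  # A, closest non-hydrogen contact criterion


@dataclass
class DistanceSeries:
    """A per-frame distance (or RMSD) series in Angstrom."""

    times: np.ndarray
    values: np.ndarray
    metric: str  # "CA-CA", "closest-heavy" or "rmsd"
    residue_pair: tuple[int, int] | None = None
    threshold: float = CONTACT_THRESHOLD

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def rmsd_series(
    ens: ConformationalEnsemble,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> DistanceSeries:
    """Per-frame least-squares RMSD over ``selection`` vs a reference.

    With ``superpose=True`` each frame is optimally superposed first, so
    the series measures internal deformation, not rigid drift.
    """
    if selection is None:
        selection = np.arange(ens.n_atoms)
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    vals = np.empty(ens.n_frames)
    for i in range(ens.n_frames):
        if superpose:
            _, vals[i] = kabsch_superpose(ens.coords[i], reference, selection)
        else:
            d = ens.coords[i, selection] - reference[selection]
            vals[i] = np.sqrt((d ** 2).sum() / selection.size)
    return DistanceSeries(times=ens.times, values=vals, metric="rmsd")


def pair_distance_series(
    ens: ConformationalEnsemble,
    res_a: int,
    res_b: int,
    metric: str = "CA-CA",
    threshold: float = CONTACT_THRESHOLD,
) -> DistanceSeries:
    """Residue-pair distance per frame.

    ``metric="CA-CA"`` uses the Calpha pair; ``metric="closest-heavy"``
    takes the minimum over all non-hydrogen atom pairs of the two residues
    (requires a topology with more than Calpha atoms).
    """
    topo = ens.topology
    if metric == "CA-CA":
        ia = topo.select(residues=[res_a], atom_names=["CA"])
        ib = topo.select(residues=[res_b], atom_names=["CA"])
        if ia.size == 0 or ib.size == 0:
            raise KeyError(f"residue {res_a} or {res_b} lacks a CA atom")
        d = np.linalg.norm(ens.coords[:, ia[0]] - ens.coords[:, ib[0]], axis=1)
    elif metric == "closest-heavy":
        ia = topo.atoms_of_residue(res_a)
        ib = topo.atoms_of_residue(res_b)
        ia = ia[topo.elements[ia] != "H"]
        ib = ib[topo.elements[ib] != "H"]
        if len(ia) <= 1 and len(ib) <= 1 and topo.n_atoms == topo.n_residues:
            raise ValueError("closest-heavy metric needs more than a CA-only topology")
        diff = ens.coords[:, ia, None, :] - ens.coords[:, None, ib, :]
        d = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceSeries(
        times=ens.times, values=d, metric=metric,
        residue_pair=(res_a, res_b), threshold=threshold,
    )


def contact_fraction(series: DistanceSeries) -> float:
    """Fraction of frames with distance below the contact threshold."""
    if len(series) == 0:
        raise ValueError("empty series")
    return float(np.mean(series.values < series.threshold))


@dataclass
class DCCMatrix:
    """Residue-residue cross-correlation of displacement fluctuations.

    Entries lie in [-1, 1] with unit diagonal; residues with zero variance
    (immobile) have undefined (NaN) rows/columns rather than zeros.
    """

    matrix: np.ndarray
    residue_ids: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.residue_ids):
            raise ValueError("matrix/residue id shape mismatch")

    def value(self, res_i: int, res_j: int) -> float:
        i = int(np.flatnonzero(self.residue_ids == res_i)[0])
        j = int(np.flatnonzero(self.residue_ids == res_j)[0])
        return float(self.matrix[i, j])


def dccm(ens: ConformationalEnsemble, selection: np.ndarray | None = None) -> DCCMatrix:
    """Dynamic cross-correlation matrix over Calpha atoms.

    ``C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)`` with ``dr`` the
    3D displacement from the time-mean position.  The ensemble should be
    rigid-body aligned first, otherwise overall rotation/translation leaks
    into the correlations.
    """
    if ens.n_frames < 2:
        raise ValueError("need at least 2 frames")
    topo = ens.topology
    if selection is None:
        selection = topo.ca_indices()
    selection = np.asarray(selection)
    x = ens.coords[:, selection, :]  # (F, R, 3)
    dx = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fik,fjk->ij", dx, dx) / ens.n_frames  # <dr_i . dr_j>
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{zero.sum()} immobile residues: DCCM entries undefined (NaN)")
        var[zero] = np.nan
    denom = np.sqrt(np.outer(var, var))
    mat = cov / denom
    np.fill_diagonal(mat, np.where(zero, np.nan, 1.0))
    res_ids = topo.residue_indices[selection]
    return DCCMatrix(matrix=mat, residue_ids=res_ids)


@dataclass
class PCAResult:
    """Essential-dynamics eigendecomposition of the coordinate covariance."""

    eigenvalues: np.ndarray        # nonincreasing, A^2
    eigenvectors: np.ndarray       # (3R, n_modes), orthonormal columns
    projections: np.ndarray        # (F, n_modes)
    residue_ids: np.ndarray
    pc1_vectors: np.ndarray        # (R, 3), eigvec components * sqrt(lambda1)
    pc1_amplitudes: np.ndarray     # (R,)

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pca_modes(
    ens: ConformationalEnsemble,
    selection: np.ndarray | None = None,
    n_modes: int | None = None,
) -> PCAResult:
    """PCA of the Calpha coordinate covariance of an aligned ensemble.

    PC1 per-residue displacement vectors are the leading eigenvector's
    3-vector components scaled by sqrt(lambda_1); amplitudes are their
    norms (the arrow-length encoding of a collective-motion plot).
    """
    if ens.n_frames < 2:
        raise ValueError("need at least 2 frames")
    topo = ens.topology
    if selection is None:
        selection = topo.ca_indices()
    selection = np.asarray(selection)
    r = selection.size
    if ens.n_frames < 3 * r:
        warnings.warn(
            f"{ens.n_frames} frames for {3 * r} coordinates: covariance is rank-deficient"
        )
    x = ens.coords[:, selection, :].reshape(ens.n_frames, 3 * r)
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc / (ens.n_frames - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    if n_modes is not None:
        w, v = w[:n_modes], v[:, :n_modes]
    proj = xc @ v
    pc1 = v[:, 0].reshape(r, 3) * np.sqrt(w[0])
    return PCAResult(
        eigenvalues=w,
        eigenvectors=v,
        projections=proj,
        residue_ids=topo.residue_indices[selection],
        pc1_vectors=pc1,
        pc1_amplitudes=np.linalg.norm(pc1, axis=1),
    )


def state_space_projection(
    rmsd: DistanceSeries | np.ndarray,
    distance: DistanceSeries | np.ndarray,
    bins: int = 50,
    cluster: bool = False,
    seed: int = 0,
):
    """2D density over (RMSD, interdomain distance) reaction coordinates.

    Returns ``(density, x_edges, y_edges)`` with the density summing to 1,
    or additionally a 2-means cluster label array when ``cluster=True``.
    """
    x = np.asarray(rmsd.values if isinstance(rmsd, DistanceSeries) else rmsd)
    y = np.asarray(distance.values if isinstance(distance, DistanceSeries) else distance)
    if len(x) != len(y):
        raise ValueError("series length mismatch")
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    density = hist / hist.sum()
    if not cluster:
        return density, xe, ye
    from sklearn.cluster import KMeans

    pts = np.column_stack([x, y])
    labels = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(pts)
    return density, xe, ye, labels


def crystal_pair_displacement(
    coords_a: np.ndarray,
    topo_a: Topology,
    coords_b: np.ndarray,
    topo_b: Topology,
    align_residues: np.ndarray | list[int],
    residue: int,
) -> float:
    """Calpha displacement (A) of one residue between two structures.

    Structure B is superposed onto A over the Calpha atoms of
    ``align_residues`` (shared residues only); the reported value is the
    post-superposition Calpha-Calpha distance of ``residue``.
    """
    sel_a = topo_a.ca_indices(residues=align_residues)
    sel_b = topo_b.ca_indices(residues=align_residues)
    shared = np.intersect1d(
        topo_a.residue_indices[sel_a], topo_b.residue_indices[sel_b]
    )
    if shared.size < 3:
        raise ValueError("fewer than 3 shared alignment residues")
    sel_a = topo_a.ca_indices(residues=shared)
    sel_b = topo_b.ca_indices(residues=shared)
    # superpose B onto A using the paired selections
    b_fit, _ = _superpose_paired(coords_b, sel_b, coords_a, sel_a)
    try:
        ia = topo_a.ca_indices(residues=[residue])[0]
        ib = topo_b.ca_indices(residues=[residue])[0]
    except IndexError:
        raise KeyError(f"residue {residue} missing from one structure") from None
    return float(np.linalg.norm(b_fit[ib] - coords_a[ia]))


def _superpose_paired(mobile, mobile_sel, reference, reference_sel):
    """Kabsch when the selections index different atom arrays."""
    m = mobile[mobile_sel]
    r = reference[reference_sel]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    out = (mobile - mc) @ rot.T + rc
    diff = out[mobile_sel] - r
    return out, float(np.sqrt((diff ** 2).sum() / len(mobile_sel)))
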