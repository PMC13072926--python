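"""RGB pixel-map representation of conformations.

Each frame becomes a square image with one pixel per atom (row-major in
topology atom order, padded with black): channel values are the min-max
normalized x, y, z coordinates mapped to 0-255 (x->R, y->G, z->B), with
normalization bounds fitted globally over every frame of the full
(both-state) dataset so that inter-state geometric differences survive
encoding.  The pixel <-> atom mapping is a bijection, which is what lets a
per-pixel importance score be read back as a per-atom (and per-residue)
score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .topology import ConformationalEnsemble, Topology

__all__ = [
    "NormalizationBounds",
    "PixelMap",
    "PixelMapDataset",
    "fit_bounds",
    "encode_frame",
    "encode_ensemble",
    "decode_pixel",
    "decode_image",
]


@dataclass(frozen=True)
class NormalizationBounds:
    """Global per-axis coordinate bounds (A) used for min-max scaling."""

    mins: tuple[float, float, float]
    maxs: tuple[float, float, float]

    def __post_init__(self):
        for lo, hi in zip(self.mins, self.maxs):
            if not hi > lo:
                raise ValueError(f"degenerate bounds: min {lo} >= max {hi}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.mins), np.asarray(self.maxs)


def fit_bounds(ensembles: list[ConformationalEnsemble]) -> NormalizationBounds:
    """Per-axis min/max over all atoms and frames of all input ensembles."""
    if not ensembles:
        raise ValueError("no ensembles given")
    mins = np.full(3, np.inf)
    maxs = np.full(3, -np.inf)
    for ens in ensembles:
        mins = np.minimum(mins, ens.coords.min(axis=(0, 1)))
        maxs = np.maximum(maxs, ens.coords.max(axis=(0, 1)))
    return NormalizationBounds(tuple(mins.tolist()), tuple(maxs.tolist()))


def _side(n_atoms: int) -> int:
    return int(math.ceil(math.sqrt(n_atoms)))


@dataclass
class PixelMap:
    """One frame as an H x W x 3 uint8 image plus the pixel<->atom map."""

    image: np.ndarray  # (H, W, 3) uint8
    n_atoms: int
    clipped: int = 0  # atoms with out-of-bounds coordinates, clipped

    @property
    def side(self) -> int:
        return self.image.shape[0]

    @property
    def padding_mask(self) -> np.ndarray:
        """Boolean (H, W); True where the pixel is padding (no atom)."""
        mask = np.ones(self.side * self.side, dtype=bool)
        mask[: self.n_atoms] = False
        return mask.reshape(self.side, self.side)

    def pixel_to_atom(self, pixel_index: int) -> int:
        if not 0 <= pixel_index < self.n_atoms:
            raise IndexError(f"pixel {pixel_index} is padding or out of range")
        return pixel_index


def _quantize(coords: np.ndarray, bounds: NormalizationBounds) -> tuple[np.ndarray, int]:
    mins, maxs = bounds.as_arrays()
    scaled = 255.0 * (coords - mins) / (maxs - mins)
    clipped = int(np.count_nonzero((scaled < 0).any(axis=-1) | (scaled > 255).any(axis=-1)))
    scaled = np.clip(scaled, 0.0, 255.0)
    return np.floor(scaled + 0.5).astype(np.uint8), clipped  # round half up


def encode_frame(
    coords: np.ndarray, bounds: NormalizationBounds, topology: Topology
) -> PixelMap:
    """Encode one frame; atom k (topology order) occupies row-major pixel k."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coordinates do not match topology atom count")
    q, clipped = _quantize(coords, bounds)
    side = _side(topology.n_atoms)
    img = np.zeros((side * side, 3), dtype=np.uint8)
    img[: topology.n_atoms] = q
    return PixelMap(image=img.reshape(side, side, 3), n_atoms=topology.n_atoms, clipped=clipped)


def decode_pixel(pixel_index: int, topology: Topology) -> tuple[int, int]:
    """Inverse of the row-major layout: pixel -> (atom index, residue index).

    Raises ``IndexError`` for padding pixels.
    """
    if not 0 <= pixel_index < topology.n_atoms:
        raise IndexError(f"pixel {pixel_index} is padding or out of range")
    return pixel_index, topology.residue_of_atom(pixel_index)


def decode_image(pm: PixelMap, bounds: NormalizationBounds) -> np.ndarray:
    """Approximate atom coordinates back from an image.

    Error is at most half a quantization step, (max-min)/510 A per axis.
    """
    mins, maxs = bounds.as_arrays()
    flat = pm.image.reshape(-1, 3)[: pm.n_atoms].astype(np.float64)
    return mins + flat / 255.0 * (maxs - mins)


@dataclass
class PixelMapDataset:
    """A labelled image stack: the classifier's input.

    ``images`` is (N, H, W, 3) uint8; ``labels`` holds the state label per
    frame, ``trajectory_ids`` the source trajectory, ``times`` the frame
    times (ps).  ``topology`` gives the shared pixel->atom mapping.
    """

    images: np.ndarray
    labels: np.ndarray
    trajectory_ids: np.ndarray
    times: np.ndarray
    topology: Topology
    bounds: NormalizationBounds
    clipped: int = 0

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def mean_image(self) -> np.ndarray:
        return self.images.mean(axis=0)

    def save(self, path) -> None:
        """Serialize to a .npz container with a JSON sidecar for the
        pixel->atom mapping and bounds."""
        base = str(path).removesuffix(".npz")
        np.savez_compressed(
            base + ".npz",
            images=self.images,
            labels=self.labels,
            trajectory_ids=self.trajectory_ids,
            times=self.times,
            clipped=np.array([self.clipped]),
        )
        side = {
            "bounds": {"mins": list(self.bounds.mins), "maxs": list(self.bounds.maxs)},
            "atom_names": self.topology.atom_names.tolist(),
            "elements": self.topology.elements.tolist(),
            "residue_indices": self.topology.residue_indices.tolist(),
            "residue_names": self.topology.residue_names.tolist(),
            "chain_ids": self.topology.chain_ids.tolist(),
            "domain_labels": (
                self.topology.domain_labels.tolist()
                if self.topology.domain_labels is not None else None
            ),
        }
        with open(base + ".json", "w") as fh:
            json.dump(side, fh)

    @staticmethod
    def load(path) -> "PixelMapDataset":
        base = str(path).removesuffix(".npz")
        data = np.load(base + ".npz")
        with open(base + ".json") as fh:
            side = json.load(fh)
        topo = Topology(
            atom_names=np.array(side["atom_names"]),
            elements=np.array(side["elements"]),
            residue_indices=np.array(side["residue_indices"]),
            residue_names=np.array(side["residue_names"]),
            chain_ids=np.array(side["chain_ids"]),
            domain_labels=(
                np.array(side["domain_labels"]) if side["domain_labels"] else None
            ),
        )
        bounds = NormalizationBounds(
            tuple(side["bounds"]["mins"]), tuple(side["bounds"]["maxs"])
        )
        return PixelMapDataset(
            images=data["images"],
            labels=data["labels"],
            trajectory_ids=data["trajectory_ids"],
            times=data["times"],
            topology=topo,
            bounds=bounds,
            clipped=int(data["clipped"][0]),
        )


def encode_ensemble(
    ensembles: list[ConformationalEnsemble],
    bounds: NormalizationBounds | None = None,
) -> PixelMapDataset:
    """Encode a list of (aligned) ensembles into one labelled dataset.

    Bounds default to a global fit over all inputs; trajectory ids are
    assigned per input ensemble in order, so chronological fold assignment
    can recover the source trajectory of each frame.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    topo = ensembles[0].topology
    if bounds is None:
        bounds = fit_bounds(ensembles)
    mins, maxs = bounds.as_arrays()
    side = _side(topo.n_atoms)
    total = sum(e.n_frames for e in ensembles)
    images = np.zeros((total, side, side, 3), dtype=np.uint8)
    labels, traj_ids, times = [], [], []
    clipped = 0
    pos = 0
    for tid, ens in enumerate(ensembles):
        q, c = _quantize(ens.coords, bounds)
        clipped += c
        flat = np.zeros((ens.n_frames, side * side, 3), dtype=np.uint8)
        flat[:, : topo.n_atoms] = q
        images[pos : pos + ens.n_frames] = flat.reshape(ens.n_frames, side, side, 3)
        pos += ens.n_frames
        labels.append(np.full(ens.n_frames, ens.state or "unknown", dtype="U32"))
        traj_ids.append(np.full(ens.n_frames, tid))
        times.append(ens.times)
    return PixelMapDataset(
        images=images,
        labels=np.concatenate(labels),
        trajectory_ids=np.concatenate(traj_ids),
        times=np.concatenate(times),
        topology=topo,
        bounds=bounds,
        clipped=clipped,
    )
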