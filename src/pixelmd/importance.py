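"""Local surrogate (LIME-style) residue-importance interpretation.

For each explained conformation, a set of perturbed pixel maps is generated
by masking random subsets of the non-padding pixels to the dataset-mean
pixel value; the classifier is queried on the perturbations; a weighted
linear surrogate is fitted to the predicted probability of the explained
class, with proximity weights exp(-d^2 / sigma^2) where d is the Euclidean
distance from the unperturbed sample in the binary presence space.  The
surrogate's coefficients are binarized (top-m magnitudes -> 1, rest -> 0),
averaged over each residue's atoms and over all explained conformations,
and the top-K residues are reported as the discriminating set.

Masking to the dataset mean (not to black) is deliberate: black is the
padding value, so black masking would alias perturbation with padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .encoding import PixelMapDataset
from .topology import Topology

__all__ = [
    "SurrogateExplanation",
    "ResidueImportanceTable",
    "perturb_samples",
    "fit_local_surrogate",
    "binarize_importance",
    "aggregate_residue_scores",
    "top_k_residues",
    "explain_dataset",
]

DEFAULT_N_PERTURB = 1000
DEFAULT_TOP_FRACTION = 0.10


def kernel_width(n_pixels: int) -> float:
    """Default proximity kernel width: 0.75 * sqrt(#non-padding pixels)."""
    return 0.75 * np.sqrt(n_pixels)


@dataclass
class SurrogateExplanation:
    """One conformation's explanation."""

    conformation_id: int
    pixel_importance: np.ndarray  # binary, len = n non-padding pixels
    coefficients: np.ndarray
    n_perturbations: int
    kernel_sigma: float

    def __post_init__(self):
        vals = set(np.unique(self.pixel_importance).tolist())
        if not vals <= {0, 1}:
            raise ValueError("pixel importance must be binary")


def perturb_samples(
    image: np.ndarray,
    n_atoms: int,
    n: int,
    seed: int,
    mean_image: np.ndarray,
    sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``n`` masked variants of one pixel map plus proximity weights.

    Returns ``(perturbed_images, presence, weights)`` where ``presence`` is
    the (n, n_atoms) binary matrix of kept (1) vs masked (0) pixels, and
    ``weights[k] = exp(-d_k^2 / sigma^2)`` with ``d_k`` the Euclidean
    distance of row k's presence vector from the all-ones original.
    """
    if n < 50:
        warnings.warn(f"only {n} perturbations; the surrogate may be underdetermined")
    side = image.shape[0]
    if sigma is None:
        sigma = kernel_width(n_atoms)
    rng = np.random.default_rng(seed)
    presence = (rng.random((n, n_atoms)) < 0.5).astype(np.int8)
    presence[0] = 1  # keep one unperturbed anchor
    flat = image.reshape(side * side, 3).astype(np.float32)
    mean_flat = np.asarray(mean_image, dtype=np.float32).reshape(side * side, 3)
    out = np.repeat(flat[None], n, axis=0)
    mask = presence == 0
    mean_rep = np.broadcast_to(mean_flat[:n_atoms], (n, n_atoms, 3))
    out[:, :n_atoms][mask] = mean_rep[mask]
    d2 = (1 - presence).sum(axis=1).astype(np.float64)  # squared Euclidean dist
    weights = np.exp(-d2 / sigma ** 2)
    imgs = np.clip(np.rint(out), 0, 255).astype(np.uint8).reshape(n, side, side, 3)
    return imgs, presence, weights


def fit_local_surrogate(
    presence: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Weighted least-squares fit of the classifier output on presence bits.

    The design is the binary presence matrix plus an intercept; the returned
    vector holds the per-pixel slopes (intercept dropped).  A rank-deficient
    design falls back to an increased ridge penalty with a warning.
    """
    presence = np.asarray(presence, dtype=np.float64)
    if len({tuple(row) for row in presence.astype(int)}) < 2:
        raise ValueError("need at least 2 distinct perturbation patterns")
    n, p = presence.shape
    x = np.hstack([np.ones((n, 1)), presence])
    w = np.asarray(weights, dtype=np.float64)
    xtw = x.T * w
    a = xtw @ x
    b = xtw @ np.asarray(target, dtype=np.float64)
    a_reg = a + ridge * np.eye(p + 1)
    try:
        coef = np.linalg.solve(a_reg, b)
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        penalty = 1e-4 * np.trace(a) / (p + 1)
        warnings.warn(f"rank-deficient surrogate design; ridge penalty {penalty:.3g}")
        coef = np.linalg.solve(a + penalty * np.eye(p + 1), b)
    return coef[1:]


def binarize_importance(
    coefficients: np.ndarray, top_fraction: float = DEFAULT_TOP_FRACTION,
    m: int | None = None,
) -> np.ndarray:
    """Mark the top-m pixels by |coefficient| as 1, the rest 0.

    ``m`` defaults to ``top_fraction`` of the pixel count (at least 1).
    Ties break toward the lower pixel index.
    """
    coefficients = np.asarray(coefficients)
    p = len(coefficients)
    if m is None:
        m = max(1, int(round(top_fraction * p)))
    m = min(m, p)
    # stable sort on (-|c|, index): lexsort with index as implicit tiebreak
    order = np.argsort(-np.abs(coefficients), kind="stable")
    out = np.zeros(p, dtype=np.int8)
    out[order[:m]] = 1
    return out


@dataclass
class ResidueImportanceTable:
    """Per-residue mean binary importance in [0, 1]."""

    residue_ids: np.ndarray
    scores: np.ndarray
    n_conformations: int
    residue_names: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        order = np.lexsort((self.residue_ids, -self.scores))
        df = pd.DataFrame(
            {
                "residue": self.residue_ids,
                "name": (self.residue_names if self.residue_names is not None
                         else [""] * len(self.residue_ids)),
                "score": self.scores,
            }
        )
        df["rank"] = np.empty(len(df), dtype=int)
        df.loc[order, "rank"] = np.arange(1, len(df) + 1)
        return df

    def score_of(self, residue: int) -> float:
        i = np.flatnonzero(self.residue_ids == residue)
        if i.size == 0:
            raise KeyError(f"residue {residue} not in table")
        return float(self.scores[i[0]])


def aggregate_residue_scores(
    explanations: list[SurrogateExplanation], topology: Topology
) -> ResidueImportanceTable:
    """score(residue) = mean over (its atoms x explained conformations)."""
    if not explanations:
        raise ValueError("no explanations to aggregate")
    a = topology.n_atoms
    stack = []
    for e in explanations:
        if len(e.pixel_importance) != a:
            raise ValueError("explanation pixel count does not match topology")
        stack.append(e.pixel_importance)
    per_atom = np.mean(stack, axis=0)  # mean over conformations, per atom
    res_ids = topology.residue_ids
    scores = np.array(
        [per_atom[topology.atoms_of_residue(r)].mean() for r in res_ids]
    )
    names = np.array(
        [topology.residue_names[topology.atoms_of_residue(r)[0]] for r in res_ids]
    )
    return ResidueImportanceTable(
        residue_ids=res_ids, scores=scores,
        n_conformations=len(explanations), residue_names=names,
    )


def top_k_residues(table: ResidueImportanceTable, k: int = 50) -> list[int]:
    """The k highest-scoring residues, ties broken by lower residue index."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(table.residue_ids):
        raise ValueError(f"k={k} exceeds residue count {len(table.residue_ids)}")
    order = np.lexsort((table.residue_ids, -table.scores))
    return table.residue_ids[order[:k]].tolist()


def explain_dataset(
    classifier,
    dataset: PixelMapDataset,
    n_per_state: int = 100,
    n_perturbations: int = DEFAULT_N_PERTURB,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    seed: int = 0,
) -> tuple[ResidueImportanceTable, list[SurrogateExplanation]]:
    """Explain a stratified sample of conformations and aggregate scores.

    ``classifier`` is a :class:`~pixelmd.classifier.TrainedClassifier`; the
    explained class of each conformation is its own true state, so
    coefficients measure evidence for the correct label.
    """
    rng = np.random.default_rng(seed)
    mean_image = dataset.mean_image()
    n_atoms = dataset.n_atoms
    sigma = kernel_width(n_atoms)
    chosen: list[int] = []
    for state in dataset.classes:
        idx = np.flatnonzero(dataset.labels == state)
        take = min(n_per_state, len(idx))
        chosen += rng.choice(idx, size=take, replace=False).tolist()
    class_index = {c: i for i, c in enumerate(classifier.classes)}
    explanations = []
    for j, conf in enumerate(chosen):
        imgs, presence, weights = perturb_samples(
            dataset.images[conf], n_atoms, n_perturbations,
            seed=int(rng.integers(2 ** 31)), mean_image=mean_image, sigma=sigma,
        )
        probs = classifier.predict_proba(imgs)
        target = probs[:, class_index[dataset.labels[conf]]]
        coef = fit_local_surrogate(presence, target, weights)
        binary = binarize_importance(coef, top_fraction=top_fraction)
        explanations.append(
            SurrogateExplanation(
                conformation_id=int(conf), pixel_importance=binary,
                coefficients=coef, n_perturbations=n_perturbations,
                kernel_sigma=sigma,
            )
        )
    table = aggregate_residue_scores(explanations, dataset.topology)
    return table, explanations
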