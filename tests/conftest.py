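"""Shared fixtures.

Expensive artifacts (trained classifiers, planted-residue recovery runs,
label-permutation nulls) are session-scoped so unit and acceptance tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import pixelmd as px


def make_separated_dataset(seed: int, n_frames: int = 150, n_traj: int = 1):
    """Small, strongly separated two-state dataset (Calpha-only, 100 residues,
    10 planted residues with a 3 A shift over 0.5 A noise -> 10x10 maps)."""
    spec = px.SyntheticSpec(
        n_residues=100,
        n_trajectories_per_state=n_traj,
        n_frames=n_frames,
        mean_shift=3.0,
        fluctuation_sigma=0.5,
        seed=seed,
    )
    data = px.simulate_dataset(spec)
    ensembles = [e for s in spec.state_labels for e in data[s]]
    ref = ensembles[0].coords[0]
    sel = ensembles[0].topology.ca_indices()
    aligned = [px.align_ensemble(e, ref, sel) for e in ensembles]
    dataset = px.encode_ensemble(aligned)
    return spec, dataset


@pytest.fixture(scope="session")
def separated_dataset():
    return make_separated_dataset(seed=0)


@pytest.fixture(scope="session")
def trained_separated(separated_dataset):
    """One classifier trained on the full separated dataset."""
    _, dataset = separated_dataset
    cfg = px.ClassifierConfig(epochs=15, seed=0)
    clf = px.train_classifier(dataset.images, dataset.labels, cfg)
    return dataset, clf


@pytest.fixture(scope="session")
def planted_recovery():
    """Planted-residue recovery across 3 seeds.

    For each seed: simulate, train, explain a stratified sample, and count
    how many of the 10 planted residues rank in the top 10 of the
    importance table.
    """
    results = []
    for seed in (0, 1, 2):
        spec, dataset = make_separated_dataset(seed=seed)
        cfg = px.ClassifierConfig(epochs=15, seed=seed)
        clf = px.train_classifier(dataset.images, dataset.labels, cfg)
        table, _ = px.explain_dataset(
            clf, dataset, n_per_state=10, n_perturbations=1000, seed=seed
        )
        top10 = set(px.top_k_residues(table, 10))
        planted = set(spec.discriminative_residues)
        results.append({
            "seed": seed,
            "planted": planted,
            "top10": top10,
            "hits": len(top10 & planted),
            "table": table,
        })
    return results


@pytest.fixture(scope="session")
def null_cv():
    """Grouped five-fold CV on data where the two states have identical
    distributions (mean shift 0), over 3 seeds."""
    means = []
    for seed in (0, 1, 2):
        spec = px.SyntheticSpec(
            n_residues=64, n_trajectories_per_state=1, n_frames=200,
            mean_shift=0.0, fluctuation_sigma=0.5, seed=seed,
        )
        data = px.simulate_dataset(spec)
        ensembles = [e for s in spec.state_labels for e in data[s]]
        ref = ensembles[0].coords[0]
        sel = ensembles[0].topology.ca_indices()
        aligned = [px.align_ensemble(e, ref, sel) for e in ensembles]
        dataset = px.encode_ensemble(aligned)
        counts = [e.n_frames for e in ensembles]
        folds = px.make_fold_assignment(counts)
        cv = px.cross_validate(
            dataset, folds, px.ClassifierConfig(epochs=5, seed=seed),
            keep_models=False,
        )
        means.append(cv.mean_accuracy)
    return means


@pytest.fixture(scope="session")
def block_dccm():
    """DCCM of a 10,000-frame ensemble with a planted rho=0.8 block."""
    spec = px.SyntheticSpec(
        n_residues=30, n_trajectories_per_state=1, n_frames=10_000,
        mean_shift=0.0, fluctuation_sigma=0.5,
        correlation_blocks=(px.CorrelationBlock((1, 5), (20, 24), 0.8),),
        seed=7,
    )
    ens = px.simulate_state_ensemble(spec, "inactive")
    return spec, px.dccm(ens)
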