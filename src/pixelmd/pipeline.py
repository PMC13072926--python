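"""End-to-end pipeline: simulate -> encode -> cross-validate -> explain ->
dynamics -> report.

Every run is driven by one YAML config and one master seed, writes into a
run directory, and is reproducible: stage outputs are content-addressed by
a hash of the configuration slice they depend on, so re-running with the
same config + seed skips completed stages and reproduces identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (ClassifierConfig, CVResult, cross_validate,
                         make_fold_assignment)
from .dynamics import (CONTACT_THRESHOLD, contact_fraction, dccm, pca_modes,
                       pair_distance_series, rmsd_series, state_space_projection)
from .encoding import PixelMapDataset, encode_ensemble
from .importance import explain_dataset, top_k_residues
from .synthetic import SyntheticSpec, default_study_spec, simulate_dataset
from .trajio import align_ensemble, write_ensemble

__all__ = ["LimeConfig", "AnalysisConfig", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("pixelmd")

STAGES = ("simulate", "encode", "train", "explain", "dynamics", "report")


@dataclass(frozen=True)
class LimeConfig:
    n_perturbations: int = 1000
    n_per_state: int = 100
    top_fraction: float = 0.10
    top_k: int = 50


@dataclass(frozen=True)
class AnalysisConfig:
    residue_pairs: tuple[tuple[int, int, str], ...] = ()
    contact_threshold: float = CONTACT_THRESHOLD
    run_dccm: bool = True
    run_pca: bool = True
    state_space: bool = True
    bins: int = 50


@dataclass
class PipelineConfig:
    synthetic: SyntheticSpec = field(default_factory=default_study_spec)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    lime: LimeConfig = field(default_factory=LimeConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    write_pdb: bool = False
    plots: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        self.synthetic.validate()
        if len(self.synthetic.state_labels) != 2:
            raise ValueError("exactly two state labels are required")
        n = self.synthetic.n_residues
        for a, b, metric in self.analysis.residue_pairs:
            if not (1 <= a <= n and 1 <= b <= n):
                raise ValueError(f"residue pair ({a}, {b}) outside 1..{n}")
            if metric not in ("CA-CA", "closest-heavy"):
                raise ValueError(f"unknown distance metric {metric!r}")
            if metric == "closest-heavy" and self.synthetic.atoms_per_residue < 2:
                raise ValueError("closest-heavy metric needs atoms_per_residue >= 2")
        if self.lime.top_k > n:
            raise ValueError(f"top_k={self.lime.top_k} exceeds residue count {n}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict(),
            "classifier": dataclasses.asdict(self.classifier),
            "lime": dataclasses.asdict(self.lime),
            "analysis": dataclasses.asdict(self.analysis),
            "seed": self.seed,
            "write_pdb": self.write_pdb,
            "plots": self.plots,
        }

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.get("synthetic", {})
        syn = syn if isinstance(syn, SyntheticSpec) else SyntheticSpec.from_dict(syn)
        clf = d.get("classifier", {})
        clf = clf if isinstance(clf, ClassifierConfig) else ClassifierConfig(
            **{**clf, "conv_kernels": tuple(clf.get("conv_kernels", (32, 32, 64, 64)))}
        )
        lime = d.get("lime", {})
        lime = lime if isinstance(lime, LimeConfig) else LimeConfig(**lime)
        ana = d.get("analysis", {})
        if not isinstance(ana, AnalysisConfig):
            pairs = tuple(
                (int(p[0]), int(p[1]), str(p[2])) for p in ana.get("residue_pairs", ())
            )
            ana = AnalysisConfig(**{**ana, "residue_pairs": pairs})
        return PipelineConfig(
            synthetic=syn, classifier=clf, lime=lime, analysis=ana,
            seed=int(d.get("seed", 0)),
            write_pdb=bool(d.get("write_pdb", False)),
            plots=bool(d.get("plots", False)),
        )

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage_dir(outdir: Path, name: str, key: dict) -> tuple[Path, bool]:
    d = outdir / f"{name}-{_hash(key)}"
    done = (d / "DONE").exists()
    d.mkdir(parents=True, exist_ok=True)
    return d, done


def _mark_done(d: Path) -> None:
    (d / "DONE").write_text("ok\n")


def run_pipeline(config: PipelineConfig, outdir, until: str = "report") -> Path:
    """Run the pipeline into ``outdir`` up to stage ``until``.

    Returns the run directory.  Completed stages (identified by a hash of
    the configuration they depend on) are not recomputed.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.save(outdir / "config.yaml")
    log.info("pixelmd %s | python %s | numpy %s | master seed %d",
             __version__, platform.python_version(), np.__version__, config.seed)
    last = STAGES.index(until)
    summary: dict = {"seed": config.seed, "version": __version__}

    # -- simulate ----------------------------------------------------------
    spec = dataclasses.replace(config.synthetic, seed=config.seed)
    sim_key = {"spec": spec.to_dict()}
    sim_dir, _ = _stage_dir(outdir, "simulate", sim_key)
    log.info("stage simulate: %d residues, %d traj/state x %d frames",
             spec.n_residues, spec.n_trajectories_per_state, spec.n_frames)
    data = _run_stage("simulate", lambda: simulate_dataset(spec))
    ensembles = [e for state in spec.state_labels for e in data[state]]
    if config.write_pdb:
        for ens in ensembles:
            write_ensemble(ens, sim_dir / f"{ens.state}_traj{ens.trajectory_id}.pdb")
        spec.save(sim_dir / "spec.yaml")
    _mark_done(sim_dir)
    summary["n_frames_total"] = sum(e.n_frames for e in ensembles)
    if last == STAGES.index("simulate"):
        _finish(outdir, summary)
        return outdir

    # -- encode ------------------------------------------------------------
    enc_key = {**sim_key, "encode": True}
    enc_dir, enc_done = _stage_dir(outdir, "encode", enc_key)
    ds_path = enc_dir / "dataset.npz"
    if enc_done and ds_path.exists():
        log.info("stage encode: cached")
        dataset = PixelMapDataset.load(ds_path)
    else:
        def _encode():
            ref = ensembles[0].coords[0]
            sel = ensembles[0].topology.ca_indices()
            aligned = [align_ensemble(e, ref, sel) for e in ensembles]
            return encode_ensemble(aligned)
        dataset = _run_stage("encode", _encode)
        dataset.save(ds_path)
        _mark_done(enc_dir)
    log.info("stage encode: %d images of %dx%d (%d coords clipped)",
             dataset.n_samples, dataset.images.shape[1], dataset.images.shape[2],
             dataset.clipped)
    summary["image_side"] = int(dataset.images.shape[1])
    if last == STAGES.index("encode"):
        _finish(outdir, summary)
        return outdir

    # -- train (grouped five-fold CV) --------------------------------------
    clf_cfg = dataclasses.replace(config.classifier, seed=config.seed)
    tr_key = {**enc_key, "classifier": dataclasses.asdict(clf_cfg)}
    tr_dir, tr_done = _stage_dir(outdir, "train", tr_key)
    counts = [int(np.sum(dataset.trajectory_ids == t))
              for t in np.unique(dataset.trajectory_ids)]
    folds = make_fold_assignment(counts)
    cv: CVResult | None = None
    metrics_path = tr_dir / "cv_metrics.tsv"
    if tr_done and metrics_path.exists():
        log.info("stage train: cached metrics (models retrained only if needed)")
        metrics = pd.read_csv(metrics_path, sep="\t")
        fold_accs = metrics["accuracy"].tolist()
    else:
        cv = _run_stage(
            "train",
            lambda: cross_validate(dataset, folds, clf_cfg, log=log.info),
        )
        cv.to_frame().to_csv(metrics_path, sep="\t", index=False)
        for i, model in enumerate(cv.models):
            model.network.save(tr_dir / f"fold{i + 1}_weights.npz")
        fold_accs = cv.fold_accuracies
        _mark_done(tr_dir)
    summary["cv_fold_accuracies"] = [float(a) for a in fold_accs]
    summary["cv_mean_accuracy"] = float(np.mean(fold_accs))
    log.info("stage train: mean CV accuracy %.4f", summary["cv_mean_accuracy"])
    if last == STAGES.index("train"):
        _finish(outdir, summary)
        return outdir

    # -- explain -----------------------------------------------------------
    ex_key = {**tr_key, "lime": dataclasses.asdict(config.lime)}
    ex_dir, ex_done = _stage_dir(outdir, "explain", ex_key)
    table_path = ex_dir / "residue_importance.tsv"
    if ex_done and table_path.exists():
        log.info("stage explain: cached")
        table_df = pd.read_csv(table_path, sep="\t")
    else:
        if cv is None:
            cv = _run_stage(
                "train(rerun for models)",
                lambda: cross_validate(dataset, folds, clf_cfg, log=log.info),
            )
        best = int(np.argmax(cv.fold_accuracies))
        def _explain():
            table, _ = explain_dataset(
                cv.models[best], dataset,
                n_per_state=config.lime.n_per_state,
                n_perturbations=config.lime.n_perturbations,
                top_fraction=config.lime.top_fraction,
                seed=config.seed,
            )
            return table
        table = _run_stage("explain", _explain)
        table_df = table.to_frame()
        table_df.to_csv(table_path, sep="\t", index=False)
        _mark_done(ex_dir)
    top = table_df.sort_values(["rank"]).head(config.lime.top_k)
    summary["top_residues"] = top["residue"].tolist()
    summary["top_scores"] = [float(s) for s in top["score"]]
    log.info("stage explain: top residue %s (score %.3f)",
             summary["top_residues"][0], summary["top_scores"][0])
    if last == STAGES.index("explain"):
        _finish(outdir, summary)
        return outdir

    # -- dynamics ----------------------------------------------------------
    dyn_key = {**sim_key, "analysis": dataclasses.asdict(config.analysis)}
    dyn_dir, dyn_done = _stage_dir(outdir, "dynamics", dyn_key)
    if not (dyn_done and (dyn_dir / "dynamics_summary.json").exists()):
        dyn_summary = _run_stage(
            "dynamics", lambda: _run_dynamics(config, spec, data, dyn_dir)
        )
        (dyn_dir / "dynamics_summary.json").write_text(json.dumps(dyn_summary, indent=2))
        _mark_done(dyn_dir)
    else:
        log.info("stage dynamics: cached")
        dyn_summary = json.loads((dyn_dir / "dynamics_summary.json").read_text())
    summary["dynamics"] = dyn_summary

    # -- report ------------------------------------------------------------
    if config.plots:
        _make_plots(outdir, dataset, table_df, dyn_dir)
    _finish(outdir, summary)
    return outdir


def _run_stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _run_dynamics(config: PipelineConfig, spec: SyntheticSpec, data, dyn_dir: Path) -> dict:
    from .trajio import align_ensemble
    from .topology import ConformationalEnsemble

    out: dict = {}
    ana = config.analysis
    for state in spec.state_labels:
        cat = ConformationalEnsemble.concatenate(data[state])
        sel = cat.topology.ca_indices()
        ref = data[state][0].coords[0]
        aligned = align_ensemble(cat, ref, sel)
        sstate: dict = {}
        rs = rmsd_series(aligned, ref, sel, superpose=False)
        sstate["rmsd_mean"] = float(rs.values.mean())
        pd.DataFrame({"time_ps": rs.times, "rmsd_A": rs.values}).to_csv(
            dyn_dir / f"rmsd_{state}.tsv", sep="\t", index=False)
        for a, b, metric in ana.residue_pairs:
            series = pair_distance_series(cat, a, b, metric, ana.contact_threshold)
            key = f"dist_{a}_{b}_{metric}"
            sstate[key] = {
                "mean": float(series.values.mean()),
                "sd": float(series.values.std()),
                "max": float(series.values.max()),
                "contact_fraction": contact_fraction(series),
            }
            pd.DataFrame({"time_ps": series.times, "distance_A": series.values}).to_csv(
                dyn_dir / f"{key}_{state}.tsv", sep="\t", index=False)
        if ana.run_dccm:
            mat = dccm(aligned, sel)
            off = mat.matrix[~np.eye(mat.matrix.shape[0], dtype=bool)]
            sstate["dccm_mean_abs_offdiag"] = float(np.nanmean(np.abs(off)))
            pd.DataFrame(mat.matrix, index=mat.residue_ids,
                         columns=mat.residue_ids).to_csv(
                dyn_dir / f"dccm_{state}.tsv", sep="\t")
        if ana.run_pca:
            pca = pca_modes(aligned, sel)
            sstate["pca_explained_pc1"] = float(pca.explained_fraction[0])
            sstate["pca_top_amplitude_residue"] = int(
                pca.residue_ids[int(np.argmax(pca.pc1_amplitudes))])
            pd.DataFrame({
                "residue": pca.residue_ids,
                "amp_A": pca.pc1_amplitudes,
                "vx": pca.pc1_vectors[:, 0],
                "vy": pca.pc1_vectors[:, 1],
                "vz": pca.pc1_vectors[:, 2],
            }).to_csv(dyn_dir / f"pca_pc1_{state}.tsv", sep="\t", index=False)
        if ana.state_space and spec.interdomain_pair is not None:
            p = spec.interdomain_pair
            dser = pair_distance_series(cat, p.residue_i, p.residue_j)
            density, _, _ = state_space_projection(rs, dser, bins=ana.bins)
            sstate["state_space_occupied_bins"] = int(np.count_nonzero(density))
        out[state] = sstate
    return out


def _make_plots(outdir: Path, dataset, table_df, dyn_dir: Path) -> None:
    from . import plotting

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)
    plotting.save_pixelmap_png(dataset.images[0], plots / "example_pixelmap.png")
    plotting.save_importance_heatmap(table_df, plots / "residue_importance.png")
    for tsv in dyn_dir.glob("dccm_*.tsv"):
        plotting.save_dccm_heatmap(
            pd.read_csv(tsv, sep="\t", index_col=0).values,
            plots / (tsv.stem + ".png"),
        )


def _finish(outdir: Path, summary: dict) -> None:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("run complete: %s", outdir / "summary.json")


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_pixelmd_tag", None) for h in log.handlers}
    if "console" not in have:
        h = logging.StreamHandler()
        h._pixelmd_tag = "console"
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    for h in [h for h in log.handlers if getattr(h, "_pixelmd_tag", None) == "file"]:
        h.close()
        log.removeHandler(h)
    fh = logging.FileHandler(outdir / "run.log")
    fh._pixelmd_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
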