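"""Config-driven orchestration of the full analysis graph.

A pipeline run takes one or more ensembles (from disk or generated
synthetically), computes per-frame descriptors, ensemble statistics with
blocking errors, interaction profiles, t-SNE cluster models with per-cluster
reports, and optionally maximum-entropy reweighting, writing delimited
tables plus a machine-readable manifest (config hash, seeds, versions) to
an output directory.  One global seed deterministically derives per-stage
seeds.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (cluster_report, downsample, hyperparameter_scan,
                         rmsd_matrix)
from .interactions import interaction_profile
from .io import (Ensemble, config_hash, read_multimodel_pdb, read_observables,
                 write_multimodel_pdb, write_report, write_topology)
from .order_parameters import frame_descriptors
from .reweighting import ReweightConfig, maxent_fit, tune_theta
from .statistics import fes2d, subensemble_summary
from .synthetic import (GeneratorConfig, sample_ensemble, synth_observables,
                        two_region_profile)

log = logging.getLogger("idpens")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence(
        [global_seed, abs(hash(stage)) % (2 ** 31)]).generate_state(1)[0]
        % (2 ** 31))


def validate_config(config: dict) -> list[str]:
    """Aggregate schema/cross-field diagnostics; empty list means valid."""
    problems = []
    if "ensembles" not in config or not config["ensembles"]:
        problems.append("config must list at least one ensemble")
    labels = [e.get("label") for e in config.get("ensembles", [])]
    if len(labels) != len(set(labels)):
        problems.append("ensemble labels must be unique")
    for spec in config.get("ensembles", []):
        if "label" not in spec:
            problems.append("every ensemble needs a label")
        if "pdb" in spec:
            if not Path(spec["pdb"]).exists():
                problems.append(f"missing ensemble file: {spec['pdb']}")
            if "topology" not in spec:
                problems.append(f"ensemble {spec.get('label')}: PDB input "
                                "requires a topology path")
            elif not Path(spec["topology"]).exists():
                problems.append(f"missing topology file: {spec['topology']}")
        elif "synthetic" not in spec:
            problems.append(f"ensemble {spec.get('label')}: needs 'pdb' or "
                            "'synthetic'")
    cl = config.get("clustering", {})
    if cl.get("enabled", True):
        if not cl.get("perplexities", [30]):
            problems.append("clustering perplexity grid is empty")
        if not cl.get("n_clusters", [4]):
            problems.append("clustering N grid is empty")
    rw = config.get("reweighting", {})
    if rw.get("enabled", False):
        if "observables" not in rw and not any(
                "synthetic" in e for e in config.get("ensembles", [])):
            problems.append("reweighting requires an observable table or a "
                            "synthetic ensemble")
    return problems


def _load_ensembles(config: dict, seed: int) -> tuple[dict[str, Ensemble], dict]:
    ensembles: dict[str, Ensemble] = {}
    truths = {}
    for spec in config["ensembles"]:
        label = spec["label"]
        if "pdb" in spec:
            ensembles[label] = read_multimodel_pdb(spec["pdb"],
                                                   spec["topology"])
        else:
            params = dict(spec["synthetic"])
            if params.pop("two_region_profile", False):
                params["helix_propensity"] = two_region_profile(
                    params.get("n_residues", 56))
            params.setdefault("seed", _stage_seed(seed, f"synth:{label}"))
            gen = GeneratorConfig(**params)
            ens, truth = sample_ensemble(gen)
            ens.provenance = label
            ensembles[label] = ens
            truths[label] = truth
    return ensembles, truths


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> Path:
    """Execute the configured analysis graph; returns the run directory."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("output_dir", "idpens_run"))
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": seed, "version": __version__}
    manifest = {**meta, "stages": {}, "config": config}
    t0 = time.time()

    def finish_stage(name):
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 2)}
        log.info("stage %s done (%.1fs)", name, time.time() - t0)

    try:
        ensembles, truths = _load_ensembles(config, seed)
        for label, ens in ensembles.items():
            write_multimodel_pdb(ens, out / f"{label}.pdb")
            write_topology(ens.topology, out / f"{label}.topology.json")
        finish_stage("ensembles")

        descriptors = {}
        for label, ens in ensembles.items():
            d = frame_descriptors(ens)
            descriptors[label] = d
            write_report(d.to_frame(), out / f"{label}.descriptors.tsv", meta)
        finish_stage("descriptors")

        stats_cfg = config.get("statistics", {})
        bins = stats_cfg.get("bins", 40)
        summary_rows = []
        for label, ens in ensembles.items():
            d = descriptors[label]
            fes = fes2d(d.salpha, d.rg, ens.frame_weights, bins=bins)
            np.savetxt(out / f"{label}.fes.tsv", fes.free_energy,
                       delimiter="\t", header=f"config_hash {chash}")
            summ = subensemble_summary(ens, d)
            summary_rows.append({
                "ensemble": label, "p": summ.population,
                "BF": summ.bound_fraction, "BF_se": summ.bound_fraction_se,
                "p_Glob": summ.globule_population,
                "p_Glob_se": summ.globule_population_se,
                "HF": summ.helix_fraction, "HF_se": summ.helix_fraction_se})
        write_report(pd.DataFrame(summary_rows), out / "summary.tsv", meta)
        finish_stage("statistics")

        for label, ens in ensembles.items():
            if ens.topology.ligand_atoms:
                prof = interaction_profile(ens, label=label)
                write_report(prof.populations.reset_index(names="residue"),
                             out / f"{label}.interactions.tsv", meta)
        finish_stage("interactions")

        cl = config.get("clustering", {})
        if cl.get("enabled", True) and sum(
                e.n_frames for e in ensembles.values()) >= 20:
            target = cl.get("downsample")
            used = {}
            for label, ens in ensembles.items():
                if target and ens.n_frames > target:
                    ens, _ = downsample(ens, target,
                                        seed=_stage_seed(seed, "downsample"),
                                        mode=cl.get("downsample_mode",
                                                    "stride"))
                used[label] = ens
            dm = rmsd_matrix(list(used.values()), list(used))
            best, table = hyperparameter_scan(
                dm, cl.get("perplexities", [30]), cl.get("n_clusters", [4]),
                seed=_stage_seed(seed, "tsne"),
                tsne_kwargs=cl.get("tsne", None))
            write_report(table, out / "cluster_scores.tsv", meta)
            labels_df = pd.DataFrame({
                "source": dm.sources, "frame": dm.frame_indices,
                "cluster": best.labels + 1,
                "embedding_x": best.embedding.coordinates[:, 0],
                "embedding_y": best.embedding.coordinates[:, 1]})
            write_report(labels_df, out / "cluster_labels.tsv", meta)
            report = cluster_report(used, best, dm)
            write_report(report, out / "cluster_report.tsv", meta)
        finish_stage("clustering")

        rw = config.get("reweighting", {})
        if rw.get("enabled", False):
            label = rw.get("ensemble", next(iter(ensembles)))
            if "observables" in rw:
                obs = read_observables(rw["observables"])
            else:
                obs = synth_observables(ensembles[label], truths[label],
                                        _stage_seed(seed, "observables"))
            n_obs = obs.values.shape[1]
            restrained = np.array(rw.get("restrained",
                                         list(range(0, n_obs, 2))))
            held = np.array(rw.get("held_out",
                                   [j for j in range(n_obs)
                                    if j not in set(restrained.tolist())]))
            cfg = ReweightConfig(restrained=restrained, held_out=held,
                                 theta=rw.get("theta"))
            if rw.get("target_kish"):
                theta, result = tune_theta(obs, None,
                                           float(rw["target_kish"]), cfg)
            else:
                if cfg.theta is None:
                    cfg.theta = 1.0
                result = maxent_fit(obs, None, cfg)
            write_report(pd.DataFrame({"frame": np.arange(result.weights.size),
                                       "weight": result.weights}),
                         out / "weights.tsv", meta)
            write_report(pd.DataFrame([{
                "theta": result.theta, "kish": result.kish,
                "fit_rmse": result.fit_rmse,
                "cv_rmse": result.cross_validation_rmse,
                "converged": result.converged}]),
                out / "reweight_summary.tsv", meta)
        finish_stage("reweighting")
    except PipelineError:
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        stage = max(manifest["stages"], default="setup")
        raise PipelineError(f"after:{stage}", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
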