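"""End-to-end orchestration: synthetic data → PRE → BME → downstream analyses.

:class:`PipelineConfig` collects every tunable of the downstream modules with
the study defaults; :func:`run_pipeline` executes the full flow

    forward PRE → data preparation → BME reweighting → landscape →
    contacts → entropy (→ titration)

on a synthetic multi-state complex, returning a machine-readable summary that
records every parameter actually used together with its provenance
("default" or "user").  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bme, contacts, entropy, landscape, synthetic, titration
from .ensemble import write_ensemble
from .pre import PhysicalConstants
from .synthetic import ChainSpec, GroundTruth

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, defaulting to the study values."""

    seed: int = 0
    # synthetic system
    chain_length: int = 311
    n_frames_per_state: int = 250
    state_weights: dict = field(
        default_factory=lambda: {"I": 0.4, "II": 0.3, "III": 0.2, "IV": 0.1}
    )
    noise_sd: float = 0.0
    kd_true: dict = field(
        default_factory=lambda: {"LD1": 17.0, "LD2": 7.0, "LD4": 13.0}
    )
    receptor_conc: float = 100.0
    # PRE forward model
    field_mhz: float = 600.0
    tau_c: float = 29e-9
    tau_i: float = 500e-12
    t_d: float = 10e-3
    r2_red: float = 40.0
    gamma2_cap: float = 450.0
    n_rotamers: int = 16
    # BME
    loess_span: float = 0.2
    smooth: bool = True
    error_scale: float = 1.0
    error_floor: float = 0.05
    error_mode: str = "inverse"
    theta_grid: tuple = tuple(np.logspace(4, -2, 13))
    # landscape
    pca_components: int = 50
    umap_fraction: float = 0.1
    knn_k: int = 15
    louvain_resolution: float = 1.0
    cluster_threshold: float = 0.01
    n_shuffles: int = 1000
    # contacts / entropy
    contact_cutoff: float = contacts.CA_CUTOFF
    high_thresh: float = 0.6
    low_thresh: float = 0.2
    n_bins: int = 35
    temperature: float = 310.0
    entropy_correction: str = "subtracted"
    # bookkeeping (not a tunable)
    _user_keys: tuple = ()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from a flat mapping; unknown keys are an error."""
        valid = {f.name for f in dataclasses.fields(cls) if f.name != "_user_keys"}
        unknown = set(data) - valid
        if unknown:
            raise PipelineError(
                f"config validation: unknown keys {sorted(unknown)}"
            )
        return cls(**data, _user_keys=tuple(sorted(data)))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def parameters(self) -> dict:
        """Every tunable with its value and provenance."""
        out = {}
        for f in dataclasses.fields(self):
            if f.name == "_user_keys":
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = {
                "value": v,
                "provenance": "user" if f.name in self._user_keys else "default",
            }
        return out

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(
            field_mhz=self.field_mhz, tau_c=self.tau_c, tau_i=self.tau_i,
            t_d=self.t_d, r2_red=self.r2_red, gamma2_cap=self.gamma2_cap,
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 run_titration: bool = True) -> dict:
    """Execute the full synthetic-data pipeline; return the run summary.

    Deterministic under a fixed config (including its seed).  When ``outdir``
    is given, result tables (weights, θ scan, contacts, entropy, titration
    fits), the ensemble, and the JSON summary are written there.
    """
    summary: dict = {"parameters": config.parameters()}
    constants = config.constants()

    gen = _stage("simulate")(_simulate)
    ens, pre_data = gen(config, constants)
    summary["n_frames"] = ens.n_frames

    prep = _stage("prep")(bme.prepare_pre_table)
    table = bme.PRETable(pre_data.table[["site", "chain", "residue", "ratio"]])
    table = prep(
        table, constants, span=config.loess_span, smooth=config.smooth,
        error_scale=config.error_scale, error_floor=config.error_floor,
        error_mode=config.error_mode,
    )
    gmat = np.vstack([pre_data.gamma2[s] for s in table.df["site"].unique()])

    scan = _stage("reweight")(bme.theta_scan)(
        gmat,
        table.df["gamma2_exp"].to_numpy(),
        table.df["sigma2"].to_numpy(),
        priors=ens.prior_weights,
        thetas=np.asarray(config.theta_grid, dtype=float),
        states=ens.states,
    )
    best = next(r for r in scan.results if r.theta == scan.selected_theta)
    weights = best.weights
    summary["reweight"] = {
        "selected_theta": scan.selected_theta,
        "chi2": best.chi2,
        "effective_sample_size": best.effective_sample_size,
        "state_weights": best.state_weights,
    }

    land = _stage("landscape")(_landscape)
    summary["landscape"] = land(config, ens, weights, outdir)

    cont = _stage("contacts")(_contacts)
    contact_summary, contact_classes = cont(config, ens, weights)
    summary["contacts"] = contact_summary

    ent = _stage("entropy")(_entropy)
    summary["entropy"] = ent(config, ens, weights, contact_classes)

    if run_titration:
        tit = _stage("titrate")(_titrate)
        summary["titration"] = tit(config)

    rg, rg_summary = landscape.radius_of_gyration(ens, weights, per_state=True)
    summary["rg"] = rg_summary

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ensemble(ens, outdir / "ensemble.pdb")
        pd.DataFrame(
            {
                "frame": np.arange(ens.n_frames),
                "state": ens.states,
                "prior": ens.prior_weights,
                "weight": weights,
            }
        ).to_csv(outdir / "weights.csv", index=False)
        scan.as_frame().to_csv(outdir / "theta_scan.csv", index=False)
        table.df.to_csv(outdir / "pre_table.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary


def _simulate(config: PipelineConfig, constants: PhysicalConstants):
    chain = ChainSpec(length=config.chain_length)
    states = synthetic.default_states()
    truth = GroundTruth(
        state_weights=config.state_weights,
        kd_true=config.kd_true,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    ens = synthetic.sample_complex_ensemble(
        chain, states, truth, config.n_frames_per_state
    )
    pre_data = synthetic.synthesize_pre(
        ens, synthetic.default_sites(), truth, constants,
        n_rotamers=config.n_rotamers,
    )
    return ens, pre_data


def _landscape(config: PipelineConfig, ens, weights, outdir):
    feats = landscape.segment_features(ens, "A")
    model = landscape.reduce_pca(feats, n_components=config.pca_components)
    model = landscape.embed_umap(
        model, subsample_fraction=config.umap_fraction, seed=config.seed
    )
    assignment = landscape.cluster_conformations(
        model, k_neighbors=config.knn_k,
        resolution=config.louvain_resolution, seed=config.seed,
    )
    contrib = landscape.cluster_contributions(
        assignment, weights, threshold=config.cluster_threshold
    )
    km = landscape.kmeans_on_embedding(
        model, k=assignment.n_clusters, seed=config.seed
    )
    report = landscape.validate_clustering(
        assignment.labels, km.labels, n_shuffles=config.n_shuffles,
        seed=config.seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "frame": np.arange(len(assignment.labels)),
                "x": model.embedding[:, 0],
                "y": model.embedding[:, 1],
                "cluster": assignment.labels,
            }
        ).to_csv(outdir / "embedding.csv", index=False)
        contrib.to_csv(outdir / "cluster_contributions.csv", index=False)
    return {
        "n_features": feats.n_features,
        "n_clusters": assignment.n_clusters,
        "top_clusters": int(contrib["top"].sum()),
        "top_share": contrib.attrs["top_set_share"],
        "ari_vs_kmeans": report.ari,
        "ami_vs_kmeans": report.ami,
        "null_ari_mean": report.null_ari_mean,
    }


def _contacts(config: PipelineConfig, ens, weights):
    per_state = contacts.contact_frequency_map(
        ens, weights, chain_a="A", cutoff=config.contact_cutoff, per_state=True
    )
    specific = contacts.state_specific_contacts(
        per_state, high_thresh=config.high_thresh, low_thresh=config.low_thresh
    )
    profiles = contacts.interaction_profile(
        ens, weights, "A", "B", cutoff=config.contact_cutoff
    )
    global_map = contacts.contact_frequency_map(
        ens, weights, chain_a="A", cutoff=config.contact_cutoff
    )
    # per-residue contact frequencies for the entropy contact classes:
    # intra-chain (max over the residue's segment pairs) and inter-chain
    n_res = ens.ca_coords("A").shape[1]
    per_res = np.zeros(n_res)
    freq_any = global_map.frequencies.max(axis=1)
    for (s, e), fval in zip(global_map.windows_a, freq_any):
        per_res[s:e] = fval
    rmap = ens.residue_map("A")
    contact_classes = {
        "intra": {rmap.number(i): float(per_res[i]) for i in range(n_res)},
        "inter": {
            rmap.number(i): float(profiles["A"].residue_probability[i])
            for i in range(n_res)
        },
    }
    return (
        {
            "n_state_specific": int(len(specific)),
            "mean_interface_probability_A": float(
                profiles["A"].segment_probability.mean()
            ),
            "mean_interface_probability_B": float(
                profiles["B"].segment_probability.mean()
            ),
        },
        contact_classes,
    )


def _entropy(config: PipelineConfig, ens, weights, contact_classes):
    tors = entropy.extract_torsions(ens, "A")
    profile = entropy.residue_entropy_profile(
        tors, weights, n_bins=config.n_bins, temperature=config.temperature,
        correction=config.entropy_correction,
    )
    comparisons = {
        kind: entropy.entropy_contact_comparison(
            profile, freqs, low=config.low_thresh, high=config.high_thresh
        )
        for kind, freqs in contact_classes.items()
    }
    return {
        "mean_entropy_rt": float(profile.table["entropy_rt"].mean()),
        "contact_comparison": comparisons,
    }


def _titrate(config: PipelineConfig):
    series = synthetic.synthesize_titration(
        config.kd_true, receptor_conc=config.receptor_conc,
        noise_sd=config.noise_sd, seed=config.seed,
        motif_residues={
            m: list(range(s, e + 1))
            for m, (s, e) in ChainSpec(length=config.chain_length)
            .helical_segments.items()
            if m in config.kd_true
        },
    )
    fits = titration.fit_kd_table(series)
    summary = titration.motif_kd_summary(fits, series.motif_map)
    return {
        row["motif"]: {"kd_mean": row["kd_mean"], "kd_sd": row["kd_sd"]}
        for _, row in summary.motif_summary.iterrows()
    }
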