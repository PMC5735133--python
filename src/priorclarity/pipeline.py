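"""End-to-end orchestration: design -> simulate -> fit -> stats -> neural -> report.

A :class:`RunConfig` (YAML-serialisable) names an explicit seed for every
stochastic stage, so any run is reproducible from its config alone.  Each
stage writes plain-text outputs (CSV/JSON) plus an HDF5 container for
trial arrays, and the :class:`RunManifest` records SHA-256 digests of all
inputs/outputs so re-runs can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import design, groupstats, model, neural, simulate
from ._version import __version__

log = logging.getLogger("priorclarity")

STAGES = ("design", "simulate", "fit", "stats", "neural", "report")


@dataclass
class NeuralSettings:
    latency_band_hz: tuple[float, float] = (12.0, 24.0)
    fraction: float = 0.8
    n_permutations: int = 1000
    coupling_band_hz: tuple[float, float] = (13.0, 23.0)
    n_trials: int = 60
    control_latency_range_ms: tuple[float, float] = (275.0, 400.0)
    patient_latency_range_ms: tuple[float, float] = (412.0, 1048.0)


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    n_per_group: int = 11
    variants: tuple[str, ...] = ("simple", "complex")
    n_starts: int = 32
    seeds: dict = field(
        default_factory=lambda: {
            "design": 11, "simulate": 22, "fit": 33, "neural": 44
        }
    )
    neural: NeuralSettings = field(default_factory=NeuralSettings)

    def __post_init__(self) -> None:
        missing = {"design", "simulate", "fit", "neural"} - set(self.seeds)
        if missing:
            raise ValueError(f"every stochastic stage needs a seed; missing {missing}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        d["neural"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(self.neural).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        ns = d.pop("neural", {})
        ns = {k: (tuple(v) if isinstance(v, list) else v) for k, v in ns.items()}
        d["variants"] = tuple(d.get("variants", ("simple", "complex")))
        return cls(neural=NeuralSettings(**ns), **d)

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    started: float
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages[stage] = {
            "outputs": {name: _digest(p) for name, p in outputs.items()},
            "finished": time.time(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted in stage '{stage}': {cause}")
        self.stage = stage


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in dependency order, writing a digest manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.content_hash(), __version__, time.time())
    config.to_yaml(out / "config.yaml")

    state: dict = {}
    for stage in STAGES:
        log.info("stage %s starting", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # halt naming the stage; keep partial outputs
            manifest.to_json(out / "manifest.json")
            raise StageError(stage, exc) from exc
        manifest.record(stage, outputs)
        log.info("stage %s done: %s", stage, ", ".join(outputs))
    manifest.to_json(out / "manifest.json")
    return manifest


def _stage_design(config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    seed = config.seeds["design"]
    pool = simulate.default_word_pool(400)
    sched = design.build_exp1_schedule(pool, "A", seed)
    exp2 = design.build_exp2_schedule(design.default_response_sets(), seed)
    repl = design.build_neutral_replication_schedule(pool, seed)
    p1 = out / "exp1_schedule.csv"
    sched.to_frame().to_csv(p1, index=False)
    p2 = out / "exp2_schedule.csv"
    design.exp2_to_frame(exp2).to_csv(p2, index=False)
    p3 = out / "replication_schedule.csv"
    design.Exp1Schedule(repl, "A").to_frame().to_csv(p3, index=False)
    p4 = out / "design_summary.json"
    p4.write_text(json.dumps(sched.summary(), indent=2))
    state["exp1"], state["exp2"] = sched, exp2
    return {"exp1": p1, "exp2": p2, "replication": p3, "summary": p4}


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    spec = simulate.CohortSpec(n_per_group=config.n_per_group,
                               seed=config.seeds["simulate"])
    cohort = simulate.simulate_cohort(spec)
    state["cohort"] = cohort
    rows = []
    truth = []
    for i, (group, ds, params) in enumerate(cohort):
        sid = f"{group}{i:02d}"
        df = ds.exp1.assign(subject=sid, group=group)
        rows.append(df)
        truth.append({"subject": sid, "group": group,
                      "sigma_prior": params.sigma_prior,
                      "threshold": params.threshold,
                      "rating_noise_sd": params.rating_noise_sd,
                      "identification_ability": params.identification_ability})
    p1 = out / "behaviour_exp1.csv"
    pd.concat(rows).to_csv(p1, index=False)
    p2 = out / "true_parameters.csv"
    pd.DataFrame(truth).to_csv(p2, index=False)
    return {"behaviour": p1, "truth": p2}


def _stage_fit(config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    seed = config.seeds["fit"]
    records = []
    for i, (group, ds, params) in enumerate(state["cohort"]):
        sid = f"{group}{i:02d}"
        means = ds.condition_means()
        means = {c: means[c] for c in model.CONDITION_ORDER}
        fits = {}
        for variant in config.variants:
            fits[variant] = model.fit_subject(
                means, ds.sensory_precision_measured, variant=variant,
                n_starts=config.n_starts, seed=seed + i,
            )
        rec = {"subject": sid, "group": group,
               "true_sigma_prior": params.sigma_prior,
               "true_threshold": params.threshold}
        for variant, fit in fits.items():
            rec.update({f"{variant}_{k}": v for k, v in fit.to_dict().items()
                        if k != "variant"})
        if {"simple", "complex"} <= set(fits):
            pref = model.compare_variants(fits["simple"], fits["complex"])
            rec["aicc_winner"] = pref.winner
            rec["delta_aicc"] = pref.delta_aicc
        records.append(rec)
    p = out / "fits.csv"
    df = pd.DataFrame(records)
    df.to_csv(p, index=False)
    state["fits"] = df
    return {"fits": p}


def _stage_stats(config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    fits = state["fits"]
    ctrl = fits[fits["group"] == "control"]
    pat = fits[fits["group"] == "patient"]
    cmp_sigma = groupstats.rank_sum_test(
        pat["simple_sigma_prior"], ctrl["simple_sigma_prior"], mode="exact"
    )
    cmp_theta = groupstats.rank_sum_test(
        pat["simple_threshold"], ctrl["simple_threshold"], mode="exact"
    )
    recov = groupstats.association(
        fits["true_sigma_prior"], fits["simple_sigma_prior"], kind="spearman"
    )
    # congruency effects straight from the cohort datasets
    effects: dict[str, list[float]] = {"control": [], "patient": []}
    for group, ds, _ in state["cohort"]:
        effects[group].append(groupstats.congruency_effect(ds.exp1)["overall"])
    summary = {
        "sigma_prior_rank_sum": dataclasses.asdict(cmp_sigma),
        "threshold_rank_sum": dataclasses.asdict(cmp_theta),
        "sigma_recovery": dataclasses.asdict(recov),
        "mean_congruency_effect": {g: float(np.mean(v)) for g, v in effects.items()},
    }
    p = out / "group_stats.json"
    p.write_text(json.dumps(summary, indent=2))
    state["group_stats"] = summary
    return {"group_stats": p}


def _stage_neural(config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    ns = config.neural
    seed = config.seeds["neural"]
    rng = np.random.default_rng(seed)

    # t80 latency recovery with implanted cohort latencies
    lat_rows = []
    for group, rng_range in (("control", ns.control_latency_range_ms),
                             ("patient", ns.patient_latency_range_ms)):
        for i in range(config.n_per_group):
            implanted = float(rng.uniform(*rng_range))
            tf_m, tf_mm = simulate.simulate_tf_contrast(
                implanted, seed=int(rng.integers(2**31))
            )
            series = neural.band_contrast_latency(
                tf_m, tf_mm, band_hz=ns.latency_band_hz, fraction=ns.fraction
            )
            lat_rows.append({"subject": f"{group}{i:02d}", "group": group,
                             "implanted_ms": implanted, "t80_ms": series.t80_ms})
    p1 = out / "latencies.csv"
    lat_df = pd.DataFrame(lat_rows)
    lat_df.to_csv(p1, index=False)

    # connectivity on coupled sources (frontal -> temporal in beta)
    spec = simulate.CouplingSpec(direction="frontal_to_temporal",
                                 band_hz=ns.coupling_band_hz)
    src = simulate.simulate_coupled_sources(spec, n_trials=ns.n_trials,
                                            seed=seed + 1)
    frontal = neural.subtract_evoked(src.frontal)
    temporal = neural.subtract_evoked(src.temporal)

    def icoh_stat(a, b):
        return neural.imaginary_coherence(
            neural.multitaper_cross_spectra(a, b, sfreq=src.sfreq)
        )

    est = neural.multitaper_cross_spectra(frontal, temporal, sfreq=src.sfreq)
    icoh = neural.imaginary_coherence(est)
    _, null_q = neural.permutation_null(
        frontal, temporal, icoh_stat,
        n_permutations=ns.n_permutations, seed=seed + 2,
    )
    gc = neural.spectral_granger(frontal, temporal, sfreq=src.sfreq)
    rel = {k: neural.relative_influence(v) for k, v in gc.values.items()}

    p2 = out / "source_trials.h5"
    with h5py.File(p2, "w") as f:
        f.create_dataset("frontal", data=src.frontal)
        f.create_dataset("temporal", data=src.temporal)
        f.attrs["sfreq"] = src.sfreq
        f.attrs["coupling_direction"] = spec.direction
    p3 = out / "connectivity.csv"
    pd.DataFrame({
        "freq_hz": est.freqs_hz,
        "imag_coherence": icoh,
        "icoh_null_95": null_q,
        "granger_frontal_to_temporal": gc.values["x_to_y"],
        "granger_temporal_to_frontal": gc.values["y_to_x"],
        "rel_influence_frontal_to_temporal": rel["x_to_y"],
        "rel_influence_temporal_to_frontal": rel["y_to_x"],
    }).to_csv(p3, index=False)
    state["latencies"] = lat_df
    state["connectivity_path"] = p3
    return {"latencies": p1, "sources": p2, "connectivity": p3}


def _stage_report(config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    lines = [f"priorclarity run report (package {__version__})", ""]
    fits = state.get("fits")
    if fits is None or fits.empty:
        raise ValueError("empty manifest: no fitted subjects to report")
    cols = ["subject", "group", "true_sigma_prior", "simple_sigma_prior",
            "true_threshold", "simple_threshold"]
    if "aicc_winner" in fits:
        cols += ["aicc_winner", "delta_aicc"]
    lines.append("Per-subject true vs fitted parameters and AICc preference:")
    lines.append(fits[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    gs = state.get("group_stats", {})
    if gs:
        rs = gs["sigma_prior_rank_sum"]
        lines += ["",
                  f"Prior-SD group comparison: U({rs['n1']},{rs['n2']}) = "
                  f"{rs['u_value']:.0f} (complement {rs['u_complement']:.0f}), "
                  f"two-sided p = {rs['p_two_sided']:.4f}",
                  "Mean congruency effect (match - mismatch rating): "
                  + ", ".join(f"{g} = {v:.2f}"
                              for g, v in gs["mean_congruency_effect"].items())]
    lat = state.get("latencies")
    if lat is not None:
        lines += ["", "Per-subject beta-band contrast latencies (t80, ms):"]
        lines.append(lat.to_string(index=False,
                                   float_format=lambda v: f"{v:.0f}"))
    p = out / "report.txt"
    p.write_text("\n".join(lines) + "\n")
    return {"report": p}


_STAGE_FUNCS = {
    "design": _stage_design,
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "stats": _stage_stats,
    "neural": _stage_neural,
    "report": _stage_report,
}
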