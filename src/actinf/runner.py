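"""Experiment runner: scenario presets, overrides, artifacts and figures.

This is the operational surface of the package.  ``simulate`` resolves a
named scenario (plus flat dotted-key overrides, precedence overrides >
preset > defaults), runs the selected experiment and writes all
artifacts — tidy CSVs, template/salience images, a JSON summary, a
manifest and a log — into the output directory.  ``report`` turns a
completed run directory into figure panels; ``make_stimuli`` renders the
template set; ``oracle_suite`` runs the analytic/finite-difference
oracle battery and reports pass/fail.

Every run is deterministic given its seed and scenario; re-running a
command with the same inputs reproduces byte-identical CSVs.
"""

from __future__ import annotations

import copy
import datetime as _dt
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError
from . import fixtures
from .active_inference import IntegratorConfig
from .motor import (
    ArmModel,
    MotorParams,
    ObservationMode,
    default_attractor,
    place_field_analysis,
    run_motor_simulation,
)
from .salience import IORParams, SaccadeSchedule, run_visual_search
from .visual_world import FovealSampler, SearchParams

__all__ = ["RunConfig", "simulate", "make_stimuli", "report", "oracle_suite"]

_EXPERIMENTS = ("visual-search", "handwriting", "oracle-suite")


@dataclass
class RunConfig:
    """What to run: experiment, scenario preset, seed, output dir, overrides."""

    experiment: str = "visual-search"
    scenario: str = "fig3-default"
    seed: int = 1
    output_dir: str = "outputs/run"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; valid: {list(_EXPERIMENTS)}"
            )


def _flat_keys(d: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_flat_keys(v, key + "."))
        else:
            out.append(key)
    return out


def _apply_overrides(cfg: dict, overrides: dict) -> dict:
    cfg = copy.deepcopy(cfg)
    valid = _flat_keys(cfg)
    for dotted, value in overrides.items():
        if dotted not in valid:
            raise ConfigurationError(
                f"unknown override key {dotted!r}; valid keys: {sorted(valid)}"
            )
        node = cfg
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node[p]
        if isinstance(value, str):
            value = yaml.safe_load(value)
        node[leaf] = value
    return cfg


def _log(lines: list[str], msg: str) -> None:
    lines.append(f"{_dt.datetime.now().isoformat(timespec='seconds')} {msg}")


def _write_text(path: str, text: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(text)


def _csv(df, path: str) -> None:
    with open(path, "w", newline="") as fh:
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.12g")


def _build_search_pieces(cfg: dict):
    face = fixtures.FaceSpec(**cfg.get("face", {}))
    hset = fixtures.default_hypotheses(
        face, angle=cfg.get("rotation_angle", 90.0), true_index=cfg.get("true_index", 0)
    )
    sampler = FovealSampler(**cfg.get("sampler", {}))
    schedule = SaccadeSchedule(**cfg.get("schedule", {}))
    params = SearchParams(**cfg.get("params", {}))
    integrator = IntegratorConfig(**cfg.get("integrator", {}))
    ior = IORParams(**cfg.get("ior", {}))
    return hset, sampler, schedule, params, integrator, ior


def simulate(config: RunConfig) -> dict:
    """Run an experiment and write its artifacts; returns the manifest."""
    scenario = fixtures.load_scenario(config.scenario)
    cfg = _apply_overrides(scenario, config.overrides)
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    scen_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]
    log: list[str] = []
    _log(log, f"simulate experiment={config.experiment} scenario={config.scenario} "
              f"seed={config.seed} scenario_hash={scen_hash} version=0.1.0")

    resolved = os.path.join(out, "resolved_config.yaml")
    _write_text(resolved, yaml.safe_dump(cfg, sort_keys=True))
    artifacts = [os.path.basename(resolved)]

    if config.experiment == "visual-search":
        artifacts += _simulate_search(cfg, config, out, log)
    elif config.experiment == "handwriting":
        artifacts += _simulate_motor(cfg, config, out, log)
    else:
        results = oracle_suite(seed=config.seed)
        path = os.path.join(out, "oracle_suite.json")
        _write_text(path, json.dumps(results, indent=2, sort_keys=True) + "\n")
        artifacts.append("oracle_suite.json")

    manifest = {
        "experiment": config.experiment,
        "scenario": config.scenario,
        "seed": config.seed,
        "scenario_hash": scen_hash,
        "artifacts": sorted(set(artifacts + ["log.txt", "manifest.json"])),
    }
    _write_text(os.path.join(out, "manifest.json"),
                json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _log(log, "done")
    _write_text(os.path.join(out, "log.txt"), "\n".join(log) + "\n")
    return manifest


def _simulate_search(cfg: dict, config: RunConfig, out: str, log: list[str]) -> list[str]:
    import pandas as pd

    hset, sampler, schedule, params, integrator, ior = _build_search_pieces(cfg)
    result = run_visual_search(
        hset, sampler, schedule=schedule, params=params, integrator=integrator,
        ior=ior, grid_side=cfg.get("grid_side", 17), seed=config.seed,
    )
    _log(log, f"visual search finished: {len(result.fixations)} fixations, "
              f"diverged={result.diverged}")
    arts: list[str] = []

    fix = pd.DataFrame(result.fixations, columns=["x", "y"])
    fix.insert(0, "saccade_index", np.arange(len(fix)))
    _csv(fix, os.path.join(out, "fixations.csv"))
    arts.append("fixations.csv")

    _csv(result.posteriors_frame(), os.path.join(out, "posteriors.csv"))
    arts.append("posteriors.csv")

    for j, smap in enumerate(result.salience_maps):
        grid = smap.as_grid("effective")
        lo, hi = grid.min(), grid.max()
        norm = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
        from .visual_world import TemplateImage

        img = TemplateImage(pixels=norm, label=f"salience_{j}")
        img.save_pgm(os.path.join(out, f"salience_{j:02d}.pgm"))
        img.save_png(os.path.join(out, f"salience_{j:02d}.png"))
        arts += [f"salience_{j:02d}.pgm", f"salience_{j:02d}.png"]

    arts += [os.path.basename(p) for p in
             result.trace.to_csv(os.path.join(out, "trace"))]

    summary = {
        "final_posteriors": result.hypothesis_weights[-1].tolist(),
        "true_index": result.true_index,
        "fixations": result.fixations.tolist(),
        "free_energy_first": float(result.trace.free_energies[0]),
        "free_energy_last": float(result.trace.free_energies[-1]),
        "diverged": result.diverged,
    }
    _write_text(os.path.join(out, "summary.json"),
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
    arts.append("summary.json")
    return arts


def _simulate_motor(cfg: dict, config: RunConfig, out: str, log: list[str]) -> list[str]:
    import pandas as pd

    attractor = default_attractor(**cfg.get("attractor", {}))
    arm = ArmModel(**cfg.get("arm", {}))
    params = MotorParams(**cfg.get("params", {}))
    integrator = IntegratorConfig(**cfg.get("integrator", {}))
    duration = cfg.get("duration_ms", 4000.0)

    action = run_motor_simulation(attractor, arm, ObservationMode.action(),
                                  duration, params=params, integrator=integrator,
                                  seed=config.seed)
    observation = run_motor_simulation(attractor, arm, ObservationMode.observation(),
                                       duration, params=params, integrator=integrator,
                                       seed=config.seed, replay_from=action)
    _log(log, f"motor run finished: winner sequence {action.winner_sequence()}")
    arts: list[str] = []
    for tag, res in (("action", action), ("observation", observation)):
        path = pd.DataFrame({
            "time_ms": res.trace.times,
            "x": res.endpoint_path[:, 0],
            "y": res.endpoint_path[:, 1],
            "theta1": res.joint_path[:, 0],
            "theta2": res.joint_path[:, 1],
        })
        _csv(path, os.path.join(out, f"path_{tag}.csv"))
        states = pd.DataFrame(res.activity,
                              columns=[f"state_{k}" for k in range(attractor.K)])
        states.insert(0, "time_ms", res.trace.times)
        tidy = states.melt(id_vars="time_ms", var_name="state_index",
                           value_name="activity")
        _csv(tidy, os.path.join(out, f"states_{tag}.csv"))
        arts += [f"path_{tag}.csv", f"states_{tag}.csv"]

    pf = place_field_analysis(action)
    _csv(pf.to_frame(), os.path.join(out, "place_fields.csv"))
    arts.append("place_fields.csv")

    summary = {
        "winner_sequence_action": action.winner_sequence(),
        "winner_sequence_observation": observation.winner_sequence(),
        "diverged": action.diverged or observation.diverged,
        "free_energy_first": float(action.trace.free_energies[0]),
        "free_energy_last": float(action.trace.free_energies[-1]),
    }
    _write_text(os.path.join(out, "summary.json"),
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
    arts.append("summary.json")
    return arts


def make_stimuli(output_dir: str, face: fixtures.FaceSpec | None = None,
                 angle: float = 90.0, fmt: str = "pgm") -> list[str]:
    """Render the three default templates to image files."""
    os.makedirs(output_dir, exist_ok=True)
    hset = fixtures.default_hypotheses(face, angle=angle)
    paths = []
    for t in hset.templates:
        p = os.path.join(output_dir, f"{t.label}.{fmt}")
        (t.save_pgm if fmt == "pgm" else t.save_png)(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def report(run_dir: str) -> list[str]:
    """Render figure panels from a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    manifest_path = os.path.join(run_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise ConfigurationError(f"missing artifacts in {run_dir!r}: ['manifest.json']")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    missing = [a for a in manifest["artifacts"]
               if not os.path.exists(os.path.join(run_dir, a))]
    if missing:
        raise ConfigurationError(f"missing artifacts in {run_dir!r}: {missing}")

    figs: list[str] = []

    def save(fig, name):
        p = os.path.join(run_dir, name)
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figs.append(p)

    if manifest["experiment"] == "visual-search":
        fix = pd.read_csv(os.path.join(run_dir, "fixations.csv"))
        post = pd.read_csv(os.path.join(run_dir, "posteriors.csv"))
        # 1: fixation overlay
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fix["x"], fix["y"], "-o", color="red")
        for i, (x, y) in enumerate(zip(fix["x"], fix["y"])):
            ax.annotate(str(i), (x, y))
        ax.set(xlim=(-1, 1), ylim=(-1, 1), title="fixation sequence")
        save(fig, "panel_fixations.png")
        # 2: salience sequence
        sal = sorted(a for a in manifest["artifacts"] if a.startswith("salience_")
                     and a.endswith(".png"))
        fig, axes = plt.subplots(1, max(len(sal), 1), figsize=(2 * max(len(sal), 1), 2))
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, sal):
            from PIL import Image

            ax.imshow(np.asarray(Image.open(os.path.join(run_dir, name))), cmap="hot")
            ax.set_axis_off()
        save(fig, "panel_salience.png")
        # 3: oculomotor traces
        tr = pd.read_csv(os.path.join(run_dir, "trace_expectations.csv"))
        oc = tr[tr["variable_name"].isin(["expectations_0", "expectations_1"])]
        fig, ax = plt.subplots(figsize=(6, 2.5))
        for name, grp in oc.groupby("variable_name"):
            ax.plot(grp["time_ms"], grp["value"], label=name)
        ax.set(title="oculomotor states", xlabel="time (ms)")
        ax.legend()
        save(fig, "panel_oculomotor.png")
        # 4: posterior bands
        fig, ax = plt.subplots(figsize=(6, 2.5))
        for k, grp in post.groupby("hypothesis"):
            ax.plot(grp["time_ms"], grp["expectation"], label=f"hypothesis {k}")
        true_grp = post[post["hypothesis"] == post["hypothesis"].min()]
        ax.fill_between(true_grp["time_ms"], true_grp["ci_low"], true_grp["ci_high"],
                        alpha=0.25)
        ax.set(title="posterior beliefs (90% band on hypothesis 0)",
               xlabel="time (ms)")
        ax.legend()
        save(fig, "panel_posteriors.png")
        # 5: free energy
        fe = pd.read_csv(os.path.join(run_dir, "trace_free_energy.csv"))
        fig, ax = plt.subplots(figsize=(6, 2.5))
        ax.plot(fe["time_ms"], fe["value"])
        ax.set(title="free energy", xlabel="time (ms)")
        save(fig, "panel_free_energy.png")
        # 6: sampled-content montage (sensory at fixation ends)
        fig, ax = plt.subplots(figsize=(6, 2.5))
        se = pd.read_csv(os.path.join(run_dir, "trace_sensory.csv"))
        first = se["variable_name"].unique()[0]
        grp = se[se["variable_name"] == first]
        ax.plot(grp["time_ms"], grp["value"])
        ax.set(title="central visual channel", xlabel="time (ms)")
        save(fig, "panel_sampled.png")
    elif manifest["experiment"] == "handwriting":
        for tag in ("action", "observation"):
            path = pd.read_csv(os.path.join(run_dir, f"path_{tag}.csv"))
            states = pd.read_csv(os.path.join(run_dir, f"states_{tag}.csv"))
            pf = pd.read_csv(os.path.join(run_dir, "place_fields.csv"))
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
            ax1.plot(path["x"], path["y"], color="0.6", lw=2)
            for k, grp in pf.groupby("state_index"):
                ax1.plot(grp["x"], grp["y"], ".", ms=4, label=f"state {k}")
            ax1.set(title=f"trajectory + half-max activity ({tag})")
            for k, grp in states.groupby("state_index"):
                ax2.plot(grp["time_ms"], grp["activity"], label=k)
            ax2.set(title="attractor state activity", xlabel="time (ms)")
            save(fig, f"panel_{tag}.png")
    else:
        raise ConfigurationError(f"no report defined for {manifest['experiment']!r}")
    return figs


# ---------------------------------------------------------------------------
# oracle battery
# ---------------------------------------------------------------------------

def oracle_suite(seed: int = 0, n_models: int = 50) -> dict:
    """Analytic / finite-difference oracle battery; returns pass flags.

    Covers the gradient oracle (random smooth models vs central finite
    differences), the exact-inference oracle (linear-Gaussian posterior
    mean and variance), the per-step free-energy descent property, and
    the brute-force salience argmax check.
    """
    from .oracles import (
        check_descent,
        check_gradients,
        check_linear_gaussian,
        check_salience_argmax,
    )

    return {
        "gradient_oracle": check_gradients(seed=seed, n_models=n_models),
        "exact_inference_oracle": check_linear_gaussian(seed=seed),
        "descent_property": check_descent(seed=seed),
        "salience_argmax_oracle": check_salience_argmax(),
    }
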