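"""End-to-end workflows: sample, seeded analysis, reporting.

These are the library entry points behind the command-line verbs.  A
:class:`RunConfig` pins down the whole experiment — model, task, grid of
activation-contraction limits, chain settings — and every output file is
stamped with the config hash so stores from different runs cannot be mixed
silently.  All randomness derives from one root seed by a documented rule,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .constraints import Seed, build_task_wrenches, build_trajectory_polytope, \
    add_seed_constraint
from .exceptions import ActSpaceError, FormatError, InfeasibleError, ProvenanceError
from .model import (HMatrix, SampleStore, TaskSpec, generate_synthetic_h,
                    load_samples, read_h_matrix, save_samples)
from .sampler import ChainConfig, audit_samples, hit_and_run

log = logging.getLogger("actspace")


@dataclass
class RunConfig:
    """Full experiment description for the pipeline verbs."""

    task: TaskSpec = field(default_factory=TaskSpec)
    deltas: tuple = (1.0, 0.5, 0.25, 0.12, 0.05)
    chain: ChainConfig = field(default_factory=lambda: ChainConfig(n_samples=5000))
    n_seeds: int = 10
    seed_filter_delta: float = 0.12
    clamp: bool = True
    out_dir: Path = Path("actspace-run")
    model_path: str | None = None
    synthetic: dict | None = None  # {"n_muscles":…, "n_wrench":…, "rng_seed":…}
    store_format: str = "csv"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.deltas = tuple(float(d) for d in self.deltas)
        if any(not (0.0 <= d <= 1.0) for d in self.deltas):
            raise ValueError("all deltas must lie in [0, 1]")
        if any(b >= a for a, b in zip(self.deltas, self.deltas[1:])):
            raise ValueError("delta grid must be strictly decreasing")
        if self.model_path is None and self.synthetic is None:
            raise ValueError("config needs either model_path or synthetic parameters")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        task = TaskSpec(**raw.pop("task", {}))
        chain = ChainConfig(**raw.pop("chain", {"n_samples": 5000}))
        model = raw.pop("model", None)
        if model:
            if "path" in model:
                raw["model_path"] = model["path"]
            if "synthetic" in model:
                raw["synthetic"] = model["synthetic"]
        return cls(task=task, chain=chain, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = {
            "task": asdict(self.task),
            "deltas": list(self.deltas),
            "chain": asdict(self.chain),
            "n_seeds": self.n_seeds,
            "seed_filter_delta": self.seed_filter_delta,
            "clamp": self.clamp,
            "model_path": self.model_path,
            "synthetic": self.synthetic,
        }
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def derive_seed(root: int, *parts) -> int:
    """Derive an independent sub-seed: hash(root, *parts) below 2**31."""
    blob = "|".join([str(int(root))] + [str(p) for p in parts])
    digest = hashlib.sha256(blob.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def resolve_model(config: RunConfig) -> HMatrix:
    if config.model_path is not None:
        return read_h_matrix(config.model_path)
    synth = dict(config.synthetic)
    return generate_synthetic_h(
        n_muscles=int(synth["n_muscles"]),
        n_wrench=int(synth["n_wrench"]),
        rng_seed=int(synth.get("rng_seed", derive_seed(config.chain.rng_seed, "model"))),
        task=config.task,
    )


def _store_path(config: RunConfig, name: str) -> Path:
    return config.out_dir / f"{name}.{config.store_format}"


def cmd_sample(config: RunConfig, model: HMatrix | None = None) -> dict:
    """Sample the unseeded trajectory polytope for every delta condition.

    Writes one sample store and one audit report per delta; infeasible
    conditions are recorded and skipped rather than aborting the grid.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    model = model or resolve_model(config)
    seq = build_task_wrenches(config.task, model)
    chash = config.config_hash()
    stores, skipped, audits = {}, {}, {}
    for delta in config.deltas:
        t0 = time.perf_counter()
        try:
            spec = build_trajectory_polytope(model, seq, delta)
        except InfeasibleError as exc:
            log.warning("delta=%s infeasible: %s", delta, exc)
            skipped[delta] = str(exc)
            continue
        chain = ChainConfig(
            n_samples=config.chain.n_samples, burn_in=config.chain.burn_in,
            thin=config.chain.thin,
            rng_seed=derive_seed(config.chain.rng_seed, f"{delta:.6f}", "unseeded"),
        )
        store = hit_and_run(spec, chain, extra_meta={
            "delta": delta, "stage": "unseeded", "config_hash": chash,
            "task_hash": config.task.task_hash(),
        })
        audit = audit_samples(spec, store.samples)
        path = _store_path(config, f"unseeded_delta_{delta:g}")
        save_samples(store, path)
        audits[delta] = audit
        (config.out_dir / f"audit_delta_{delta:g}.json").write_text(
            json.dumps(audit, indent=2)
        )
        stores[delta] = path
        log.info("delta=%s: %d samples in %.1fs (audit pass=%s)",
                 delta, store.n_samples, time.perf_counter() - t0,
                 audit["all_pass"])
    return {"stores": stores, "skipped": skipped, "audits": audits,
            "config_hash": chash}


def cmd_seeded(config: RunConfig, unseeded_store_path,
               model: HMatrix | None = None) -> dict:
    """Run the seeded protocol against one unseeded store.

    Filters the unseeded trajectories by the seed-filter rate limit,
    selects seeds at random, samples the seeded (and, if configured,
    clamped) polytopes, projects every slice through the unseeded
    principal components, and reports per-seed hull-area ratios.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    store = load_samples(unseeded_store_path)
    chash = config.config_hash()
    if store.meta.get("config_hash") != chash:
        raise ProvenanceError(
            f"unseeded store {unseeded_store_path} was produced under config "
            f"{store.meta.get('config_hash')!r}, not {chash!r}"
        )
    delta = float(store.meta["delta"])
    model = model or resolve_model(config)
    seq = build_task_wrenches(config.task, model)
    unseeded_ts = analysis.reshape_to_trajectories(store)
    filtered = analysis.filter_by_delta(unseeded_ts, config.seed_filter_delta)
    if filtered.n_traj == 0:
        raise ActSpaceError(
            f"no trajectories met the seed filter delta="
            f"{config.seed_filter_delta}; increase the filter delta or sample "
            "more trajectories"
        )
    k = min(config.n_seeds, filtered.n_traj)
    if k < config.n_seeds:
        log.warning("only %d trajectories passed the filter; using %d seeds",
                    filtered.n_traj, k)
    seeds = analysis.select_seeds(
        filtered, k, derive_seed(config.chain.rng_seed, "seeds")
    )
    models = analysis.fit_pc_per_timestep(unseeded_ts)
    spec = build_trajectory_polytope(model, seq, delta)

    reports = []
    store_paths = {"seeded": [], "clamped": []}
    variants = [("seeded", False)] + ([("clamped", True)] if config.clamp else [])
    for s_id, seed in enumerate(seeds):
        for stage, clamp in variants:
            sspec = add_seed_constraint(spec, Seed(seed.activation, clamp=clamp))
            chain = ChainConfig(
                n_samples=config.chain.n_samples, burn_in=config.chain.burn_in,
                thin=config.chain.thin,
                rng_seed=derive_seed(config.chain.rng_seed, f"{delta:.6f}",
                                     stage, s_id),
            )
            sstore = hit_and_run(sspec, chain, extra_meta={
                "delta": delta, "stage": stage, "seed_id": s_id,
                "config_hash": chash, "task_hash": config.task.task_hash(),
                "seed_activation": [float(v) for v in seed.activation],
            })
            path = _store_path(config, f"{stage}_delta_{delta:g}_seed{s_id}")
            save_samples(sstore, path)
            store_paths[stage].append(path)
            seeded_ts = analysis.reshape_to_trajectories(sstore)
            rep = analysis.hull_area_report(seeded_ts, unseeded_ts, models,
                                            seed_id=s_id)
            rep.insert(0, "stage", stage)
            reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    report_path = config.out_dir / f"hull_area_report_delta_{delta:g}.csv"
    report.to_csv(report_path, index=False)
    t1 = report[(report["t"] == 1) & (report["stage"] == "seeded")]
    mean_ratio_t1 = float(t1["ratio"].mean())
    log.info("mean seeded/unseeded hull-area ratio at t=1: %.4f", mean_ratio_t1)
    return {
        "report": report, "report_path": report_path,
        "mean_ratio_t1": mean_ratio_t1, "seeds": seeds,
        "store_paths": store_paths, "config_hash": chash,
    }


def cmd_report(store_paths, out_dir) -> dict:
    """Summarise stores into speed/occupancy tables and PC-plane figures.

    All stores must carry the same config hash; a mismatch is refused with
    the differing hashes listed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stores = [load_samples(p) for p in store_paths]
    if not stores:
        raise ActSpaceError("no stores given to report on")
    hashes = {s.meta.get("config_hash") for s in stores}
    if len(hashes) > 1:
        raise ProvenanceError(
            f"stores mix different configurations: {sorted(map(str, hashes))}"
        )
    if any(s.n_samples == 0 for s in stores):
        raise ActSpaceError("a store is empty; nothing to report")

    speed_blocks = []
    occ_blocks = []
    for store in stores:
        ts = analysis.reshape_to_trajectories(store)
        occ = analysis.occupancy_summary(ts).reset_index()
        occ.insert(0, "delta", store.meta.get("delta"))
        occ.insert(1, "stage", store.meta.get("stage", "unseeded"))
        occ_blocks.append(occ)
        speeds = analysis.differentiate(ts)
        maxima = analysis.max_abs_speed(speeds)
        blk = pd.DataFrame(maxima, columns=list(ts.muscle_names))
        blk.insert(0, "delta", store.meta.get("delta"))
        blk.insert(1, "stage", store.meta.get("stage", "unseeded"))
        speed_blocks.append(blk)
    occ_path = out_dir / "occupancy_summary.csv"
    pd.concat(occ_blocks, ignore_index=True).to_csv(occ_path, index=False)
    speed_path = out_dir / "max_abs_speeds.csv"
    pd.concat(speed_blocks, ignore_index=True).to_csv(speed_path, index=False)

    fig_path = _pc_figure(stores, out_dir)
    return {"occupancy": occ_path, "speeds": speed_path, "figure": fig_path}


def _pc_figure(stores, out_dir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    unseeded = [s for s in stores if s.meta.get("stage", "unseeded") == "unseeded"]
    if not unseeded:
        return None
    base = analysis.reshape_to_trajectories(unseeded[0])
    if base.n_traj < base.n_muscles + 1:
        return None
    models = analysis.fit_pc_per_timestep(base)
    T = base.n_steps
    fig, axes = plt.subplots(1, T, figsize=(2.2 * T, 2.4), sharex=True, sharey=True)
    axes = np.atleast_1d(axes)
    for t, ax in enumerate(axes):
        pts = analysis.project(base, models, t)
        ax.scatter(pts[:, 0], pts[:, 1], s=2, alpha=0.25, color="steelblue",
                   label="unseeded")
        try:
            from scipy.spatial import ConvexHull
            hull = ConvexHull(pts)
            loop = np.append(hull.vertices, hull.vertices[0])
            ax.plot(pts[loop, 0], pts[loop, 1], color="navy", lw=0.8)
        except Exception:  # degenerate slice: skip the overlay
            pass
        for s in stores:
            if s.meta.get("stage") in ("seeded", "clamped"):
                sp = analysis.project(analysis.reshape_to_trajectories(s), models, t)
                ax.scatter(sp[:, 0], sp[:, 1], s=2, alpha=0.4, color="firebrick")
        ax.set_title(f"t={t}", fontsize=8)
    fig.suptitle("Feasible activations per time slice (unseeded PC plane)")
    fig.tight_layout()
    path = out_dir / "pc_plane.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
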