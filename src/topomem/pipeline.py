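"""End-to-end orchestration: simulate, fit, score, test, report.

A single YAML/dict configuration drives all stages in dependency order:

1. ``stimulus`` — render the sweeping-bar aperture movie;
2. ``bold`` — simulate voxels from the CSS forward model and fit them;
3. ``cohort`` — simulate the memory-guided-saccade experiment;
4. ``scoring`` — score every trial (saccade detection, errors, exclusions);
5. ``stats`` — seven-group collapse checks, omnibus and post-hoc tests.

Each run writes its outputs plus a manifest (``manifest.json``) listing
every file with a content hash, per-stage timing and status, making runs
reproducible and diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

log = logging.getLogger("topomem")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "topomem_out",
    "log_level": "INFO",
    "stimulus": {
        "extent_deg": 10.0,
        "n_pix": 48,
        "widths": [1.0, 2.0, 3.0],
        "n_steps": 16,
        "blank_frames": 4,
        "tr_s": 2.0,
    },
    "bold": {
        "enabled": True,
        "n_voxels": 20,
        "snr": 5.0,
        "ve_threshold": 0.1,
    },
    "cohort": {
        "enabled": True,
        "n_subjects": 3,
        "n_runs": 1,
        "trials_per_run": 30,
        "effects": {},  # e.g. {"sPCS,contra,mgs": 2.0}
        "exclusion_rate": 0.05,
    },
    "scoring": {
        "saccade_threshold": 30.0,
        "min_primary_amp": 2.0,
        "fep_window_ms": 100.0,
    },
    "stats": {
        "alpha": 0.05,
    },
}


def _validate(cfg: dict, template: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in template:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if isinstance(template[key], dict) and key != "effects":
            if not isinstance(val, dict):
                raise ValueError(f"configuration section {path + key!r} must be a mapping")
            _validate(val, template[key], path + key + ".")


def load_config(source: str | dict | None = None) -> dict:
    """Merge a YAML file or dict over the defaults, rejecting unknown keys."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, str):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    _validate(source, DEFAULT_CONFIG)
    for key, val in source.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict) and key != "effects":
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_effects(raw: dict) -> dict:
    out = {}
    for key, val in (raw or {}).items():
        if isinstance(key, str):
            site, lat, metric = key.split(",")
            out[(site, lat, metric)] = float(val)
        else:
            out[tuple(key)] = float(val)
    return out


def run_pipeline(config: str | dict | None = None, seed: int | None = None,
                 out_dir: str | None = None) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    from . import __version__, io, oculo, prf, stats, stimulus, synth

    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = out_dir
    os.makedirs(cfg["out_dir"], exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg["log_level"].upper(), logging.INFO))

    manifest: dict = {"version": __version__, "seed": cfg["seed"],
                      "config": cfg, "stages": {}, "outputs": {}}
    rng = np.random.default_rng(cfg["seed"])

    def out_path(name: str) -> str:
        return os.path.join(cfg["out_dir"], name)

    def record(name: str) -> None:
        manifest["outputs"][name] = _sha256(out_path(name))

    def stage(name: str):
        def decorator(fn):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                            "seconds": round(time.time() - t0, 3)}
                _write_manifest(manifest, out_path("manifest.json"))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.time() - t0, 3)}
            log.info("stage %s: ok", name)
        return decorator

    state: dict = {}

    @stage("stimulus")
    def _stimulus():
        sc = cfg["stimulus"]
        grid = stimulus.make_grid(sc["extent_deg"], sc["n_pix"])
        parts = [stimulus.default_mapping_movie(
            grid, width_deg=w, tr_s=sc["tr_s"], n_steps=sc["n_steps"],
            blank_frames=sc["blank_frames"]) for w in sc["widths"]]
        movie = stimulus.concat_movies(parts)
        stimulus.save_movie(movie, out_path("apertures.npz"))
        record("apertures.npz")
        state["grid"], state["movie"] = grid, movie

    if cfg["bold"]["enabled"]:
        @stage("bold")
        def _bold():
            bc = cfg["bold"]
            sim = synth.BoldSimConfig(snr=bc["snr"], tr_s=cfg["stimulus"]["tr_s"],
                                      seed=int(rng.integers(2 ** 31)))
            Y, truth = synth.simulate_voxels(sim, state["movie"], bc["n_voxels"])
            io.write_voxels_npz(out_path("bold.npz"), Y, sim.tr_s)
            record("bold.npz")
            fits = prf.fit_many(Y, state["movie"])
            io.write_fits_csv(fits, out_path("prf_fits.csv"))
            record("prf_fits.csv")
            cov = prf.coverage_map(fits, state["grid"], bc["ve_threshold"])
            np.savez_compressed(out_path("coverage.npz"), density=cov.density)
            record("coverage.npz")
            state["fits"] = fits

    if cfg["cohort"]["enabled"]:
        @stage("cohort")
        def _cohort():
            cc = cfg["cohort"]
            spec = synth.CohortSpec(
                n_subjects=cc["n_subjects"], n_runs=cc["n_runs"],
                trials_per_run=cc["trials_per_run"],
                effects=_parse_effects(cc["effects"]),
                exclusion_rate=cc["exclusion_rate"],
                seed=int(rng.integers(2 ** 31)))
            traces, truth = synth.simulate_cohort(spec)
            truth.to_csv(out_path("cohort_truth.csv"), index=False)
            record("cohort_truth.csv")
            state["traces"] = traces

        @stage("scoring")
        def _scoring():
            sc = cfg["scoring"]
            score_cfg = oculo.ScoreConfig(
                saccade_threshold=sc["saccade_threshold"],
                min_primary_amp=sc["min_primary_amp"],
                fep_window_ms=sc["fep_window_ms"])
            scores = oculo.score_session(state["traces"], score_cfg)
            frame = oculo.scores_to_frame(scores)
            frame.to_csv(out_path("scores.csv"), index=False)
            record("scores.csv")
            state["scores"] = frame

        @stage("stats")
        def _stats():
            alpha = cfg["stats"]["alpha"]
            labeled = stats.assign_laterality(state["scores"])
            collapse = stats.collapse_checks(labeled, alpha=alpha)
            reports = stats.run_group_tests(labeled, alpha=alpha)
            deltas = stats.per_subject_delta(labeled)
            deltas.to_csv(out_path("subject_deltas.csv"), index=False)
            record("subject_deltas.csv")
            payload = {
                "collapse": {"lr_p": collapse.lr_p,
                             "collapse_lr": collapse.collapse_lr,
                             "delay_p_min": (min(collapse.delay_pvalues.values())
                                             if collapse.delay_pvalues else None),
                             "collapse_delays": collapse.collapse_delays},
                "tests": {m: r.to_dict() for m, r in reports.items()},
            }
            with open(out_path("report.json"), "w") as fh:
                json.dump(payload, fh, indent=2)
            record("report.json")
            with open(out_path("report.txt"), "w") as fh:
                fh.write(stats.report_text(reports) + "\n")
            record("report.txt")

    _write_manifest(manifest, out_path("manifest.json"))
    return manifest


def _write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
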