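"""Staged end-to-end workflow over on-disk artifacts.

Each stage consumes the previous stage's manifest and writes its own (JSON
beside CSV artifacts), so every product on disk carries the config hash and
seeds needed to regenerate it exactly. Stages:

    simulate   -> cohorts/<name>/           synthetic cohorts + ground truth
    window     -> windows/<name>.csv        accepted window manifests
    granger    -> granger/<name>_frequencies.csv
    dynotears  -> dynotears/<name>_frequencies.csv
    aggregate  -> aggregate/<name>_<method>_{heatmap,consensus}.csv
    associate  -> associate/findings_<method>.csv

The first cohort is the validation set (candidate screening); the remaining
cohorts are test sets used only for confirmation.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import dynotears as dyn_mod
from . import granger as gc_mod
from . import synthetic, windowing
from .config import PipelineConfig
from .exceptions import ConfigError, MissingManifestError

log = logging.getLogger("psgcausal")

STAGES = ("simulate", "window", "granger", "dynotears", "aggregate", "associate")


def _derive_seed(master: int, *key: int) -> int:
    """Counter-keyed child seed (stable under cohort/subject count changes)."""
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0]
               % (2 ** 31))


def _stage_up_to_date(directory: Path, stage: str, cfg: PipelineConfig) -> dict | None:
    """Return the existing manifest if this stage already ran with this config."""
    path = directory / "manifest.json"
    if not path.exists():
        return None
    with open(path) as fh:
        payload = json.load(fh)
    if (payload.get("stage") == stage
            and payload.get("config_hash") == cfg.config_hash()):
        log.info("%s: up to date (config %s), skipping", stage, cfg.config_hash())
        return payload
    return None


def _write_manifest(directory: Path, payload: dict) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _read_manifest(directory: Path, needed_by: str, produced_by: str) -> dict:
    path = directory / "manifest.json"
    if not path.exists():
        raise MissingManifestError(
            f"stage '{needed_by}' requires {path}, produced by the "
            f"'{produced_by}' stage — run that stage first")
    with open(path) as fh:
        return json.load(fh)


def _planted_covariate(cfg: PipelineConfig, channel_names: list[str]
                       ) -> synthetic.CovariateSpec:
    if "ECG" in channel_names and "EEG_LO" in channel_names:
        return synthetic.default_waist_covariate(channel_names)
    # generic roster: plant the waist-girth analogue on ch1 -> ch0, lag 1
    spec = synthetic.default_waist_covariate()
    return synthetic.CovariateSpec(
        name=spec.name, distribution=spec.distribution,
        target_edge=(1, 0, 1), effect=spec.effect)


def stage_simulate(cfg: PipelineConfig, out_dir: str | Path,
                   force: bool = False) -> dict:
    out_dir = Path(out_dir)
    cached = None if force else _stage_up_to_date(out_dir / "cohorts", "simulate", cfg)
    if cached is not None:
        return cached
    d = cfg.channels
    names = (synthetic.DEFAULT_CHANNELS if d == len(synthetic.DEFAULT_CHANNELS)
             else [f"ch{i}" for i in range(d)])
    model = synthetic.make_ground_truth(
        d=d, p=cfg.true_order, lag_density=cfg.lag_density,
        contemp_density=cfg.contemp_density,
        target_spectral_radius=cfg.target_spectral_radius,
        seed=_derive_seed(cfg.seed, 0))
    covariate = _planted_covariate(cfg, names)
    src, tgt, lag = covariate.target_edge
    model = synthetic.set_edge_weight(model, src, tgt, lag,
                                      cfg.planted_edge_weight)
    cohorts = {}
    for j, cname in enumerate(cfg.cohorts):
        cohort_seed = _derive_seed(cfg.seed, 1, j)
        recs, table = synthetic.make_cohort(
            cfg.n_subjects, model, covariate, cfg.n_seconds,
            seed=cohort_seed, rate_hz=cfg.rate_hz, channel_names=names)
        cdir = out_dir / "cohorts" / cname
        synthetic.write_cohort(recs, cdir, fmt="npz", ground_truth=model,
                               covariate_table=table,
                               extra_manifest={"cohort_seed": cohort_seed,
                                               "config_hash": cfg.config_hash()})
        cohorts[cname] = str(cdir.relative_to(out_dir))
        log.info("simulate: cohort %s — %d subjects, %.0f s each",
                 cname, len(recs), cfg.n_seconds)
    payload = {"stage": "simulate", "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "cohorts": cohorts,
               "planted_edge": {"source": src, "target": tgt, "lag": lag,
                                "weight": cfg.planted_edge_weight,
                                "covariate": covariate.name}}
    _write_manifest(out_dir / "cohorts", payload)
    cfg.to_json(out_dir / "config.json")
    return payload


def _load_cohorts(cfg: PipelineConfig, out_dir: Path, needed_by: str):
    manifest = _read_manifest(out_dir / "cohorts", needed_by, "simulate")
    out = {}
    for cname, rel in manifest["cohorts"].items():
        recs, table, _ = synthetic.read_cohort(out_dir / rel)
        out[cname] = (recs, table)
    return out, manifest


def stage_window(cfg: PipelineConfig, out_dir: str | Path,
                 force: bool = False) -> dict:
    out_dir = Path(out_dir)
    cached = None if force else _stage_up_to_date(out_dir / "windows", "window", cfg)
    if cached is not None:
        return cached
    cohorts, _ = _load_cohorts(cfg, out_dir, "window")
    wdir = out_dir / "windows"
    wdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for j, (cname, (recs, _table)) in enumerate(cohorts.items()):
        frames = []
        accepted = rejected = 0
        for i, rec in enumerate(recs):
            rec = windowing.resample_to_common_rate(rec, cfg.rate_hz)
            ws = windowing.select_windows(
                rec, window_s=cfg.window_s, grid_s=cfg.grid_s,
                quota=cfg.quota, seed=_derive_seed(cfg.seed, 2, j, i),
                max_order=cfg.max_order)
            accepted += len(ws)
            rejected += ws.rejected_count
            frames.append(ws.to_manifest())
        df = pd.concat(frames, ignore_index=True)
        fname = f"{cname}.csv"
        df.to_csv(wdir / fname, index=False)
        files[cname] = fname
        log.info("window: cohort %s — %d accepted, %d rejected",
                 cname, accepted, rejected)
    payload = {"stage": "window", "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "files": files, "quota": cfg.quota}
    _write_manifest(wdir, payload)
    return payload


def _iter_subject_windows(cfg, rec, wdf, zscore: bool):
    """Yield standardized Window objects for one recording, per manifest."""
    rows = wdf[(wdf["recording_id"] == rec.subject_id) & wdf["accepted"]]
    L = int(round(cfg.window_s * cfg.rate_hz))
    for _, row in rows.iterrows():
        start = int(row["start_sample"])
        raw = windowing.Window(
            recording_id=rec.subject_id, start_sample=start,
            data=rec.data[:, start:start + L], rate_hz=cfg.rate_hz,
            channel_names=rec.channel_names)
        win = windowing.standardize(raw, "zscored" if zscore else "centered")
        win.order = int(row["order"])
        yield win


def stage_granger(cfg: PipelineConfig, out_dir: str | Path,
                  force: bool = False) -> dict:
    out_dir = Path(out_dir)
    cached = None if force else _stage_up_to_date(out_dir / "granger", "granger", cfg)
    if cached is not None:
        return cached
    cohorts, _ = _load_cohorts(cfg, out_dir, "granger")
    wmanifest = _read_manifest(out_dir / "windows", "granger", "window")
    gdir = out_dir / "granger"
    gdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for cname, (recs, _table) in cohorts.items():
        wdf = pd.read_csv(out_dir / "windows" / wmanifest["files"][cname])
        per_subject = {}
        for rec in recs:
            rec = windowing.resample_to_common_rate(rec, cfg.rate_hz)
            results = []
            for win in _iter_subject_windows(cfg, rec, wdf, zscore=False):
                res = gc_mod.pairwise_conditional_gc(
                    win.data.T, win.order, alpha=cfg.alpha,
                    channel_names=win.channel_names,
                    adjust=(cfg.by_scope == "window"))
                results.append(res)
            if cfg.by_scope == "cohort":
                pass  # pooled below, across the whole cohort
            per_subject[rec.subject_id] = results
        if cfg.by_scope == "cohort":
            flat = [r for rs in per_subject.values() for r in rs]
            pooled = gc_mod.pool_by_across_windows(flat, alpha=cfg.alpha)
            it = iter(pooled)
            per_subject = {sid: [next(it) for _ in rs]
                           for sid, rs in per_subject.items()}
        adjac = {sid: [r.adjacency for r in rs]
                 for sid, rs in per_subject.items()}
        freqs = cohort_mod.link_frequencies(adjac, cfg.quota, method="granger")
        names = recs[0].channel_names
        fname = f"{cname}_frequencies.csv"
        cohort_mod.frequencies_to_frame(freqs, names).to_csv(
            gdir / fname, index=False)
        files[cname] = fname
        n_links = int(np.sum([f.counts for f in freqs]))
        log.info("granger: cohort %s — %d link identifications over %d windows",
                 cname, n_links, sum(f.quota for f in freqs))
    payload = {"stage": "granger", "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "files": files, "alpha": cfg.alpha,
               "by_scope": cfg.by_scope}
    _write_manifest(gdir, payload)
    return payload


def stage_dynotears(cfg: PipelineConfig, out_dir: str | Path,
                    order: int | None = None, force: bool = False) -> dict:
    """Per-window DBN fits, thresholded at cfg.tau and lag-collapsed.

    ``order=None`` uses each window's AICc-selected VAR order (shared-order
    mode, the tractable default for whole-cohort runs); pass an integer to
    fix it, or use :func:`dynotears.select_order_dbn` for independent
    selection on individual windows.
    """
    out_dir = Path(out_dir)
    cached = None if force else _stage_up_to_date(out_dir / "dynotears", "dynotears", cfg)
    if cached is not None:
        return cached
    cohorts, _ = _load_cohorts(cfg, out_dir, "dynotears")
    wmanifest = _read_manifest(out_dir / "windows", "dynotears", "window")
    ddir = out_dir / "dynotears"
    ddir.mkdir(parents=True, exist_ok=True)
    files = {}
    for cname, (recs, _table) in cohorts.items():
        wdf = pd.read_csv(out_dir / "windows" / wmanifest["files"][cname])
        adjac = {}
        for rec in recs:
            rec = windowing.resample_to_common_rate(rec, cfg.rate_hz)
            mats = []
            for win in _iter_subject_windows(cfg, rec, wdf, zscore=True):
                p = order if order is not None else win.order
                res = dyn_mod.fit_dynotears(
                    win.data.T, p, lambda_w=cfg.lambda_w,
                    lambda_a=cfg.lambda_a,
                    channel_names=win.channel_names)
                summary = dyn_mod.threshold_and_collapse(res, cfg.tau)
                mats.append(summary.collapsed)
            adjac[rec.subject_id] = mats
        freqs = cohort_mod.link_frequencies(adjac, cfg.quota, method="dynotears")
        names = recs[0].channel_names
        fname = f"{cname}_frequencies.csv"
        cohort_mod.frequencies_to_frame(freqs, names).to_csv(
            ddir / fname, index=False)
        files[cname] = fname
        log.info("dynotears: cohort %s done", cname)
    payload = {"stage": "dynotears", "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "files": files, "tau": cfg.tau,
               "lambda_w": cfg.lambda_w, "lambda_a": cfg.lambda_a}
    _write_manifest(ddir, payload)
    return payload


def _frequencies_from_csv(path: Path, quota: int, method: str):
    df = pd.read_csv(path)
    d = int(max(df["source_idx"].max(), df["target_idx"].max())) + 1
    freqs = []
    for sid, sub in df.groupby("subject_id", sort=True):
        counts = np.zeros((d, d), dtype=int)
        counts[sub["target_idx"], sub["source_idx"]] = sub["count"]
        freqs.append(cohort_mod.SubjectLinkFrequency(
            subject_id=sid, counts=counts, quota=quota, method=method))
    names_map = dict(zip(df["source_idx"], df["source"]))
    names = [names_map.get(i, f"ch{i}") for i in range(d)]
    return freqs, names


def _available_methods(out_dir: Path) -> list[str]:
    return [m for m in ("granger", "dynotears")
            if (out_dir / m / "manifest.json").exists()]


def stage_aggregate(cfg: PipelineConfig, out_dir: str | Path,
                    force: bool = False) -> dict:
    out_dir = Path(out_dir)
    cached = None if force else _stage_up_to_date(out_dir / "aggregate", "aggregate", cfg)
    if cached is not None:
        return cached
    adir = out_dir / "aggregate"
    adir.mkdir(parents=True, exist_ok=True)
    methods = _available_methods(out_dir)
    if not methods:
        raise MissingManifestError(
            "stage 'aggregate' requires granger/ or dynotears/ results — run "
            "the 'granger' (or 'dynotears') stage first")
    files = {}
    for method in methods:
        manifest = _read_manifest(out_dir / method, "aggregate", method)
        for cname, fname in manifest["files"].items():
            freqs, names = _frequencies_from_csv(out_dir / method / fname,
                                                 cfg.quota, method)
            result = cohort_mod.cohort_heatmap_and_consensus(
                freqs, cfg.consensus_threshold, channel_names=names)
            heat = pd.DataFrame(result.heatmap, index=names, columns=names)
            heat.to_csv(adir / f"{cname}_{method}_heatmap.csv")
            edges = [{"source": names[y], "target": names[x]}
                     for x, y in zip(*np.nonzero(result.consensus))]
            pd.DataFrame(edges, columns=["source", "target"]).to_csv(
                adir / f"{cname}_{method}_consensus.csv", index=False)
            files[f"{cname}_{method}"] = {
                "heatmap": f"{cname}_{method}_heatmap.csv",
                "consensus": f"{cname}_{method}_consensus.csv"}
            log.info("aggregate: %s/%s — %d consensus links",
                     cname, method, int(result.consensus.sum()))
    payload = {"stage": "aggregate", "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "files": files,
               "consensus_threshold": cfg.consensus_threshold}
    _write_manifest(adir, payload)
    return payload


def stage_associate(cfg: PipelineConfig, out_dir: str | Path,
                    force: bool = False) -> dict:
    out_dir = Path(out_dir)
    cached = None if force else _stage_up_to_date(out_dir / "associate", "associate", cfg)
    if cached is not None:
        return cached
    cohorts, _ = _load_cohorts(cfg, out_dir, "associate")
    sdir = out_dir / "associate"
    sdir.mkdir(parents=True, exist_ok=True)
    methods = _available_methods(out_dir)
    if not methods:
        raise MissingManifestError(
            "stage 'associate' requires granger/ or dynotears/ results — run "
            "those stages first")
    validation = cfg.cohorts[0]
    test_names = list(cfg.cohorts[1:])
    files = {}
    for method in methods:
        manifest = _read_manifest(out_dir / method, "associate", method)
        val_freqs, names = _frequencies_from_csv(
            out_dir / method / manifest["files"][validation], cfg.quota, method)
        val_table = cohorts[validation][1]
        numeric = [c for c in val_table.columns
                   if c != "subject_id"
                   and pd.api.types.is_numeric_dtype(val_table[c])]
        candidates = cohort_mod.covariate_screen(
            val_freqs, val_table, covariates=numeric, alpha=cfg.alpha)
        test_freqs = {}
        test_tables = {}
        for tname in test_names:
            test_freqs[tname], _ = _frequencies_from_csv(
                out_dir / method / manifest["files"][tname], cfg.quota, method)
            test_tables[tname] = cohorts[tname][1]
        findings = cohort_mod.confirm_associations(
            candidates, test_freqs, test_tables, alpha=cfg.alpha)
        fname = f"findings_{method}.csv"
        cohort_mod.findings_to_frame(findings, names).to_csv(
            sdir / fname, index=False)
        files[method] = fname
        n_conf = sum(f.confirmed for f in findings)
        log.info("associate: %s — %d candidates, %d confirmed",
                 method, len(findings), n_conf)
    payload = {"stage": "associate", "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "files": files, "validation": validation,
               "test_cohorts": test_names, "alpha": cfg.alpha}
    _write_manifest(sdir, payload)
    return payload


def run_all(cfg: PipelineConfig, out_dir: str | Path,
            dynotears_order: int | None = None, force: bool = False) -> dict:
    out_dir = Path(out_dir)
    stage_simulate(cfg, out_dir, force=force)
    stage_window(cfg, out_dir, force=force)
    stage_granger(cfg, out_dir, force=force)
    stage_dynotears(cfg, out_dir, order=dynotears_order, force=force)
    stage_aggregate(cfg, out_dir, force=force)
    return stage_associate(cfg, out_dir, force=force)
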