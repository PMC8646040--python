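"""End-to-end run orchestration: design → sweep → statistics → disk.

Canonical outputs of :func:`run_pipeline` in the output directory:

* ``curves.csv``         — tidy per-replicate steady-state values
  (condition, cv, train, xi_seed, frequency_hz, mean_w, mean_ca_uM)
* ``per_replicate.csv``  — per-replicate thresholds, areas, ratios
* ``summary.json``       — condition-level statistics, pairwise test
  tables, resolved configuration
* ``manifest.json``      — resolved config, seed table, package
  version, SHA-256 checksums of the canonical outputs; sufficient to
  re-run the pipeline bit-identically
* ``fig_*.png``          — convenience figures (optional)
* ``traces/``            — full traces per replicate (optional, large)

Everything stochastic derives from ``design.base_seed``; re-running the
same configuration reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import FDPCurve, analyze_sweep, sweep
from .config import RunConfig, save_config
from .drive import build_design, regular_train
from .errors import ConfigurationError
from .simulator import save_trace, simulate

__all__ = ["run_pipeline", "write_curves", "read_curves", "summarize", "sha256_file"]

logger = logging.getLogger(__name__)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_curves(curves: dict, path) -> None:
    """Concatenate all conditions into one tidy CSV."""
    frames = [curves[cv].to_frame() for cv in sorted(curves)]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_curves(path) -> dict:
    """Rebuild ``{cv: FDPCurve}`` from a curves.csv written by write_curves."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cv", "train", "xi_seed", "frequency_hz", "mean_w", "mean_ca_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"curves file lacks column(s): {', '.join(sorted(missing))}")
    curves = {}
    for cv, group in df.groupby("cv"):
        freqs = np.sort(group["frequency_hz"].unique())
        keys = sorted({(cv, int(t), int(x)) for t, x in zip(group["train"], group["xi_seed"])},
                      key=lambda k: (k[1], k[2]))
        w = np.empty((len(keys), freqs.size))
        ca = np.empty_like(w)
        for r, (cvk, t, x) in enumerate(keys):
            sub = group[(group["train"] == t) & (group["xi_seed"] == x)]
            sub = sub.set_index("frequency_hz").loc[freqs]
            w[r] = sub["mean_w"].to_numpy()
            ca[r] = sub["mean_ca_uM"].to_numpy()
        curves[float(cv)] = FDPCurve(cv=float(cv), frequencies=freqs, w=w, ca=ca,
                                     replicate_keys=keys)
    return curves


def summarize(curves: dict, config: RunConfig) -> dict:
    """Run the statistics stage and return the JSON-ready summary dict."""
    a = config.analysis
    result = analyze_sweep(
        curves, plateau_tol=a.plateau_tol, area_mode=a.area_mode,
        test=a.test, correction=a.correction, alpha=a.alpha,
        permutation_resamples=a.permutation_resamples,
        seed=config.design.base_seed,
    )
    comparisons = {}
    for metric, comp in result["comparisons"].items():
        comparisons[metric] = None if comp is None else {
            "test": comp.test, "correction": comp.correction,
            "alpha": comp.alpha,
            "pairs": comp.table.to_dict(orient="records"),
        }
    summary = {
        "conditions": {
            curves[cv].label: (None if result["conditions"][cv] is None
                               else result["conditions"][cv].to_dict())
            for cv in sorted(curves)
        },
        "comparisons": comparisons,
        "config": config.to_dict(),
    }
    return {"summary": _jsonable(summary), "per_replicate": result["per_replicate"]}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the whole protocol and write all outputs.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage = "design"
    try:
        t0 = time.perf_counter()
        drives = build_design(config.design, config.simulation.duration)
        seed_table = {
            f"cv{k[0]:g}_train{k[1]}_xi{k[2]}": {
                "seed_train": d.seed_train, "seed_xi": d.seed_xi,
                "n_events": len(d.train),
            } for k, d in sorted(drives.items())
        }
        timings[stage] = time.perf_counter() - t0
        logger.info("design: %d drives in %.2f s", len(drives), timings[stage])

        stage = "sweep"
        t0 = time.perf_counter()
        curves = sweep(config.params, config.simulation, config.design,
                       config.frequencies)
        timings[stage] = time.perf_counter() - t0
        logger.info("sweep: %d conditions x %d replicates x %d frequencies in %.1f s",
                    len(curves), config.design.n_replicates,
                    len(config.frequencies), timings[stage])

        stage = "analyze"
        t0 = time.perf_counter()
        summary = summarize(curves, config)
        timings[stage] = time.perf_counter() - t0

        stage = "write"
        t0 = time.perf_counter()
        write_curves(curves, out / "curves.csv")
        summary["per_replicate"].to_csv(out / "per_replicate.csv", index=False,
                                        float_format="%.17g")
        (out / "summary.json").write_text(
            json.dumps(summary["summary"], indent=2) + "\n"
        )
        save_config(config, out / "config.yaml")
        if config.output.save_traces:
            tdir = out / "traces"
            tdir.mkdir(exist_ok=True)
            for key, drive in sorted(drives.items()):
                for f in config.frequencies:
                    tr = simulate(config.params, config.simulation,
                                  regular_train(f, config.simulation.duration), drive)
                    save_trace(tr, tdir / f"trace_cv{key[0]:g}_t{key[1]}_x{key[2]}_{f:g}Hz.csv")
        figures = []
        if config.output.figures:
            from . import plotting
            plotting.plot_fdp_curves(curves, "ca", path=out / "fig_ca_vs_frequency.png")
            plotting.plot_fdp_curves(curves, "w", path=out / "fig_w_vs_frequency.png")
            if len(curves) > 1:
                res = summary["summary"]["conditions"]
                from .analysis import PlasticityAreas
                conds = {
                    d["cv"]: PlasticityAreas(
                        cv=d["cv"], f0=d["f0_hz"], f_plus=d["f_plus_hz"],
                        ltd_area=d["ltd_area"], ltp_area=d["ltp_area"],
                        ca_at_f0=d["ca_at_f0_uM"],
                        ltd_area_ratio=d["ltd_area_ratio_pct"],
                        ltp_area_ratio=d["ltp_area_ratio_pct"],
                    ) for d in res.values() if d is not None
                }
                if conds:
                    plotting.plot_area_stats(conds, summary["per_replicate"],
                                             path=out / "fig_area_stats.png")
            figures = sorted(p.name for p in out.glob("fig_*.png"))
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        exc.add_note(f"pipeline failed during stage '{stage}'")
        raise

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed_table": seed_table,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "figures": figures,
        "checksums": {
            name: sha256_file(out / name)
            for name in ("curves.csv", "per_replicate.csv", "summary.json")
        },
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")
    logger.info("pipeline complete: outputs in %s", out)
    return manifest
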