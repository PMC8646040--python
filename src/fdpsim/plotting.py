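"""Figure conveniences: trace panels, FDP curves, area-statistic bars.

Figures mirror the canonical numeric outputs and are never the
authoritative record of a run; the CSV/JSON files are. Error bars show
the standard error of the mean across replicates by default (switch to
``dispersion='sd'`` for standard deviations).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .analysis import FDPCurve, PlasticityAreas, condition_label

__all__ = ["plot_trace", "plot_fdp_curves", "plot_area_stats"]

_COLORS = {0.0: "black", 1.0: "tab:red", 3.0: "tab:blue", 5.0: "tab:green"}


def _color(cv: float):
    return _COLORS.get(cv, None)


def plot_trace(trace, start_ms: float | None = None, path=None):
    """Calcium and weight time courses of one run (final window by default)."""
    if start_ms is None:
        start_ms = trace.provenance.get("config", {}).get("window_start", trace.t[0])
    mask = trace.t >= start_ms
    fig, (ax_ca, ax_w) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    ax_ca.plot(trace.t[mask], trace.ca[mask], lw=0.6)
    ax_ca.set_ylabel("Ca (μM)")
    ax_w.plot(trace.t[mask], trace.w[mask], lw=0.8)
    ax_w.axhline(1.0, color="gray", lw=0.5, ls="--")
    ax_w.set_ylabel("relative weight W")
    ax_w.set_xlabel("time (ms)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_fdp_curves(curves: dict, quantity: str = "w",
                    dispersion: str = "sem", path=None):
    """Mean ± error curves vs input frequency for every condition.

    ``quantity`` is 'w' (relative synaptic weight) or 'ca' (steady-state
    calcium, μM).
    """
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for cv in sorted(curves):
        curve: FDPCurve = curves[cv]
        if quantity == "w":
            y, err = curve.mean_w, (curve.sem_w() if dispersion == "sem" else curve.sd_w())
        else:
            y, err = curve.mean_ca, (curve.sem_ca() if dispersion == "sem" else curve.sd_ca())
        style = dict(color=_color(cv), ls="--" if cv == 0 else "-",
                     marker="o", ms=3, capsize=2, label=curve.label)
        ax.errorbar(curve.frequencies, y, yerr=err, **style)
    if quantity == "w":
        ax.axhline(1.0, color="gray", lw=0.5)
        ax.set_ylabel("relative synaptic weight W")
    else:
        ax.set_ylabel("steady-state Ca (μM)")
    ax.set_xlabel("input frequency (Hz)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_area_stats(conditions: dict, per_replicate, path=None):
    """Bar panels of area ratios, thresholds and calcium-at-threshold.

    ``conditions`` maps cv → PlasticityAreas (mean-curve statistics,
    drawn as bars); ``per_replicate`` is the tidy per-replicate table
    used for the SEM error bars.
    """
    cvs = sorted(conditions)
    labels = [condition_label(cv) for cv in cvs]
    panels = [
        ("ltd_area_ratio_pct", "LTD-area ratio (%)",
         [conditions[cv].ltd_area_ratio for cv in cvs]),
        ("ltp_area_ratio_pct", "LTP-area ratio (%)",
         [conditions[cv].ltp_area_ratio for cv in cvs]),
        ("f0_hz", "LTD/LTP threshold f0 (Hz)",
         [conditions[cv].f0 for cv in cvs]),
        ("ca_at_f0_uM", "Ca at threshold (μM)",
         [conditions[cv].ca_at_f0 for cv in cvs]),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, (col, title, bars) in zip(axes.ravel(), panels):
        sems = []
        for cv in cvs:
            vals = per_replicate.loc[per_replicate["cv"] == cv, col].dropna()
            sems.append(vals.sem() if len(vals) > 1 else 0.0)
        if all(b is not None for b in bars):
            ax.bar(labels, bars, yerr=sems, capsize=3,
                   color=[_color(cv) or "tab:gray" for cv in cvs], alpha=0.8)
        ax.set_title(title, fontsize=10)
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
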