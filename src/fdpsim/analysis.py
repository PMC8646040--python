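"""Frequency sweeps and the bespoke plasticity statistics.

A sweep runs the simulator over a frequency grid for every replicate of
every CV condition and summarizes each run by its steady-state mean
weight and calcium. From the per-condition mean weight curve W(f) the
module computes:

* **f0** — the LTD/LTP threshold: the frequency at which W(f) first
  returns to 1 after falling below 1 as f increases from 0;
* **f_plus** — the upper integration limit: the smaller of 20 Hz and
  the first frequency where the curve plateaus;
* **LTD-area** ∫₀^f0 W df and **LTP-area** ∫_f0^f+ W df (trapezoidal),
  and their percent ratios against the fluctuation-free control;
* pairwise significance tests of the per-replicate statistics between
  conditions (Welch's t-test with Holm correction by default).

Below the lowest simulated frequency the weight curve is extended flat,
so the integral from 0 Hz is well defined. An ``area_mode`` switch
selects the literal ∫W df reading (default) or the deviation-from-
baseline areas ∫(1−W) df and ∫(W−1) df.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .drive import ReplicateDesign, build_design, regular_train
from .errors import ConfigurationError, ThresholdUndefinedError
from .params import ModelParams
from .simulator import SimulationConfig, simulate, window_mean

__all__ = [
    "FDPCurve",
    "PlasticityAreas",
    "GroupComparison",
    "sweep",
    "find_threshold_f0",
    "find_f_plus",
    "compute_areas",
    "compare_groups",
    "condition_label",
]

logger = logging.getLogger(__name__)

F_MAX_HZ = 20.0  # cap of the LTP integration range


def condition_label(cv: float) -> str:
    """Human-readable condition name: 'control' for cv = 0, else 'cv<k>'."""
    if cv == 0:
        return "control"
    return f"cv{cv:g}"


@dataclass(frozen=True)
class FDPCurve:
    """Per-replicate steady-state weight/calcium over a frequency grid.

    ``w`` and ``ca`` have shape (n_replicates, n_frequencies); rows are
    keyed by ``replicate_keys`` (cv, train index, xi-seed index).
    """

    cv: float
    frequencies: np.ndarray
    w: np.ndarray
    ca: np.ndarray
    replicate_keys: list = field(default_factory=list)

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        if f.size < 1 or np.any(np.diff(f) <= 0):
            raise ConfigurationError("frequencies must be non-empty and strictly increasing")
        if self.w.shape != self.ca.shape or self.w.shape[1] != f.size:
            raise ConfigurationError(
                f"replicate matrices {self.w.shape} inconsistent with {f.size} frequencies"
            )

    @property
    def label(self) -> str:
        return condition_label(self.cv)

    @property
    def n_replicates(self) -> int:
        return self.w.shape[0]

    # frequency-wise aggregates across replicates
    @property
    def mean_w(self) -> np.ndarray:
        return self.w.mean(axis=0)

    @property
    def mean_ca(self) -> np.ndarray:
        return self.ca.mean(axis=0)

    def sd_w(self) -> np.ndarray:
        return self.w.std(axis=0, ddof=1)

    def sd_ca(self) -> np.ndarray:
        return self.ca.std(axis=0, ddof=1)

    def sem_w(self) -> np.ndarray:
        return self.sd_w() / np.sqrt(self.n_replicates)

    def sem_ca(self) -> np.ndarray:
        return self.sd_ca() / np.sqrt(self.n_replicates)

    def to_frame(self) -> pd.DataFrame:
        """Tidy rows: condition, replicate key, frequency, mean_w, mean_ca."""
        rows = []
        for r in range(self.n_replicates):
            key = self.replicate_keys[r] if self.replicate_keys else (self.cv, r)
            for c, f in enumerate(self.frequencies):
                rows.append({
                    "condition": self.label, "cv": self.cv,
                    "train": key[1], "xi_seed": key[2] if len(key) > 2 else 0,
                    "frequency_hz": f,
                    "mean_w": self.w[r, c], "mean_ca_uM": self.ca[r, c],
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlasticityAreas:
    """Threshold and area statistics of one condition's mean curve.

    Areas are in Hz·(weight units); ratios are percent of the control
    condition's areas (the control's own ratios are 100 by definition).
    """

    cv: float
    f0: float
    f_plus: float
    ltd_area: float
    ltp_area: float
    ca_at_f0: float
    ltd_area_ratio: float | None = None
    ltp_area_ratio: float | None = None
    area_mode: str = "literal"

    @property
    def label(self) -> str:
        return condition_label(self.cv)

    def to_dict(self) -> dict:
        return {
            "condition": self.label, "cv": self.cv,
            "f0_hz": self.f0, "f_plus_hz": self.f_plus,
            "ltd_area": self.ltd_area, "ltp_area": self.ltp_area,
            "ca_at_f0_uM": self.ca_at_f0,
            "ltd_area_ratio_pct": self.ltd_area_ratio,
            "ltp_area_ratio_pct": self.ltp_area_ratio,
            "area_mode": self.area_mode,
        }


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise test table for one per-replicate statistic."""

    metric: str
    test: str
    correction: str
    alpha: float
    table: pd.DataFrame  # columns: condition_a, condition_b, statistic, p, p_adj, significant

    def significant_pairs(self) -> list:
        t = self.table
        return list(map(tuple, t.loc[t["significant"], ["condition_a", "condition_b"]].values))


def sweep(params: ModelParams, sim_config: SimulationConfig,
          design: ReplicateDesign, frequencies) -> dict:
    """Run the full (condition × replicate × frequency) simulation grid.

    Within a replicate the same background drive is reused across all
    presynaptic frequencies, so curves differ across frequency only
    through the presynaptic train. Returns ``{cv: FDPCurve}``.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0 or np.any(np.diff(freqs) <= 0):
        raise ConfigurationError("frequencies must be non-empty and strictly increasing")
    drives = build_design(design, sim_config.duration)
    pre_trains = {f: regular_train(f, sim_config.duration) for f in freqs}
    curves = {}
    for cv in design.cv_levels:
        keys = design.replicate_keys(cv)
        w = np.empty((len(keys), freqs.size))
        ca = np.empty_like(w)
        for r, key in enumerate(keys):
            for c, f in enumerate(freqs):
                try:
                    trace = simulate(params, sim_config, pre_trains[f], drives[key])
                    summary = window_mean(trace, key=key)
                except Exception as exc:
                    exc.add_note(f"while simulating replicate {key} at {f} Hz")
                    raise
                w[r, c] = summary.mean_w
                ca[r, c] = summary.mean_ca
            logger.info("condition %s replicate %s done", condition_label(cv), key)
        curves[cv] = FDPCurve(cv=cv, frequencies=freqs, w=w, ca=ca,
                              replicate_keys=keys)
    return curves


def _as_curve_arrays(curve) -> tuple:
    """Accept an FDPCurve or a (frequencies, w_mean) pair."""
    if isinstance(curve, FDPCurve):
        return curve.frequencies, curve.mean_w
    f, w = curve
    return np.asarray(f, dtype=float), np.asarray(w, dtype=float)


def find_threshold_f0(curve) -> float:
    """LTD/LTP threshold: first return of W(f) to 1 after a dip below 1.

    Scans the condition-mean curve from low frequency; the crossing
    frequency is linearly interpolated between the bracketing grid
    points (exact when a grid value equals 1).

    Raises
    ------
    ThresholdUndefinedError
        Naming the failing clause: the curve never falls below 1, or
        falls below but never recovers.
    """
    f, w = _as_curve_arrays(curve)
    if f.size < 2:
        raise ConfigurationError("need at least 2 curve points")
    dipped = False
    for i in range(f.size):
        if w[i] < 1.0:
            dipped = True
        elif dipped:  # w[i] >= 1 after a dip: crossing in (f[i-1], f[i]]
            if w[i] == 1.0:
                return float(f[i])
            return float(f[i - 1] + (1.0 - w[i - 1]) / (w[i] - w[i - 1]) * (f[i] - f[i - 1]))
    if not dipped:
        raise ThresholdUndefinedError(
            "threshold undefined: weight curve never falls below 1"
        )
    raise ThresholdUndefinedError(
        "threshold undefined: weight curve never returns to 1 after its dip"
    )


def find_f_plus(curve, plateau_tol: float = 0.0) -> float:
    """Upper limit of the LTP range: min(20 Hz, onset of a plateau).

    A plateau starts at the left frequency of the first interval whose
    slope magnitude |ΔW/Δf| is strictly below ``plateau_tol`` (weight
    per Hz). The default tolerance 0 disables plateau detection, so the
    limit is the 20 Hz cap (or the curve's last frequency for sweeps
    that end below 20 Hz).
    """
    f, w = _as_curve_arrays(curve)
    cap = float(min(F_MAX_HZ, f[-1]))
    if f.size >= 2 and plateau_tol > 0:
        slopes = np.abs(np.diff(w) / np.diff(f))
        hits = np.nonzero(slopes < plateau_tol)[0]
        if hits.size:
            return float(min(cap, f[hits[0]]))
    return cap


def _area_nodes(f: np.ndarray, y: np.ndarray, lo: float, hi: float) -> tuple:
    """Trapezoid nodes of y(f) on [lo, hi], flat-extended below f[0]."""
    if hi > f[-1] + 1e-12:
        raise ConfigurationError(
            f"curve ends at {f[-1]} Hz but integration needs {hi} Hz"
        )
    nodes = np.unique(np.concatenate([[lo, hi], f[(f > lo) & (f < hi)]]))
    # flat extension: np.interp holds y[0] left of f[0]
    vals = np.interp(nodes, f, y)
    return nodes, vals


def compute_areas(curve, f0: float, f_plus: float,
                  area_mode: str = "literal") -> PlasticityAreas:
    """Trapezoidal LTD/LTP areas of the condition-mean weight curve.

    LTD-area integrates over [0, f0] and LTP-area over [f0, f_plus],
    with the interpolated point at f0 included as a node and the curve
    extended flat from its first grid point down to 0 Hz.

    ``area_mode='literal'`` integrates W itself, the threshold-area
    definition as printed. ``'deviation'`` measures the geometric area
    between the curve and the W = 1 baseline — max(1−W, 0) on the LTD
    range and max(W−1, 0) on the LTP range — i.e. the shaded-region
    reading of the published area schematics; portions of the curve on
    the wrong side of the baseline contribute zero rather than
    cancelling.
    """
    if not 0 < f0 < f_plus:
        raise ConfigurationError(f"need 0 < f0 < f_plus, got f0={f0}, f_plus={f_plus}")
    if area_mode not in ("literal", "deviation"):
        raise ConfigurationError(f"unknown area_mode '{area_mode}'")
    f, w = _as_curve_arrays(curve)
    nodes_d, w_d = _area_nodes(f, w, 0.0, f0)
    nodes_p, w_p = _area_nodes(f, w, f0, f_plus)
    if area_mode == "literal":
        ltd = np.trapezoid(w_d, nodes_d)
        ltp = np.trapezoid(w_p, nodes_p)
    else:
        ltd = np.trapezoid(np.maximum(1.0 - w_d, 0.0), nodes_d)
        ltp = np.trapezoid(np.maximum(w_p - 1.0, 0.0), nodes_p)
    ca_at_f0 = float("nan")
    if isinstance(curve, FDPCurve):
        ca_at_f0 = float(np.interp(f0, f, curve.mean_ca))
    cv = curve.cv if isinstance(curve, FDPCurve) else float("nan")
    return PlasticityAreas(
        cv=cv, f0=float(f0), f_plus=float(f_plus),
        ltd_area=float(ltd), ltp_area=float(ltp),
        ca_at_f0=ca_at_f0, area_mode=area_mode,
    )


def compare_groups(samples: dict, test: str = "welch",
                   correction: str = "holm", alpha: float = 0.05,
                   metric: str = "", permutation_resamples: int = 10000,
                   seed: int = 0) -> GroupComparison:
    """All pairwise condition comparisons for one per-replicate statistic.

    Parameters
    ----------
    samples : dict
        Condition label → 1-D array of per-replicate values (NaNs are
        dropped; every condition needs ≥ 2 finite values).
    test : {'welch', 'permutation'}
        Welch's unequal-variance t-test (default) or a two-sided
        permutation test on the difference of means.
    correction : {'holm', 'none'}
        Multiple-comparison correction across the pairs.
    alpha : float
        Family-wise significance level for the ``significant`` flags.
    """
    if test not in ("welch", "permutation"):
        raise ConfigurationError(f"unknown test '{test}'")
    if correction not in ("holm", "none"):
        raise ConfigurationError(f"unknown correction '{correction}'")
    clean = {}
    for cond, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ConfigurationError(
                f"condition '{cond}' has {v.size} finite replicate value(s); "
                "need >= 2 for a dispersion estimate"
            )
        clean[cond] = v
    pairs = list(itertools.combinations(clean, 2))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        xa, xb = clean[a], clean[b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            # identical constant samples: no evidence of a difference
            stat, p = 0.0, 1.0
        elif test == "welch":
            res = stats.ttest_ind(xa, xb, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.permutation_test(
                (xa, xb), lambda x, y: np.mean(x) - np.mean(y),
                permutation_type="independent", alternative="two-sided",
                n_resamples=permutation_resamples, rng=rng,
            )
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"condition_a": a, "condition_b": b, "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    p_raw = table["p"].to_numpy()
    if correction == "holm":
        table["p_adj"] = multipletests(p_raw, alpha=alpha, method="holm")[1]
    else:
        table["p_adj"] = p_raw
    table["significant"] = table["p_adj"] < alpha
    return GroupComparison(metric=metric, test=test, correction=correction,
                           alpha=alpha, table=table)


def analyze_sweep(curves: dict, plateau_tol: float = 0.0,
                  area_mode: str = "deviation", test: str = "welch",
                  correction: str = "holm", alpha: float = 0.05,
                  permutation_resamples: int = 10000, seed: int = 0) -> dict:
    """Full statistics of a sweep: thresholds, areas, ratios, tests.

    Condition-level statistics (one f0, f_plus, LTD-/LTP-area per
    condition) are computed on the condition-mean weight curve; area
    ratios are percent of the control (cv = 0) mean-curve areas.
    Per-replicate statistics use each replicate's own curve (threshold
    failures become NaN and are dropped from the tests) and feed the
    pairwise group comparisons of LTD-area ratio, LTP-area ratio, f0
    and calcium-at-f0.

    Returns a dict with keys ``conditions`` ({label: PlasticityAreas}),
    ``per_replicate`` (tidy DataFrame) and ``comparisons``
    ({metric: GroupComparison or None if not computable}).
    """
    if not curves:
        raise ConfigurationError("no curves to analyze")
    has_control = 0.0 in curves
    control_areas = None
    cond_stats = {}
    for cv in sorted(curves):
        curve = curves[cv]
        try:
            f0 = find_threshold_f0(curve)
        except ThresholdUndefinedError as exc:
            # condition without a defined threshold: statistics stay absent
            logger.warning("condition %s: %s", condition_label(cv), exc)
            cond_stats[cv] = None
            continue
        f_plus = find_f_plus(curve, plateau_tol)
        areas = compute_areas(curve, f0, f_plus, area_mode)
        cond_stats[cv] = areas
    if has_control and cond_stats[0.0] is not None:
        control_areas = cond_stats[0.0]
        updated = {}
        for cv, a in cond_stats.items():
            if a is None:
                updated[cv] = None
                continue
            updated[cv] = PlasticityAreas(
                cv=a.cv, f0=a.f0, f_plus=a.f_plus,
                ltd_area=a.ltd_area, ltp_area=a.ltp_area,
                ca_at_f0=a.ca_at_f0, area_mode=a.area_mode,
                ltd_area_ratio=100.0 * a.ltd_area / control_areas.ltd_area,
                ltp_area_ratio=100.0 * a.ltp_area / control_areas.ltp_area,
            )
        cond_stats = updated

    rows = []
    for cv in sorted(curves):
        curve = curves[cv]
        for r in range(curve.n_replicates):
            key = curve.replicate_keys[r] if curve.replicate_keys else (cv, r, 0)
            rep = (curve.frequencies, curve.w[r])
            row = {"condition": curve.label, "cv": cv,
                   "train": key[1], "xi_seed": key[2] if len(key) > 2 else 0,
                   "f0_hz": np.nan, "f_plus_hz": np.nan,
                   "ltd_area": np.nan, "ltp_area": np.nan,
                   "ltd_area_ratio_pct": np.nan, "ltp_area_ratio_pct": np.nan,
                   "ca_at_f0_uM": np.nan}
            try:
                f0_r = find_threshold_f0(rep)
                fp_r = find_f_plus(rep, plateau_tol)
                a_r = compute_areas(rep, f0_r, fp_r, area_mode)
                row.update({
                    "f0_hz": f0_r, "f_plus_hz": fp_r,
                    "ltd_area": a_r.ltd_area, "ltp_area": a_r.ltp_area,
                    "ca_at_f0_uM": float(np.interp(f0_r, curve.frequencies, curve.ca[r])),
                })
                if control_areas is not None:
                    row["ltd_area_ratio_pct"] = 100.0 * a_r.ltd_area / control_areas.ltd_area
                    row["ltp_area_ratio_pct"] = 100.0 * a_r.ltp_area / control_areas.ltp_area
            except ThresholdUndefinedError as exc:
                logger.warning("replicate %s: %s", key, exc)
            rows.append(row)
    per_replicate = pd.DataFrame(rows)

    metric_cols = {
        "ltd_area_ratio": "ltd_area_ratio_pct",
        "ltp_area_ratio": "ltp_area_ratio_pct",
        "f0": "f0_hz",
        "ca_at_f0": "ca_at_f0_uM",
    }
    comparisons = {}
    if len(curves) >= 2:
        for metric, col in metric_cols.items():
            samples = {
                condition_label(cv): per_replicate.loc[
                    per_replicate["cv"] == cv, col].to_numpy()
                for cv in sorted(curves)
            }
            try:
                comparisons[metric] = compare_groups(
                    samples, test=test, correction=correction, alpha=alpha,
                    metric=metric, permutation_resamples=permutation_resamples,
                    seed=seed,
                )
            except ConfigurationError as exc:
                logger.warning("comparison of %s skipped: %s", metric, exc)
                comparisons[metric] = None
    return {"conditions": cond_stats, "per_replicate": per_replicate,
            "comparisons": comparisons}
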