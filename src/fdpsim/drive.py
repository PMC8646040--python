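"""Synthetic presynaptic and background drive generation.

Everything stochastic in the study enters here: regular presynaptic
spike trains (constant inter-spike interval), homogeneous 1 Hz Poisson
background event trains, and i.i.d. Gaussian per-event amplitude factors
with mean 1 and a prescribed coefficient of variation (CV). The
replicate design mirrors the study protocol: a fixed set of Poisson
trains shared across CV conditions, crossed with several independent
amplitude seeds per train and CV (5 trains × 3 seeds = 15 replicates at
defaults), plus a fluctuation-free control (CV = 0, all factors 1).

Reproducibility: every random stream is derived from a single base seed
through documented ``numpy.random.SeedSequence`` spawn keys, so any
individual replicate can be regenerated in isolation:

* Poisson train ``i``          → ``SeedSequence((base_seed, 0, i))``
* amplitudes ``(cv_k, i, j)``  → ``SeedSequence((base_seed, 1, k, i, j))``

where ``k`` indexes the CV level in ``cv_levels`` and ``j`` the
amplitude seed within a train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SpikeTrain",
    "BackgroundDrive",
    "ReplicateDesign",
    "regular_train",
    "poisson_train",
    "draw_amplitudes",
    "build_design",
    "save_drive",
    "load_drive",
]


@dataclass(frozen=True)
class SpikeTrain:
    """A sorted sequence of event times on [0, duration), in ms."""

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ConfigurationError(f"{self.label or 'train'}: times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= self.duration):
            raise ConfigurationError(
                f"{self.label or 'train'}: times must lie in [0, duration)"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BackgroundDrive:
    """A background event train plus its per-event amplitude factors.

    ``xi[i]`` multiplies the voltage kernel of event ``train.times[i]``;
    the factors are i.i.d. Normal(1, cv) draws (all exactly 1 when
    cv = 0). Negative draws are kept by default — see
    :func:`draw_amplitudes`.
    """

    train: SpikeTrain
    xi: np.ndarray
    cv: float
    seed_train: int
    seed_xi: int

    def __post_init__(self):
        xi = np.asarray(self.xi, dtype=float)
        object.__setattr__(self, "xi", xi)
        if xi.size != len(self.train):
            raise ConfigurationError(
                f"xi length {xi.size} != event count {len(self.train)}"
            )
        if self.cv < 0:
            raise ConfigurationError(f"cv must be >= 0, got {self.cv}")
        if self.cv == 0 and xi.size and not np.all(xi == 1.0):
            raise ConfigurationError("cv = 0 requires all amplitude factors == 1")


@dataclass(frozen=True)
class ReplicateDesign:
    """The replicate layout of the study.

    ``n_trains`` Poisson background trains are shared across all CV
    levels; each (CV, train) cell gets ``n_xi_seeds`` independent
    amplitude draws, giving ``n_trains × n_xi_seeds`` replicates per CV.
    ``cv_levels`` should include 0 for the fluctuation-free control.
    """

    n_trains: int = 5
    n_xi_seeds: int = 3
    cv_levels: tuple = (0.0, 1.0, 3.0, 5.0)
    base_seed: int = 0
    bg_rate_hz: float = 1.0
    truncate_negative_xi: bool = False

    def __post_init__(self):
        if self.n_trains < 1 or self.n_xi_seeds < 1:
            raise ConfigurationError("n_trains and n_xi_seeds must be >= 1")
        object.__setattr__(self, "cv_levels", tuple(float(c) for c in self.cv_levels))

    @property
    def n_replicates(self) -> int:
        """Replicates per CV level."""
        return self.n_trains * self.n_xi_seeds

    def replicate_keys(self, cv: float):
        """(cv, train index, xi-seed index) keys of one condition."""
        return [(cv, i, j) for i in range(self.n_trains) for j in range(self.n_xi_seeds)]


def _child_seed(*key) -> int:
    """Deterministic 32-bit child seed from a spawn-key tuple."""
    return int(np.random.SeedSequence(key).generate_state(1, np.uint32)[0])


def regular_train(freq: float, duration: float, phase: float = 0.0,
                  label: str = "") -> SpikeTrain:
    """Constant-interval presynaptic train: events at phase + k·1000/freq.

    Parameters
    ----------
    freq : float
        Firing rate in Hz (> 0); the inter-spike interval is 1000/freq ms.
    duration : float
        Span in ms; events fill [phase, duration).
    phase : float
        Time of the first spike (ms), default 0.
    """
    if not freq > 0:
        raise ConfigurationError(f"freq must be > 0, got {freq}")
    if not duration > 0:
        raise ConfigurationError(f"duration must be > 0, got {duration}")
    isi = 1000.0 / freq
    n = int(np.ceil((duration - phase) / isi))
    times = phase + isi * np.arange(max(n, 0))
    times = times[times < duration]
    return SpikeTrain(times, duration, label or f"regular_{freq}Hz")


def poisson_train(rate: float, duration: float, seed: int,
                  label: str = "") -> SpikeTrain:
    """Homogeneous Poisson process realization on [0, duration).

    Sampled exactly: the event count is Poisson(rate·duration) and event
    times are order statistics of uniforms. Identical seeds give
    identical trains.

    Parameters
    ----------
    rate : float
        Mean event rate in Hz.
    duration : float
        Span in ms.
    seed : int
        Seed for the dedicated PCG64 stream of this train.
    """
    if not rate > 0:
        raise ConfigurationError(f"rate must be > 0, got {rate}")
    rng = np.random.Generator(np.random.PCG64(seed))
    n = rng.poisson(rate * duration / 1000.0)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    # a tie between two uniforms is measure-zero but would violate the
    # strict-monotonicity invariant; nudge duplicates apart
    while times.size > 1 and np.any(np.diff(times) <= 0):
        times = np.sort(times + rng.uniform(0, 1e-9, size=n))
    return SpikeTrain(times, duration, label or f"poisson_{rate}Hz_seed{seed}")


def draw_amplitudes(n: int, cv: float, seed: int,
                    truncate_negative: bool = False) -> np.ndarray:
    """n i.i.d. amplitude factors ~ Normal(mean 1, SD cv).

    ``cv = 0`` returns exact ones (the control). For cv ≥ 1 the normal
    has substantial mass below zero; such draws correspond to
    transiently hyperpolarizing events and are kept as drawn unless
    ``truncate_negative`` clips them at 0.
    """
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    if cv < 0:
        raise ConfigurationError(f"cv must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(n)
    rng = np.random.Generator(np.random.PCG64(seed))
    xi = rng.normal(1.0, cv, size=n)
    if truncate_negative:
        xi = np.maximum(xi, 0.0)
    return xi


def build_design(design: ReplicateDesign, duration: float) -> dict:
    """Generate every BackgroundDrive of the replicate design.

    Returns a dict keyed by ``(cv, train_index, xi_seed_index)``. The
    same ``n_trains`` Poisson trains (derived from ``base_seed``) are
    shared across CV levels, so conditions differ only in their
    amplitude factors; the control level (cv = 0) uses factors ≡ 1.
    """
    trains = []
    train_seeds = []
    for i in range(design.n_trains):
        s = _child_seed(design.base_seed, 0, i)
        train_seeds.append(s)
        trains.append(poisson_train(design.bg_rate_hz, duration, s,
                                    label=f"bg_train{i}"))
    drives = {}
    for k, cv in enumerate(design.cv_levels):
        for i in range(design.n_trains):
            for j in range(design.n_xi_seeds):
                s_xi = _child_seed(design.base_seed, 1, k, i, j)
                xi = draw_amplitudes(len(trains[i]), cv, s_xi,
                                     design.truncate_negative_xi)
                drives[(cv, i, j)] = BackgroundDrive(
                    train=trains[i], xi=xi, cv=cv,
                    seed_train=train_seeds[i], seed_xi=s_xi,
                )
    return drives


def save_drive(drive: BackgroundDrive, csv_path) -> None:
    """Write a drive as CSV (time_ms, xi) plus a JSON seed sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_ms": drive.train.times, "xi": drive.xi}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    meta = {
        "duration_ms": drive.train.duration,
        "label": drive.train.label,
        "cv": drive.cv,
        "seed_train": drive.seed_train,
        "seed_xi": drive.seed_xi,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_drive(csv_path) -> BackgroundDrive:
    """Read back a drive written by :func:`save_drive`, bit-exactly."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    train = SpikeTrain(df["time_ms"].to_numpy(), meta["duration_ms"], meta["label"])
    return BackgroundDrive(
        train=train, xi=df["xi"].to_numpy(), cv=meta["cv"],
        seed_train=meta["seed_train"], seed_xi=meta["seed_xi"],
    )
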