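"""Model parameters of the calcium-control plasticity synapse.

The model couples a relative synaptic weight W to the postsynaptic
calcium concentration through a calcium-dependent learning rate
``eta(Ca)`` and target weight ``omega(Ca)``; calcium enters through
NMDA-receptor channels gated by the membrane potential, which is driven
by presynaptic EPSPs and by 1 Hz Poisson background events whose
amplitudes fluctuate with a configurable coefficient of variation.

All default values below are the published constants of that model.
Internal canonical time unit is the millisecond; ``p1`` and ``p4`` are
printed in seconds (``eta`` is an s⁻¹ rate) and are converted where the
integrator needs ms⁻¹.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the weight, calcium and membrane-potential dynamics.

    Attributes
    ----------
    p1, p4 : float
        Learning-rate constants, in seconds. ``eta`` is bounded above by
        ``1/p4``.
    p2 : float
        Learning-rate offset in the μM³ scale of ``Ca**p3``. The default
        1000 (= p1/1e-4, the printed value) makes eta essentially
        calcium-independent (≈ 1 s⁻¹ everywhere), so the weight relaxes
        toward the time-average of omega; this reading reproduces the
        published frequency-dependence, including a defined LTD/LTP
        threshold in every fluctuation condition. The source model's
        alternative p2 = p1 × 1e-4 = 1e-5 (slow learning at low
        calcium) is selectable and is discussed in docs/methods.md: it
        deepens the control dip but abolishes the LTD phase entirely at
        high fluctuation.
    p3 : float
        Exponent of calcium in the learning rate (pure number).
    alpha1, alpha2 : float
        Calcium thresholds (μM) of the LTD dip and LTP rise of omega.
    beta1, beta2 : float
        Sigmoid steepnesses (1/μM) at alpha1 and alpha2.
    i_f, i_s : float
        Fast/slow weights of the NMDA glutamate-unbinding kernel
        (dimensionless; defaults sum to 1).
    tau_f, tau_s : float
        Fast/slow NMDA kernel time constants (ms).
    p0 : float
        Fraction of NMDA receptors moving from closed to open state
        (pure fraction).
    g_nmda : float
        NMDA calcium-flux conductance magnitude (μM·ms⁻¹·mV⁻¹). Stored
        as a magnitude; the published table prints it with a minus sign.
        Default 1/500, the value of the source calcium-control model.
        The published table prints the magnitude as 1/140 = 3.57 × 1/500,
        i.e. the magnesium-block constant 3.57 folded into the
        conductance; taken at face value per (ms·mV) it makes every
        single-spike calcium transient overshoot alpha2, which abolishes
        the low-frequency LTD phase entirely (see docs/methods.md). Set
        ``g_nmda=1/140`` to audit the printed value.
    mg : float
        Extracellular magnesium concentration (mM) in the block factor.
    v_r : float
        NMDA calcium-current reversal potential (mV).
    v_rest : float
        Resting membrane potential (mV).
    s : float
        Amplitude scale of background events (mV).
    tau1, tau2 : float
        Slow/fast time constants (ms) of the double-exponential PSP
        kernel shared by EPSPs and background events.
    tau_ca : float
        Calcium decay time constant (ms); 80 ms is representative of
        deep-layer cortical pyramidal cells.
    epsp_scale : float
        Amplitude (mV) applied to the EPSP kernel. The default 1.0 is
        the EPSP equation as printed (no amplitude factor; kernel peak
        ≈ 0.70 mV, a physiological single-fiber EPSP). Setting it to
        ``s`` scales EPSPs like background events; that choice makes
        single EPSPs 14 mV, compresses the LTD phase to a sliver below
        ~1.2 Hz and inverts the calcium-versus-CV ordering — see
        docs/methods.md.
    literal_nmda_sign : bool
        Audit switch. If True, the voltage gate uses the literally
        printed sign convention (negative for V < v_r, so calcium is
        driven out of the cell); the default False uses the influx
        (non-negative) convention the model's dynamics require.
    """

    p1: float = 0.1          # s
    p2: float = 1000.0       # μM³ scale
    p3: float = 3.0
    p4: float = 1.0          # s
    alpha1: float = 0.35     # μM
    alpha2: float = 0.55     # μM
    beta1: float = 80.0      # 1/μM
    beta2: float = 80.0      # 1/μM
    i_f: float = 0.75
    i_s: float = 0.25
    tau_f: float = 50.0      # ms
    tau_s: float = 200.0     # ms
    p0: float = 0.5
    g_nmda: float = 1.0 / 500.0   # μM·ms⁻¹·mV⁻¹, magnitude
    mg: float = 1.0          # mM
    v_r: float = 130.0       # mV
    v_rest: float = -65.0    # mV
    s: float = 20.0          # mV
    tau1: float = 50.0       # ms
    tau2: float = 5.0        # ms
    tau_ca: float = 80.0     # ms
    epsp_scale: float = 1.0  # mV
    literal_nmda_sign: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def epsp_amplitude(self) -> float:
        """EPSP kernel amplitude in mV."""
        return self.epsp_scale

    def validate(self) -> None:
        """Check the structural invariants; raise ConfigurationError."""
        positive_times = {
            "p1": self.p1, "p4": self.p4, "tau_f": self.tau_f,
            "tau_s": self.tau_s, "tau1": self.tau1, "tau2": self.tau2,
            "tau_ca": self.tau_ca,
        }
        for name, value in positive_times.items():
            if not (math.isfinite(value) and value > 0):
                raise ConfigurationError(f"{name} must be a positive time, got {value}")
        if not self.tau2 < self.tau1:
            raise ConfigurationError(
                f"PSP kernel needs tau2 < tau1, got tau2={self.tau2}, tau1={self.tau1}"
            )
        if not self.tau_f < self.tau_s:
            raise ConfigurationError(
                f"NMDA kernel needs tau_f < tau_s, got tau_f={self.tau_f}, tau_s={self.tau_s}"
            )
        if not self.alpha1 < self.alpha2:
            raise ConfigurationError(
                f"omega needs alpha1 < alpha2, got {self.alpha1}, {self.alpha2}"
            )
        if not (0.0 < self.p0 <= 1.0):
            raise ConfigurationError(f"p0 must lie in (0, 1], got {self.p0}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown model parameter(s): {', '.join(sorted(unknown))}"
            )
        return cls(**d)
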