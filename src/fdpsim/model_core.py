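"""Pure, stateless evaluation of the calcium-control model functions.

These are the building blocks of the synapse model: the logistic
``sigmoid``, the calcium-dependent target weight ``omega`` and learning
rate ``eta``, the magnesium-blocked NMDA voltage gate ``nmda_gate``, and
the double-exponential postsynaptic-potential kernel. All functions are
vectorized over their first argument and perform no unit conversion:
``eta`` returns an s⁻¹ rate (its constants are printed in seconds), all
kernel times are in ms.

The integrator in :mod:`fdpsim.simulator` inlines compiled copies of
these functions; the test suite pins the two sets to each other at
1e-12 relative so they cannot drift apart.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DomainError
from .params import ModelParams

__all__ = ["sigmoid", "omega", "eta", "nmda_gate", "double_exp_kernel"]


def _require_finite(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite")
    return arr


def _require_nonneg_ca(ca) -> np.ndarray:
    arr = _require_finite(ca, "ca")
    if np.any(arr < 0):
        raise DomainError(
            "negative calcium concentration; this usually signals an "
            "integrator sign bug upstream"
        )
    return arr


def sigmoid(x, beta):
    """Logistic function exp(βx) / (1 + exp(βx)), overflow-safe.

    Parameters
    ----------
    x : array_like
        Concentration offset (μM).
    beta : array_like
        Steepness (1/μM).

    Returns
    -------
    ndarray or float
        Values in (0, 1); exactly satisfies
        ``sigmoid(x, b) + sigmoid(-x, b) == 1``.
    """
    x = _require_finite(x, "x")
    beta = _require_finite(beta, "beta")
    out = expit(beta * x)
    return out if out.ndim else float(out)


def omega(ca, params: ModelParams = ModelParams()):
    """Calcium-dependent target weight Ω(Ca).

    Ω(Ca) = 1 + 4·sig(Ca − α2, β2) − sig(Ca − α1, β1).

    Near zero calcium Ω ≈ 1 (no change); between α1 and α2 it dips
    towards 0 (the LTD zone); above α2 it saturates at 4 (the LTP zone).

    Raises
    ------
    DomainError
        If ``ca`` is negative or non-finite.
    """
    ca = _require_nonneg_ca(ca)
    out = 1.0 + 4.0 * expit(params.beta2 * (ca - params.alpha2)) \
        - expit(params.beta1 * (ca - params.alpha1))
    return out if out.ndim else float(out)


def eta(ca, params: ModelParams = ModelParams()):
    """Calcium-dependent learning rate η(Ca), in s⁻¹.

    η(Ca) = [p1 / (p2 + Ca^p3) + p4]⁻¹.

    Strictly increasing in calcium, from ≈ p2/p1 at zero calcium to the
    ceiling 1/p4: weight changes are slow at low calcium and take effect
    within seconds at high calcium.

    Raises
    ------
    DomainError
        If ``ca`` is negative or non-finite.
    """
    ca = _require_nonneg_ca(ca)
    out = 1.0 / (params.p1 / (params.p2 + ca ** params.p3) + params.p4)
    return out if out.ndim else float(out)


def nmda_gate(v, params: ModelParams = ModelParams()):
    """NMDA-receptor voltage gate H(V): calcium flux per unit kernel.

    Default (influx) convention::

        H(V) = P0 · |G_NMDA| · (Vr − V) / (1 + (Mg/3.57)·exp(−0.062·V))

    which is ≥ 0 for all V ≤ Vr and vanishes at the reversal potential.
    The denominator is the magnesium block, relieved by depolarization.
    With ``params.literal_nmda_sign`` the sign of the published table is
    reproduced verbatim (the negation of the above); that choice drives
    calcium out of the cell for sub-reversal potentials and exists for
    audit only.

    Units: μM·ms⁻¹ per unit of the (dimensionless) glutamate kernel.
    """
    v = _require_finite(v, "v")
    block = 1.0 + (params.mg / 3.57) * np.exp(-0.062 * v)
    out = params.p0 * abs(params.g_nmda) * (params.v_r - v) / block
    if params.literal_nmda_sign:
        out = -out
    return out if out.ndim else float(out)


def double_exp_kernel(t, tau_slow: float, tau_fast: float):
    """Causal double-exponential kernel Θ(t)·[exp(−t/τslow) − exp(−t/τfast)].

    The shape shared by the EPSP and background-event voltage kernels
    (τ1 = 50 ms, τ2 = 5 ms at defaults): zero at t ≤ 0, a single
    interior maximum at τslow·τfast·ln(τslow/τfast)/(τslow − τfast),
    decaying to zero afterwards.

    Raises
    ------
    ConfigurationError
        If ``tau_fast >= tau_slow`` (the kernel would be non-positive).
    """
    if not tau_fast < tau_slow:
        raise ConfigurationError(
            f"kernel needs tau_fast < tau_slow, got {tau_fast} >= {tau_slow}"
        )
    t = _require_finite(t, "t")
    # clamp before exponentiating so t << 0 cannot overflow exp(-t/tau)
    tpos = np.maximum(t, 0.0)
    out = np.exp(-tpos / tau_slow) - np.exp(-tpos / tau_fast)
    return out if out.ndim else float(out)
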