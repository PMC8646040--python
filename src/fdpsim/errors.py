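"""Exception hierarchy for fdpsim."""


class FdpsimError(Exception):
    """Base class for all fdpsim errors."""


class DomainError(FdpsimError, ValueError):
    """A model function was evaluated outside its mathematical domain.

    A negative calcium concentration reaching :func:`fdpsim.model_core.eta`
    or :func:`fdpsim.model_core.omega` usually signals a sign bug in the
    integrator upstream rather than bad user input.
    """


class ConfigurationError(FdpsimError, ValueError):
    """Invalid parameter, simulation or run configuration."""


class IntegrationError(FdpsimError, RuntimeError):
    """The fixed-step integrator produced a non-finite state.

    Carries the step index and the name of the state variable that
    diverged so the offending replicate can be re-run in isolation.
    """

    def __init__(self, step: int, state: str):
        self.step = step
        self.state = state
        super().__init__(
            f"non-finite value in state '{state}' at integration step {step}"
        )


class ThresholdUndefinedError(FdpsimError, ValueError):
    """The LTD/LTP threshold f0 does not exist for a weight curve.

    Raised either because the steady-state weight never dips below the
    baseline of 1, or because it dips but never recovers to 1 within the
    simulated frequency range. The message names the failing clause.
    """
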