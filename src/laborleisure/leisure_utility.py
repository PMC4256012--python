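"""Microscopic utility-of-leisure functions.

The model assigns an innate, duration-dependent utility ``U_L(tau)`` to a
leisure bout of ``tau`` seconds.  Three canonical forms are supported:

``linear``
    ``U_L(tau) = C_L * tau`` — constant marginal utility ``C_L`` (utility per
    second).  The subject is indifferent to how a given total leisure time is
    split into bouts.
``log1p``
    ``U_L(tau) = C_L * log(1 + tau)`` — strictly concave, defined at
    ``tau = 0``, with ``U_L(0) = 0``.  This is the default concave form.
``log``
    ``U_L(tau) = C_L * log(tau)`` — strictly concave, divergent at the
    origin.  Retained because the softmax policy it induces is exactly a
    (truncated) gamma distribution.

Utility units are arbitrary; ``C_L`` carries units of utility per second for
the linear form and is a dimensionless multiplier of the logarithm otherwise.
The family is deliberately a small closed contract (value + marginal) so that
other quasi-concave forms can be added without touching the solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class UtilityForm(str, Enum):
    """Functional form of the microscopic utility of leisure."""

    LINEAR = "linear"
    LOG1P = "log1p"
    LOG = "log"


@dataclass(frozen=True)
class LeisureUtility:
    """Microscopic utility of leisure ``U_L(tau)`` and its marginal.

    Parameters
    ----------
    form
        One of :class:`UtilityForm` (or its string value).
    C_L
        Marginal-utility coefficient.  Utility per second for the linear
        form; dimensionless multiplier of the log for the log forms.
    """

    form: UtilityForm
    C_L: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", UtilityForm(self.form))
        object.__setattr__(self, "C_L", float(self.C_L))

    # -- public evaluation ------------------------------------------------

    def evaluate(self, tau):
        """Utility of a leisure bout of duration ``tau`` seconds.

        ``tau`` may be a scalar or array.  Raises :class:`ValueError` for
        negative durations, and for ``tau == 0`` with the pure-log form
        (where the utility diverges).
        """
        tau_arr = np.asarray(tau, dtype=float)
        if np.any(tau_arr < 0):
            raise ValueError("leisure duration must be non-negative")
        if self.form is UtilityForm.LOG and np.any(tau_arr == 0):
            raise ValueError("log utility is undefined at tau = 0")
        out = self._values(tau_arr)
        return out if np.ndim(tau) else float(out)

    def marginal(self, tau):
        """Marginal utility ``dU_L/dtau`` at duration ``tau``."""
        tau_arr = np.asarray(tau, dtype=float)
        if np.any(tau_arr < 0):
            raise ValueError("leisure duration must be non-negative")
        if self.form is UtilityForm.LINEAR:
            out = np.full_like(tau_arr, self.C_L)
        elif self.form is UtilityForm.LOG1P:
            out = self.C_L / (1.0 + tau_arr)
        else:
            if np.any(tau_arr == 0):
                raise ValueError("log utility is undefined at tau = 0")
            out = self.C_L / tau_arr
        return out if np.ndim(tau) else float(out)

    __call__ = evaluate

    # -- internal ---------------------------------------------------------

    def _values(self, tau_arr: np.ndarray) -> np.ndarray:
        """Vectorized values with ``-inf`` at ``tau = 0`` for the pure-log
        form.  Used by the solver, whose densities vanish there anyway."""
        if self.form is UtilityForm.LINEAR:
            return self.C_L * tau_arr
        if self.form is UtilityForm.LOG1P:
            return self.C_L * np.log1p(tau_arr)
        with np.errstate(divide="ignore"):
            return self.C_L * np.log(tau_arr)


def linear(C_L: float) -> LeisureUtility:
    """Linear utility of leisure with constant marginal ``C_L``."""
    return LeisureUtility(UtilityForm.LINEAR, C_L)


def log1p(C_L: float) -> LeisureUtility:
    """Concave ``C_L * log(1 + tau)`` utility (finite at the origin)."""
    return LeisureUtility(UtilityForm.LOG1P, C_L)


def log(C_L: float) -> LeisureUtility:
    """Concave ``C_L * log(tau)`` utility (gamma-policy closed form)."""
    return LeisureUtility(UtilityForm.LOG, C_L)
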