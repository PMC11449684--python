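"""Scalar activation functions and their derivatives.

Nine elementwise nonlinearities are provided: the eight standard ones
(ReLU, Leaky ReLU, Clipped ReLU, ELU, GELU, tanh, softsign, swish) and
the *rectified softsign*,

    F(x) = x / (1 + x)   for x >= 0,      F(x) = 0   for x < 0,

which equals the softsign composed with a ReLU (in either order, since
softsign preserves sign).  The rectified softsign keeps the softsign's
polynomially saturating positive branch — bounded in [0, 1), gentle
gradients far from the origin — while zeroing the negative branch like a
ReLU.

All functions satisfy F(0) = 0 and are applied elementwise with
broadcasting over arrays of any rank; output shape equals input shape.
Derivatives at kinks follow a documented one-sided convention (see
:func:`activate_grad`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "ACTIVATION_NAMES",
    "ActivationSpec",
    "activate",
    "activate_grad",
]

#: Canonical ordering of the nine activation names.
ACTIVATION_NAMES = (
    "relu",
    "leaky_relu",
    "clipped_relu",
    "elu",
    "gelu",
    "tanh",
    "softsign",
    "swish",
    "rectified_softsign",
)

#: exact 1/sqrt(2); the erf argument scale of the exact GELU.
GELU_EXACT_CONSTANT = 1.0 / math.sqrt(2.0)


class ActivationConfigError(ValueError):
    """Raised for an unknown activation name or invalid hyperparameter."""


class ActivationDomainError(ValueError):
    """Raised when an activation is evaluated on non-finite input."""


@dataclass(frozen=True)
class ActivationSpec:
    """Names one of the nine nonlinearities plus its hyperparameters.

    Parameters
    ----------
    name
        One of :data:`ACTIVATION_NAMES`.
    slope
        Negative-branch slope ``a`` of the leaky ReLU.  Ignored by every
        other function.  Default 0.01 (the common toolbox convention).
    ceiling
        Clipping threshold of the clipped ReLU; must be positive.
        Ignored by every other function.  Default 10.0.
    alpha
        ELU saturation parameter; must be positive.  Default 1.0.
    gelu_constant
        Scale of the erf argument in the GELU.  Defaults to the exact
        1/sqrt(2); set to 0.707 for a literal low-precision variant.
    """

    name: str
    slope: float = 0.01
    ceiling: float = 10.0
    alpha: float = 1.0
    gelu_constant: float = field(default=GELU_EXACT_CONSTANT)

    def __post_init__(self) -> None:
        if self.name not in ACTIVATION_NAMES:
            raise ActivationConfigError(
                f"unknown activation {self.name!r}; expected one of "
                f"{', '.join(ACTIVATION_NAMES)}"
            )
        if self.ceiling <= 0:
            raise ActivationConfigError("clipped_relu ceiling must be > 0")
        if self.alpha <= 0:
            raise ActivationConfigError("elu alpha must be > 0")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ActivationDomainError("activation input must be finite")


def activate(spec: ActivationSpec, x):
    """Apply the named activation elementwise.

    Accepts a scalar or an array of any rank; returns the same shape.
    Scalars in, Python floats out.
    """
    arr = np.asarray(x, dtype=np.float64 if np.isscalar(x) else None)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    _check_finite(arr)
    out = _FORWARD[spec.name](spec, arr)
    if np.isscalar(x):
        return float(out)
    return out


def activate_grad(spec: ActivationSpec, x):
    """Derivative dF/dx of the named activation, elementwise.

    At non-differentiable points the one-sided convention is: the
    derivative at ``x = 0`` of relu, clipped_relu and rectified_softsign
    is the right-hand limit (1, 1 and 1 respectively); leaky_relu at 0
    likewise takes its right-hand slope 1; clipped_relu at the ceiling
    takes the right-hand value 0.
    """
    arr = np.asarray(x, dtype=np.float64 if np.isscalar(x) else None)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    _check_finite(arr)
    out = _GRAD[spec.name](spec, arr)
    if np.isscalar(x):
        return float(out)
    return out


# -- forward definitions ----------------------------------------------------

def _relu(spec, x):
    return np.maximum(x, 0.0)


def _leaky_relu(spec, x):
    return np.where(x < 0, spec.slope * x, x)


def _clipped_relu(spec, x):
    return np.clip(x, 0.0, spec.ceiling)


def _elu(spec, x):
    # alpha * (e^x - 1) on the negative branch: continuous at 0 for all alpha
    return np.where(x < 0, spec.alpha * np.expm1(np.minimum(x, 0.0)), x)


def _gelu(spec, x):
    return 0.5 * x * (1.0 + erf(spec.gelu_constant * x))


def _tanh(spec, x):
    return np.tanh(x)


def _softsign(spec, x):
    return x / (1.0 + np.abs(x))


def _swish(spec, x):
    return x * expit(x)


def _rectified_softsign(spec, x):
    return np.where(x < 0, 0.0, x / (1.0 + np.abs(x)))


# -- derivatives ------------------------------------------------------------

def _relu_grad(spec, x):
    return np.where(x >= 0, 1.0, 0.0)


def _leaky_relu_grad(spec, x):
    return np.where(x >= 0, 1.0, spec.slope)


def _clipped_relu_grad(spec, x):
    return np.where((x >= 0) & (x < spec.ceiling), 1.0, 0.0)


def _elu_grad(spec, x):
    return np.where(x < 0, spec.alpha * np.exp(np.minimum(x, 0.0)), 1.0)


def _gelu_grad(spec, x):
    c = spec.gelu_constant
    return 0.5 * (1.0 + erf(c * x)) + x * c * np.exp(-((c * x) ** 2)) / math.sqrt(math.pi)


def _tanh_grad(spec, x):
    t = np.tanh(x)
    return 1.0 - t * t


def _softsign_grad(spec, x):
    d = 1.0 + np.abs(x)
    return 1.0 / (d * d)


def _swish_grad(spec, x):
    s = expit(x)
    return s + x * s * (1.0 - s)


def _rectified_softsign_grad(spec, x):
    d = 1.0 + np.abs(x)
    return np.where(x < 0, 0.0, 1.0 / (d * d))


_FORWARD = {
    "relu": _relu,
    "leaky_relu": _leaky_relu,
    "clipped_relu": _clipped_relu,
    "elu": _elu,
    "gelu": _gelu,
    "tanh": _tanh,
    "softsign": _softsign,
    "swish": _swish,
    "rectified_softsign": _rectified_softsign,
}

_GRAD = {
    "relu": _relu_grad,
    "leaky_relu": _leaky_relu_grad,
    "clipped_relu": _clipped_relu_grad,
    "elu": _elu_grad,
    "gelu": _gelu_grad,
    "tanh": _tanh_grad,
    "softsign": _softsign_grad,
    "swish": _swish_grad,
    "rectified_softsign": _rectified_softsign_grad,
}
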