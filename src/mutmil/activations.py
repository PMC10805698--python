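"""Adaptive activation functions with trainable curvature.

Three smooth activations built from a single primitive, the adaptive
square root ``ASR(x, a) = sqrt(exp(a) + x^2)``:

* ``ARU(x, a) = 0.5 * (x + ASR(x, a))`` — a smooth rectifier that tends to
  ReLU as ``a -> -inf`` and is strictly positive for finite inputs.
* ``ASU(x, a_lo, a_hi) = (x + ASR(x, a_lo)) / (ASR(x, a_lo) + ASR(x, a_hi))``
  — a sigmoid-like unit strictly inside (0, 1); the two curvature
  parameters shape the approach to each bound independently.

The input enters only as ``x**2``, never as ``exp(x)``, so the functions
cannot overflow no matter how large the aggregated values get — a property
that matters when summing activated features over bags with many instances.

Curvature parameters are trainable. Defaults are tuned so that at
initialization ARU matches softplus and ASU matches the logistic sigmoid
at x = 0 in both value and slope:

* ARU(0, a0) = 0.5 * exp(a0 / 2) = ln 2  =>  ``ARU_ALPHA0 = 2 ln(2 ln 2)``
* ASU slope at 0 with equal alphas is ``1 / (2 exp(a0/2))``; setting it to
  the sigmoid's 1/4 gives ``ASU_ALPHA0 = 2 ln 2`` (value 0.5 by symmetry).

Scalar/numpy forms are exposed for analysis; the same formulas applied to
:class:`~mutmil.autodiff.Tensor` inputs are differentiable, including with
respect to the alphas.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = ["asr", "aru", "asu", "ARU_ALPHA0", "ASU_ALPHA0"]

#: Default ARU curvature: matches softplus at x=0 (value ln 2).
ARU_ALPHA0: float = 2.0 * math.log(2.0 * math.log(2.0))

#: Default ASU curvature (both bounds): matches sigmoid value 1/2 and
#: slope 1/4 at x=0.
ASU_ALPHA0: float = 2.0 * math.log(2.0)


def _exp(a):
    return a.exp() if isinstance(a, Tensor) else np.exp(a)


def _sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def asr(x, alpha):
    """Adaptive square root: ``sqrt(exp(alpha) + x**2)``.

    Smooth everywhere, always >= |x|, and tends to |x| as alpha -> -inf.
    Works on floats, numpy arrays, or Tensors (broadcasting applies).
    """
    return _sqrt(_exp(alpha) + x * x)


def aru(x, alpha):
    """Adaptive rectifying unit: ``0.5 * (x + asr(x, alpha))``.

    Strictly positive for finite x, monotone increasing, and approaches
    ReLU as alpha -> -inf while staying differentiable everywhere.
    """
    return 0.5 * (x + asr(x, alpha))


def asu(x, alpha_lower, alpha_upper):
    """Adaptive sigmoid unit, bounded by (0, 1).

    ``(x + asr(x, alpha_lower)) / (asr(x, alpha_lower) + asr(x, alpha_upper))``

    The lower/upper alphas control the curvature approaching 0 and 1
    respectively; with equal alphas the function is point-symmetric about
    (0, 1/2) like the logistic sigmoid.
    """
    lo = asr(x, alpha_lower)
    hi = asr(x, alpha_upper)
    return (x + lo) / (lo + hi)
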