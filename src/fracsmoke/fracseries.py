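"""Algebra of truncated fractional power series.

A :class:`FracBasisSeries` is a finite expansion

.. math::

    f(t) = \\sum_{k=0}^{R} c_k \\, e_k(t), \\qquad
    e_k(t) = \\frac{t^{k\\chi}}{\\Gamma(k\\chi + 1)},

at one fixed fractional order ``chi`` in (0, 1].  This basis is closed under
the operations the q-HATM recursion needs:

* products: ``e_i * e_j = B(i, j; chi) * e_{i+j}`` with the Gamma-ratio
  coefficient ``B(i, j; chi) = Gamma((i+j)chi+1) / (Gamma(i chi+1) Gamma(j chi+1))``,
* the Atangana-Baleanu fractional integral, which acts linearly on the basis as
  ``e_k -> (1/K) * ((1-chi) e_k + chi e_{k+1})``.

At ``chi = 1`` the basis degenerates to ``t^k / k!`` and the series is an
ordinary Maclaurin polynomial; the AB integral then reduces to plain
antidifferentiation with zero constant.

All operations silently truncate at the series' truncation order ``R``: terms
that would land above ``e_R`` are discarded.  The solver chooses ``R`` at least
as large as the number of iterations, so nothing is lost at the orders it
reports (the order-``r`` solution term has basis degree at most ``r``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "FracBasisSeries",
    "IncompatibleSeriesError",
    "DomainError",
    "make_constant",
    "basis_element",
    "add",
    "scale",
    "multiply",
    "ab_integral",
    "evaluate",
    "evaluate_grid",
    "gamma_ratio",
    "to_json",
    "from_json",
]


class IncompatibleSeriesError(ValueError):
    """Two series with different chi, K or truncation order were combined."""


class DomainError(ValueError):
    """Evaluation requested outside the domain t >= 0."""


@dataclass(frozen=True)
class FracBasisSeries:
    """Truncated series sum_k c_k t^(k*chi)/Gamma(k*chi+1) at fixed chi.

    Parameters
    ----------
    chi
        Fractional order, in (0, 1].
    kcap
        Normalization value K(chi) > 0 of the AB operator (conventionally 1).
    coeffs
        Coefficients ``c_0 .. c_R``; the length fixes the truncation order R.
    """

    chi: float
    kcap: float
    coeffs: tuple[float, ...] = field(default=(0.0,))

    def __post_init__(self) -> None:
        if not (0.0 < self.chi <= 1.0):
            raise DomainError(f"fractional order chi={self.chi} outside (0, 1]")
        if not (self.kcap > 0.0 and math.isfinite(self.kcap)):
            raise DomainError(f"normalization K={self.kcap} must be a positive real")
        coeffs = tuple(float(c) for c in self.coeffs)
        if len(coeffs) == 0:
            raise ValueError("a series needs at least the constant coefficient c_0")
        if not all(math.isfinite(c) for c in coeffs):
            raise ValueError("series coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def trunc_order(self) -> int:
        """Index bound R of retained basis elements."""
        return len(self.coeffs) - 1

    def degree(self) -> int:
        """Largest k with c_k != 0, or 0 for the zero series."""
        for k in range(self.trunc_order, -1, -1):
            if self.coeffs[k] != 0.0:
                return k
        return 0

    # Operator sugar; the module-level functions are the primary API.
    def __add__(self, other: "FracBasisSeries") -> "FracBasisSeries":
        return add(self, other)

    def __mul__(self, other):
        if isinstance(other, FracBasisSeries):
            return multiply(self, other)
        return scale(self, float(other))

    __rmul__ = __mul__

    def __neg__(self) -> "FracBasisSeries":
        return scale(self, -1.0)

    def __sub__(self, other: "FracBasisSeries") -> "FracBasisSeries":
        return add(self, scale(other, -1.0))

    def __call__(self, t: float) -> float:
        return evaluate(self, t)


def _check_compatible(a: FracBasisSeries, b: FracBasisSeries) -> None:
    if a.chi != b.chi or a.kcap != b.kcap or a.trunc_order != b.trunc_order:
        raise IncompatibleSeriesError(
            "series disagree in (chi, K, trunc_order): "
            f"({a.chi}, {a.kcap}, {a.trunc_order}) vs ({b.chi}, {b.kcap}, {b.trunc_order})"
        )


def make_constant(value: float, chi: float, kcap: float, trunc_order: int) -> FracBasisSeries:
    """Series with c_0 = value and all higher coefficients zero."""
    if trunc_order < 0:
        raise ValueError("trunc_order must be >= 0")
    if not math.isfinite(value):
        raise ValueError("constant value must be finite")
    coeffs = (float(value),) + (0.0,) * trunc_order
    return FracBasisSeries(chi=chi, kcap=kcap, coeffs=coeffs)


def basis_element(k: int, chi: float, kcap: float, trunc_order: int) -> FracBasisSeries:
    """The basis series e_k = t^(k*chi)/Gamma(k*chi+1) (k <= trunc_order)."""
    if not (0 <= k <= trunc_order):
        raise ValueError(f"basis index {k} outside [0, {trunc_order}]")
    coeffs = [0.0] * (trunc_order + 1)
    coeffs[k] = 1.0
    return FracBasisSeries(chi=chi, kcap=kcap, coeffs=tuple(coeffs))


def add(a: FracBasisSeries, b: FracBasisSeries) -> FracBasisSeries:
    """Coefficientwise sum of two compatible series."""
    _check_compatible(a, b)
    coeffs = tuple(x + y for x, y in zip(a.coeffs, b.coeffs))
    return FracBasisSeries(chi=a.chi, kcap=a.kcap, coeffs=coeffs)


def scale(a: FracBasisSeries, s: float) -> FracBasisSeries:
    """Scalar multiple of a series."""
    return FracBasisSeries(chi=a.chi, kcap=a.kcap, coeffs=tuple(s * c for c in a.coeffs))


def gamma_ratio(i: int, j: int, chi: float) -> float:
    """Product coefficient B(i, j; chi) = Γ((i+j)χ+1) / (Γ(iχ+1) Γ(jχ+1)).

    At chi = 1 this is the binomial coefficient C(i+j, i).  Computed via
    log-Gamma so large indices do not overflow.
    """
    return float(
        np.exp(gammaln((i + j) * chi + 1.0) - gammaln(i * chi + 1.0) - gammaln(j * chi + 1.0))
    )


def multiply(a: FracBasisSeries, b: FracBasisSeries) -> FracBasisSeries:
    """Cauchy product in the e_k basis, truncated at the shared order R.

    Pointwise exact: evaluate(multiply(a, b), t) equals
    evaluate(a, t) * evaluate(b, t) whenever degree(a) + degree(b) <= R.
    """
    _check_compatible(a, b)
    R = a.trunc_order
    out = [0.0] * (R + 1)
    for i, ca in enumerate(a.coeffs):
        if ca == 0.0:
            continue
        for j, cb in enumerate(b.coeffs):
            if cb == 0.0 or i + j > R:
                continue
            out[i + j] += ca * cb * gamma_ratio(i, j, a.chi)
    return FracBasisSeries(chi=a.chi, kcap=a.kcap, coeffs=tuple(out))


def ab_integral(a: FracBasisSeries) -> FracBasisSeries:
    """Atangana-Baleanu fractional integral, exactly on the basis.

    The AB integral of g is ``(1-chi)/K * g + chi/(K Gamma(chi)) *
    int_0^t g(v)(t-v)^(chi-1) dv``; on the basis this is the linear map
    ``e_k -> (1/K)((1-chi) e_k + chi e_{k+1})``.  The spill term ``e_{R+1}``
    is discarded by truncation.  At chi = 1, K = 1 it is ordinary
    antidifferentiation with zero constant.
    """
    R = a.trunc_order
    out = [0.0] * (R + 1)
    w0 = (1.0 - a.chi) / a.kcap
    w1 = a.chi / a.kcap
    for k, c in enumerate(a.coeffs):
        if c == 0.0:
            continue
        out[k] += w0 * c
        if k + 1 <= R:
            out[k + 1] += w1 * c
    return FracBasisSeries(chi=a.chi, kcap=a.kcap, coeffs=tuple(out))


def evaluate(a: FracBasisSeries, t: float) -> float:
    """Value of the series at time t >= 0.

    Uses exp(k*chi*log t - logGamma(k*chi+1)) for t > 0; at t = 0 only the
    constant term survives (e_k(0) = delta_{k0}).
    """
    if t < 0:
        raise DomainError(f"t={t} < 0: fractional powers undefined for negative time")
    if t == 0.0:
        return a.coeffs[0]
    c = np.asarray(a.coeffs)
    k = np.arange(len(c))
    logs = k * a.chi * math.log(t) - gammaln(k * a.chi + 1.0)
    return float(np.sum(c * np.exp(logs)))


def evaluate_grid(a: FracBasisSeries, t_grid) -> np.ndarray:
    """Vectorized :func:`evaluate` over a grid of non-negative times."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise DomainError("t_grid contains negative times")
    c = np.asarray(a.coeffs)
    k = np.arange(len(c))
    out = np.full(t.shape, a.coeffs[0], dtype=float)
    pos = t > 0
    if np.any(pos):
        logs = np.outer(np.log(t[pos]), k * a.chi) - gammaln(k * a.chi + 1.0)
        out[pos] = np.exp(logs) @ c
    return out


def to_json(a: FracBasisSeries) -> str:
    """Serialize as ``{"chi": ..., "K": ..., "coeffs": [...]}``."""
    return json.dumps({"chi": a.chi, "K": a.kcap, "coeffs": list(a.coeffs)})


def from_json(s: str) -> FracBasisSeries:
    d = json.loads(s)
    return FracBasisSeries(chi=d["chi"], kcap=d["K"], coeffs=tuple(d["coeffs"]))
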