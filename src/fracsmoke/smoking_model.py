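"""Five-compartment tobacco-use model with a snuffing class.

The population splits into susceptible smokers M, a snuffing (smokeless
tobacco) class L, irregular smokers N, regular smokers O and quitters P.
The integer-order dynamics are

    dM/dt = theta - chi1*M*L - lam*M + beta*O
    dL/dt = chi1*M*L - chi2*L*N - (mu + lam)*L
    dN/dt = chi2*L*N - (sigma + gamma + lam)*N
    dO/dt = gamma*N - (beta + rho + lam)*O
    dP/dt = rho*O - lam*P

and the fractional variant replaces d/dt by the Atangana-Baleanu-Caputo
derivative of order chi.  The right-hand side is constant + linear +
bilinear, which is what makes the homotopy-polynomial expansion in
:func:`homotopy_term` a finite convolution.

Summing the equations gives the bookkeeping identity

    sum_i rhs_i = theta - lam*(M+L+N+O+P) - mu*L - sigma*N

(recruitment minus natural deaths minus the two tobacco-attributable death
flows), exposed as :func:`conservation_rhs` and used as an exact invariant
in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

from . import fracseries as fs
from .fracseries import FracBasisSeries

__all__ = [
    "ModelParams",
    "InitialState",
    "StateVector",
    "COMPARTMENTS",
    "rhs",
    "rhs_series",
    "conservation_rhs",
    "homotopy_term",
]

#: Compartment labels, in state-vector order.
COMPARTMENTS = ("M", "L", "N", "O", "P")


class StateVector(NamedTuple):
    """Compartment sizes at one time point.

    Negative entries are legal: truncated series solutions may undershoot
    zero, and that is reported as a diagnostic rather than clamped.
    """

    M: float
    L: float
    N: float
    O: float
    P: float


@dataclass(frozen=True)
class ModelParams:
    """The nine non-negative rate constants.

    theta  : recruitment rate (birth or migration) per unit time
    chi1   : susceptible -> snuffing contact rate
    chi2   : snuffing -> irregular-smoker contact rate
    gamma  : irregular -> regular smoker rate
    rho    : quit rate (regular -> quit)
    lam    : natural death rate
    beta   : relapse rate (quit -> susceptible)
    mu     : extra death rate of the snuffing class due to tobacco use
    sigma  : death rate from smoking-related disease (irregular smokers)
    """

    theta: float = 0.1
    chi1: float = 0.003
    chi2: float = 0.002
    gamma: float = 0.004
    rho: float = 0.05
    lam: float = 0.002
    beta: float = 0.003
    mu: float = 0.003
    sigma: float = 0.003

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"rate {name}={value} must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        """Build from config keys; accepts 'lambda' as an alias for lam."""
        d = dict(d)
        if "lambda" in d:
            d["lam"] = d.pop("lambda")
        return cls(**d)


@dataclass(frozen=True)
class InitialState:
    """Compartment sizes at t = 0 (defaults: 68, 40, 30, 20, 15)."""

    M0: float = 68.0
    L0: float = 40.0
    N0: float = 30.0
    O0: float = 20.0
    P0: float = 15.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"initial size {name}={value} must be non-negative")

    def as_state(self) -> StateVector:
        return StateVector(self.M0, self.L0, self.N0, self.O0, self.P0)

    @classmethod
    def variant_quit_swapped(cls) -> "InitialState":
        """Variant initial data with the regular and quit compartments
        interchanged (O0 = 15, P0 = 20), which circulates in some
        restatements of this model.  The defaults are the set consistent
        with the first-order series coefficients."""
        return cls(O0=15.0, P0=20.0)

    @classmethod
    def from_dict(cls, d: dict) -> "InitialState":
        return cls(**d)


def rhs(state: Sequence[float], params: ModelParams) -> StateVector:
    """Right-hand side of the integer-order system at one state."""
    M, L, N, O, P = state
    p = params
    return StateVector(
        p.theta - p.chi1 * M * L - p.lam * M + p.beta * O,
        p.chi1 * M * L - p.chi2 * L * N - (p.mu + p.lam) * L,
        p.chi2 * L * N - (p.sigma + p.gamma + p.lam) * N,
        p.gamma * N - (p.beta + p.rho + p.lam) * O,
        p.rho * O - p.lam * P,
    )


def conservation_rhs(state: Sequence[float], params: ModelParams) -> float:
    """theta - lam*(M+L+N+O+P) - mu*L - sigma*N.

    Equals sum(rhs(state)) identically; computed here from the population
    totals so the two sides are independent.
    """
    M, L, N, O, P = state
    total = M + L + N + O + P
    return params.theta - params.lam * total - params.mu * L - params.sigma * N


def rhs_series(
    state: Sequence[FracBasisSeries], params: ModelParams
) -> tuple[FracBasisSeries, ...]:
    """Right-hand side applied to series-valued compartments.

    Products use the fractional-basis Cauchy product, so the result is the
    series expansion of rhs along the solution, truncated at the shared
    truncation order.  Used by the residual diagnostic.
    """
    M, L, N, O, P = state
    proto = M
    p = params
    theta = fs.make_constant(p.theta, proto.chi, proto.kcap, proto.trunc_order)
    ML = fs.multiply(M, L)
    LN = fs.multiply(L, N)
    return (
        theta + (-p.chi1) * ML + (-p.lam) * M + p.beta * O,
        p.chi1 * ML + (-p.chi2) * LN + (-(p.mu + p.lam)) * L,
        p.chi2 * LN + (-(p.sigma + p.gamma + p.lam)) * N,
        p.gamma * N + (-(p.beta + p.rho + p.lam)) * O,
        p.rho * O + (-p.lam) * P,
    )


def homotopy_term(
    r: int,
    history: Sequence[Sequence[FracBasisSeries]],
    params: ModelParams,
    n: int = 1,
) -> tuple[FracBasisSeries, ...]:
    """Order-(r-1) homotopy polynomial F_{r-1} of the right-hand side.

    ``history`` holds the solution terms of orders 0..r-1, each a 5-sequence
    of series.  Bilinear terms expand into convolutions over the history
    (e.g. sum_{i=0}^{r-1} M_i * L_{r-1-i}); linear terms act on index r-1.
    The constant source theta carries the homotopy factor (1 - k_r/n),
    which is 1 at r = 1 and 0 for r >= 2 (k_r = n there), so it enters
    F_0 only.
    """
    if r < 1:
        raise ValueError("homotopy terms start at r=1; order 0 is the initial data")
    if len(history) < r:
        raise ValueError(f"history has {len(history)} orders, need 0..{r - 1}")
    p = params
    proto = history[0][0]
    zero = fs.make_constant(0.0, proto.chi, proto.kcap, proto.trunc_order)

    conv_ML = zero
    conv_LN = zero
    for i in range(r):
        conv_ML = conv_ML + fs.multiply(history[i][0], history[r - 1 - i][1])
        conv_LN = conv_LN + fs.multiply(history[i][1], history[r - 1 - i][2])

    M_, L_, N_, O_, P_ = history[r - 1]
    source = p.theta if r == 1 else 0.0  # factor (1 - k_r/n)
    theta = fs.make_constant(source, proto.chi, proto.kcap, proto.trunc_order)
    return (
        theta + (-p.chi1) * conv_ML + (-p.lam) * M_ + p.beta * O_,
        p.chi1 * conv_ML + (-p.chi2) * conv_LN + (-(p.mu + p.lam)) * L_,
        p.chi2 * conv_LN + (-(p.sigma + p.gamma + p.lam)) * N_,
        p.gamma * N_ + (-(p.beta + p.rho + p.lam)) * O_,
        p.rho * O_ + (-p.lam) * P_,
    )
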