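"""Independent reference computations and synthetic fixtures.

Everything here is deliberately implemented without touching the
fractional-series algebra or the q-HATM recursion, so that agreement
between a solver result and an oracle is evidence rather than tautology:

* :func:`taylor_oracle` — Maclaurin coefficients of a quadratic ODE system
  by the exact integer-order recursion, using plain polynomial arithmetic;
* :func:`rk4_solve` — classical fixed-step fourth-order Runge-Kutta;
* :func:`ab_integral_quadrature` — the Atangana-Baleanu integral evaluated
  from its defining weakly-singular integral by adaptive quadrature, with a
  substitution that removes the endpoint singularity;
* :func:`random_model` — seeded small random quadratic systems;
* :func:`smoking_system_spec` — the five-compartment smoking model expressed
  as a :class:`QuadraticSystemSpec` (the default fixture).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from .smoking_model import InitialState, ModelParams

__all__ = [
    "QuadraticSystemSpec",
    "taylor_oracle",
    "rk4_solve",
    "ab_integral_quadrature",
    "random_model",
    "smoking_system_spec",
    "spec_to_json",
    "spec_from_json",
]


@dataclass
class QuadraticSystemSpec:
    """An autonomous ODE system x' = c + A x + quadratic terms.

    ``bilinear`` is a sparse list of ``(i, j, k, w)`` entries meaning that
    equation i gains the term ``w * x_j * x_k``.  The smoking model is one
    instance (dimension 5, two bilinear interactions per infection-like
    contact).
    """

    dim: int
    const: np.ndarray
    linear: np.ndarray
    bilinear: list[tuple[int, int, int, float]]
    x0: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.const = np.asarray(self.const, dtype=float)
        self.linear = np.asarray(self.linear, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        assert self.const.shape == (self.dim,)
        assert self.linear.shape == (self.dim, self.dim)
        assert self.x0.shape == (self.dim,)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        out = self.const + self.linear @ x
        for i, j, k, w in self.bilinear:
            out[i] += w * x[j] * x[k]
        return out


def smoking_system_spec(
    params: ModelParams | None = None, init: InitialState | None = None
) -> QuadraticSystemSpec:
    """The smoking model as a quadratic system (default fixture)."""
    p = params or ModelParams()
    ic = init or InitialState()
    A = np.array(
        [
            [-p.lam, 0, 0, p.beta, 0],
            [0, -(p.mu + p.lam), 0, 0, 0],
            [0, 0, -(p.sigma + p.gamma + p.lam), 0, 0],
            [0, 0, p.gamma, -(p.beta + p.rho + p.lam), 0],
            [0, 0, 0, p.rho, -p.lam],
        ]
    )
    bil = [
        (0, 0, 1, -p.chi1),
        (1, 0, 1, p.chi1),
        (1, 1, 2, -p.chi2),
        (2, 1, 2, p.chi2),
    ]
    return QuadraticSystemSpec(
        dim=5,
        const=np.array([p.theta, 0, 0, 0, 0]),
        linear=A,
        bilinear=bil,
        x0=np.array(ic.as_state()),
        name="smoking_default",
    )


def taylor_oracle(spec: QuadraticSystemSpec, order: int) -> np.ndarray:
    """Maclaurin coefficients a_0..a_order of the classical solution.

    Exact power-series recursion for x(t) = sum_r a_r t^r:

        (r+1) a_{r+1} = c delta_{r0} + A a_r
                        + sum over bilinear (i,j,k,w):
                          w * sum_{m=0}^{r} (a_m)_j (a_{r-m})_k  -> eq i

    Returns an array of shape (order+1, dim).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    a = np.zeros((order + 1, spec.dim))
    a[0] = spec.x0
    for r in range(order):
        nxt = spec.linear @ a[r]
        if r == 0:
            nxt = nxt + spec.const
        for i, j, k, w in spec.bilinear:
            nxt[i] += w * sum(a[m, j] * a[r - m, k] for m in range(r + 1))
        a[r + 1] = nxt / (r + 1)
    return a


def rk4_solve(spec: QuadraticSystemSpec, t_grid, step: float = 1e-3) -> np.ndarray:
    """Classical fixed-step RK4 trajectory at the requested grid points.

    Each grid interval is covered by substeps of size at most ``step``.
    Returns an array of shape (len(t_grid), dim); t_grid must be
    non-decreasing and start at t >= 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    if np.any(np.diff(t_grid) < 0) or (len(t_grid) and t_grid[0] < 0):
        raise ValueError("t_grid must be non-decreasing and non-negative")
    out = np.empty((len(t_grid), spec.dim))
    x = spec.x0.copy()
    t = 0.0
    for idx, t_target in enumerate(t_grid):
        span = t_target - t
        if span > 0:
            nsub = max(1, math.ceil(span / step))
            dt = span / nsub
            for _ in range(nsub):
                k1 = spec.rhs(x)
                k2 = spec.rhs(x + 0.5 * dt * k1)
                k3 = spec.rhs(x + 0.5 * dt * k2)
                k4 = spec.rhs(x + dt * k3)
                x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t = t_target
        out[idx] = x
    return out


def ab_integral_quadrature(f, chi: float, kcap: float, t: float) -> float:
    """Atangana-Baleanu integral of f at t, from the defining integral.

    I[f](t) = (1-chi)/K * f(t) + chi/(K Gamma(chi)) * int_0^t f(v)(t-v)^(chi-1) dv.

    The weakly singular kernel is removed with u = (t-v)^chi, giving
    int_0^t f(v)(t-v)^(chi-1) dv = (1/chi) int_0^{t^chi} f(t - u^(1/chi)) du,
    which adaptive quadrature handles to ~1e-10 relative error for smooth f.
    """
    if not (0.0 < chi <= 1.0):
        raise ValueError(f"chi={chi} outside (0, 1]")
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0.0:
        return (1.0 - chi) / kcap * f(0.0)
    inner, _ = quad(
        lambda u: f(t - u ** (1.0 / chi)),
        0.0,
        t**chi,
        epsabs=1e-12,
        epsrel=1e-11,
        limit=200,
    )
    return (1.0 - chi) / kcap * f(t) + inner / (kcap * gamma_fn(chi))


def random_model(seed: int) -> QuadraticSystemSpec:
    """Seeded small random quadratic system (dim <= 4, entries in [-1, 1]).

    Bounded coefficients and initial states keep the solution series
    well-behaved on t in [0, 0.5], so Taylor/RK4 comparisons converge.
    """
    rng = np.random.default_rng(seed)
    d = int(rng.integers(2, 5))
    const = rng.uniform(-1, 1, d)
    linear = rng.uniform(-1, 1, (d, d))
    n_bil = int(rng.integers(1, 2 * d))
    bilinear = [
        (
            int(rng.integers(d)),
            int(rng.integers(d)),
            int(rng.integers(d)),
            float(rng.uniform(-1, 1)),
        )
        for _ in range(n_bil)
    ]
    x0 = rng.uniform(-1, 1, d)
    return QuadraticSystemSpec(
        dim=d, const=const, linear=linear, bilinear=bilinear, x0=x0,
        name=f"random_{seed}",
    )


def spec_to_json(spec: QuadraticSystemSpec) -> str:
    return json.dumps(
        {
            "name": spec.name,
            "dim": spec.dim,
            "const": spec.const.tolist(),
            "linear": spec.linear.tolist(),
            "bilinear": [list(b) for b in spec.bilinear],
            "x0": spec.x0.tolist(),
        }
    )


def spec_from_json(s: str) -> QuadraticSystemSpec:
    d = json.loads(s)
    return QuadraticSystemSpec(
        dim=d["dim"],
        const=np.array(d["const"]),
        linear=np.array(d["linear"]),
        bilinear=[(int(i), int(j), int(k), float(w)) for i, j, k, w in d["bilinear"]],
        x0=np.array(d["x0"]),
        name=d.get("name", ""),
    )
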