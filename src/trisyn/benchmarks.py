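"""Reference signals with known dynamical and informational properties.

Every generator returns a :class:`BenchmarkSeries` whose
``known_properties`` map records the reference values the series is
meant to exhibit (analytic where available, from converged numerical
estimates otherwise), so estimator tests can consume them directly.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BenchmarkSeries:
    name: str
    parameters: dict
    seed: int
    values: np.ndarray
    known_properties: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.name}: non-finite values")
        self.values = v


def logistic_map(r: float, x0: float, n: int, discard: int = 0) -> BenchmarkSeries:
    """Iterates of x -> r x (1 - x).

    For r = 4 the map is fully chaotic with Lyapunov exponent ln 2 per
    iterate; for r = 3.2 the orbit settles on a stable period-2 cycle
    (negative exponent).  No transient is discarded by default, so the
    convergent approach to an attractor is part of the series.
    """
    if not (0.0 < x0 < 1.0):
        raise ValueError("x0 must lie in (0, 1)")
    if not (0.0 < r <= 4.0):
        raise ValueError("r must lie in (0, 4]")
    total = n + discard
    x = np.empty(total)
    x[0] = x0
    for i in range(total - 1):
        x[i + 1] = r * x[i] * (1.0 - x[i])
    props = {}
    if r == 4.0:
        props["max_lyapunov"] = {"value": math.log(2.0), "tol": 0.1 * math.log(2.0),
                                 "note": "analytic, fully chaotic logistic map"}
    if r == 3.2:
        props["max_lyapunov_sign"] = {"value": -1, "note": "stable period-2 cycle"}
    return BenchmarkSeries("logistic_map", {"r": r, "x0": x0, "n": n}, 0,
                           x[discard:], props)


def henon_map(a: float = 1.4, b: float = 0.3, n: int = 10000, seed: int = 0,
              discard: int = 1000, max_retries: int = 20) -> BenchmarkSeries:
    """x-component of the Hénon map after transient discard.

    At the canonical (a, b) = (1.4, 0.3) the attractor has correlation
    dimension ~1.2.  Diverging orbits restart from a fresh seeded initial
    condition (bounded retries).
    """
    if n < 1000:
        raise ValueError("need n >= 1000")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        u, v = rng.uniform(-0.1, 0.1, 2)
        xs = np.empty(n + discard)
        ok = True
        for i in range(n + discard):
            u, v = 1.0 - a * u * u + v, b * u
            if abs(u) > 1e6:
                ok = False
                break
            xs[i] = u
        if ok:
            props = {
                "correlation_dimension": {"value": 1.2, "tol": 0.1,
                                          "note": "numeric estimate, canonical parameters"},
                "embedding_dimension": {"value": 2, "note": "planar map"},
            }
            return BenchmarkSeries("henon_map", {"a": a, "b": b, "n": n}, seed,
                                   xs[discard:], props)
    raise RuntimeError("Hénon orbit diverged for all retried initial conditions")


def lorenz_series(sigma: float = 10.0, rho: float = 28.0, beta: float = 8.0 / 3.0,
                  dt: float = 0.02, n: int = 10000,
                  initial=(1.0, 1.0, 1.0), discard_time: float = 10.0) -> BenchmarkSeries:
    """x-component of the Lorenz system, fixed-step RK4 integration.

    The classical parameters give the chaotic butterfly attractor, which
    a delay embedding needs three dimensions to unfold; rho < 1 decays to
    the origin.
    """
    if dt > 0.02:
        raise ValueError("dt must be <= 0.02")
    discard = int(round(discard_time / dt))

    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    s = np.array(initial, dtype=float)
    xs = np.empty(n + discard)
    for i in range(n + discard):
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(s)):
            raise RuntimeError("non-finite Lorenz state")
        xs[i] = s[0]
    props = {}
    if rho > 24.74:
        props["embedding_dimension"] = {"value": 3, "note": "chaotic attractor"}
    if rho < 1.0:
        props["fixed_point"] = {"value": 0.0, "note": "origin globally stable below rho=1"}
    return BenchmarkSeries("lorenz", {"sigma": sigma, "rho": rho, "beta": beta,
                                      "dt": dt, "n": n}, 0, xs[discard:], props)


def noisy_sine(period: float = 100.0, n: int = 20000, noise: float = 0.1,
               seed: int = 0) -> BenchmarkSeries:
    """Sine wave with additive Gaussian observation noise.

    The workhorse limit-cycle benchmark: the AMI delay sits at a quarter
    period, two embedding dimensions suffice, the correlation dimension
    is 1 and the Lyapunov exponent is zero.  ``period`` need not be an
    integer number of samples (and for correlation-sum tests should not
    be, to avoid exact sample-grid recurrences).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    x = np.sin(2.0 * np.pi * t / period) + noise * rng.standard_normal(n)
    return BenchmarkSeries("noisy_sine", {"period": period, "noise": noise, "n": n},
                           seed, x,
                           {"ami_delay": {"value": period / 4.0, "tol": 2,
                                          "note": "quarter period"},
                            "embedding_dimension": {"value": 2, "note": "limit cycle"}})


def _binary_entropy(p: float) -> float:
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def exact_te_coupled_binary(coupling: float) -> float:
    """Exact TE(X -> Y) for the coupled binary pair, by enumeration.

    X is i.i.d. fair binary and Y(t+1) copies X(t) with probability c,
    else flips a fair coin.  The exact joint law of
    (X_t, Y_t, Y_{t+1}) is enumerated and the conditional mutual
    information I(Y_{t+1}; X_t | Y_t) computed from it.
    """
    c = coupling
    joint = {}
    for x in (0, 1):
        for y in (0, 1):
            for yn in (0, 1):
                p_yn = c * (1.0 if yn == x else 0.0) + (1 - c) * 0.5
                joint[(x, y, yn)] = 0.25 * p_yn  # X_t, Y_t independent, each fair
    te = 0.0
    for y in (0, 1):
        p_y = sum(joint[(x, y, yn)] for x in (0, 1) for yn in (0, 1))
        for x in (0, 1):
            for yn in (0, 1):
                p = joint[(x, y, yn)]
                if p == 0:
                    continue
                p_x_y = sum(joint[(x, y, k)] for k in (0, 1))
                p_yn_y = sum(joint[(k, y, yn)] for k in (0, 1))
                te += p * math.log2(p * p_y / (p_x_y * p_yn_y))
    return max(0.0, te)


def coupled_binary_processes(coupling: float, n: int, seed: int = 0):
    """Driver/driven binary pair with exactly known transfer entropy.

    Returns ``(x_series, y_series)`` as BenchmarkSeries; the driver X is
    i.i.d. fair binary and Y(t+1) = X(t) with probability ``coupling``,
    otherwise a fresh fair coin.  ``known_properties`` carries the exact
    TE in both directions (closed form: ``1 - H_b((1+c)/2)`` forward,
    0 backward).
    """
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    copy = rng.random(n) < coupling
    noise = rng.integers(0, 2, n)
    y = np.empty(n, dtype=np.int64)
    y[0] = rng.integers(0, 2)
    y[1:] = np.where(copy[:-1], x[:-1], noise[:-1])
    te_exact = exact_te_coupled_binary(coupling)
    props = {
        "te_forward": {"value": te_exact, "tol": 0.01,
                       "note": "exact by enumeration; equals 1 - H_b((1+c)/2)"},
        "te_backward": {"value": 0.0, "tol": 0.01, "note": "no reverse coupling"},
    }
    params = {"coupling": coupling, "n": n}
    return (BenchmarkSeries("coupled_binary_x", params, seed, x.astype(float), props),
            BenchmarkSeries("coupled_binary_y", params, seed, y.astype(float), props))


def theta_poisson_trains(theta_freq: float = 8.0, gamma_freq: float = 40.0,
                         rate: float = 40.0, duration: float = 10000.0,
                         n_trains: int = 8, seed: int = 0) -> list[np.ndarray]:
    """Theta-nested gamma Poisson spike trains (estimator fixtures).

    Same statistical contract as the simulator's stochastic drive
    generator, exposed directly so spike-train estimators can be
    validated on input with a known rhythmic structure.
    """
    from .config import DriveSpec
    from .dynamics import generate_drive_trains

    spec = DriveSpec(source="EC2", theta_frequency=theta_freq,
                     gamma_frequency=gamma_freq, mean_rate=rate, seed=seed,
                     n_fibers=n_trains, deterministic=False)
    return generate_drive_trains(spec, n_trains, duration, 0.1)
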