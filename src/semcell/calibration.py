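"""Uncertainty quantification and parameter fitting.

A polynomial-chaos expansion (PCE) surrogate of the indentation force–time
output is built by least-squares point collocation in a basis orthonormal
with respect to independent Normal priors (probabilists' Hermite
polynomials in the standardized variables).  The PCE coefficients yield the
output mean, standard deviation and first-order Sobol indices per time
point.  Calibration minimizes the RMSE between a simulated and a target
force curve with the derivative-free Nelder–Mead simplex.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ParameterPrior",
    "default_priors",
    "basis_size",
    "multi_indices",
    "sample_design",
    "PceSurrogate",
    "build_pce",
    "moments_and_sobol",
    "rmse_cost",
    "FitResult",
    "fit_parameters",
    "make_indentation_runner",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterPrior:
    """Independent Normal prior, N(mu, sigma), sigma defaulting to 0.1 mu."""

    name: str
    mu: float
    sigma: float | None = None

    def __post_init__(self):
        if self.sigma is None:
            object.__setattr__(self, "sigma", 0.1 * abs(self.mu))
        if self.sigma <= 0:
            raise ValueError(f"prior sigma for {self.name} must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.normal(self.mu, self.sigma, size=n)
        if self.mu > 0:
            # physical positivity: a Normal tail below zero is
            # astronomically unlikely at sigma = 0.1 mu but clamp it anyway
            floor = 1e-6 * self.mu
            low = draws < floor
            if low.any():
                warnings.warn(f"clamped {low.sum()} non-positive draws of "
                              f"{self.name}")
                draws[low] = floor
        return draws


#: nominal UQ means for the six varied mechanical parameters
UQ_NOMINALS = {
    "kappa0": 1.5e-2,     # N/m
    "eta0": 5.0e-2,       # N·s/m
    "kappa_nuc": 6.0e-2,  # N/m
    "eta_nuc": 2.2e-1,    # N·s/m
    "k12": 1.5,
    "lambda": 0.75,
}


def default_priors() -> list[ParameterPrior]:
    return [ParameterPrior(name, mu) for name, mu in UQ_NOMINALS.items()]


# ---------------------------------------------------------------------------
# Hermite basis
# ---------------------------------------------------------------------------

def basis_size(degree: int, dim: int) -> int:
    """Number of total-degree-≤ basis terms, C(degree + dim, degree)."""
    return math.comb(degree + dim, degree)


def multi_indices(degree: int, dim: int) -> list[tuple[int, ...]]:
    """All multi-indices with total degree ≤ degree, graded order."""
    out = [idx for idx in product(range(degree + 1), repeat=dim)
           if sum(idx) <= degree]
    out.sort(key=lambda idx: (sum(idx), idx))
    return out


def _hermite_norm(z: np.ndarray, kmax: int) -> np.ndarray:
    """Orthonormal probabilists' Hermite values He_k(z)/sqrt(k!)."""
    vals = np.empty((kmax + 1,) + z.shape)
    vals[0] = 1.0
    if kmax >= 1:
        vals[1] = z
    for k in range(1, kmax):
        vals[k + 1] = z * vals[k] - k * vals[k - 1]
    for k in range(kmax + 1):
        vals[k] /= math.sqrt(math.factorial(k))
    return vals


def _design_matrix(inputs, priors, indices):
    inputs = np.asarray(inputs, dtype=float)
    kmax = max(max(idx) for idx in indices)
    z = (inputs - np.array([p.mu for p in priors])) \
        / np.array([p.sigma for p in priors])
    herm = [_hermite_norm(z[:, j], kmax) for j in range(len(priors))]
    phi = np.empty((len(inputs), len(indices)))
    for t, idx in enumerate(indices):
        col = np.ones(len(inputs))
        for j, k in enumerate(idx):
            if k:
                col = col * herm[j][k]
        phi[:, t] = col
    return phi


def sample_design(priors, degree=4, oversampling=2, seed=None, rng=None):
    """Random collocation design: oversampling × basis_size prior draws."""
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = oversampling * basis_size(degree, len(priors))
    return np.column_stack([p.sample(rng, n) for p in priors])


# ---------------------------------------------------------------------------
# Surrogate
# ---------------------------------------------------------------------------

@dataclass
class PceSurrogate:
    """Least-squares PCE: coefficients per output time point."""

    priors: list[ParameterPrior]
    degree: int
    indices: list[tuple[int, ...]]
    coeffs: np.ndarray           # (n_terms, n_outputs)
    times: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return len(self.priors)

    def evaluate(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        phi = _design_matrix(points, self.priors, self.indices)
        return phi @ self.coeffs


def build_pce(inputs, outputs, priors, degree=4, times=None) -> PceSurrogate:
    """Regress outputs (n_samples, n_outputs) onto the Hermite basis.

    Requires at least as many samples as basis terms; recovers any output
    that is a polynomial of total degree ≤ degree in the inputs exactly
    (up to regression conditioning).
    """
    inputs = np.asarray(inputs, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim == 1:
        outputs = outputs[:, None]
    indices = multi_indices(degree, len(priors))
    if len(inputs) < len(indices):
        raise ValueError(
            f"underdetermined design: {len(inputs)} samples for "
            f"{len(indices)} basis terms")
    phi = _design_matrix(inputs, priors, indices)
    coeffs, *_ = np.linalg.lstsq(phi, outputs, rcond=None)
    return PceSurrogate(priors=list(priors), degree=degree, indices=indices,
                        coeffs=coeffs,
                        times=None if times is None else np.asarray(times))


def moments_and_sobol(surrogate: PceSurrogate):
    """Mean, standard deviation and first-order Sobol indices per output.

    In the orthonormal basis the mean is the constant coefficient and the
    variance the sum of squared non-constant coefficients; the first-order
    index of parameter i collects the terms involving parameter i alone.
    Outputs with zero variance get NaN indices (undefined, not 0/0).
    """
    c = surrogate.coeffs
    idx = np.array(surrogate.indices)
    const = np.all(idx == 0, axis=1)
    mu = c[const][0]
    var = np.sum(c[~const] ** 2, axis=0)
    # regression round-off on a constant output leaves ~1e-30 variance;
    # treat it as exactly zero so the indices come out undefined
    floor = (1e-9 * np.maximum(1.0, np.abs(mu))) ** 2
    var = np.where(var <= floor, 0.0, var)
    sobol = {}
    for j, prior in enumerate(surrogate.priors):
        only_j = (idx[:, j] > 0) & np.all(np.delete(idx, j, axis=1) == 0,
                                          axis=1)
        num = np.sum(c[only_j] ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            sobol[prior.name] = np.where(var > 0, num / var, np.nan)
    return mu, np.sqrt(var), sobol


# ---------------------------------------------------------------------------
# RMSE cost and Nelder–Mead fitting
# ---------------------------------------------------------------------------

def _as_time_force(curve):
    if isinstance(curve, pd.DataFrame):
        return curve["time"].to_numpy(float), curve["force"].to_numpy(float)
    t, f = curve
    return np.asarray(t, dtype=float), np.asarray(f, dtype=float)


def rmse_cost(simulated, target) -> float:
    """RMSE between curves after interpolating the simulation onto the
    target's timestamps (restricted to the overlapping time support)."""
    ts, fs = _as_time_force(simulated)
    tt, ft = _as_time_force(target)
    if len(ts) == 0 or len(tt) == 0:
        raise ValueError("empty force curve")
    lo, hi = max(ts.min(), tt.min()), min(ts.max(), tt.max())
    if hi <= lo:
        raise ValueError("force curves have no overlapping time support")
    sel = (tt >= lo) & (tt <= hi)
    interp = np.interp(tt[sel], ts, fs)
    return float(np.sqrt(np.mean((interp - ft[sel]) ** 2)))


def make_indentation_runner(config, free_params, *, protocol=None, seed=11,
                            relax_steps=3000, tip_stiffness_factor=50.0,
                            smooth=3, plane_extent=70.0):
    """Deterministic map from parameter vectors to indentation force curves.

    Prepares one spread cell on a full-plane substrate, relaxed to a deep
    minimum under the nominal parameters, and reuses that state for every
    evaluation, so the force curve varies smoothly with the mechanical
    parameters rather than through rearrangement cascades.  The tip uses a
    softer penalty (``tip_stiffness_factor`` × u0/deq³) and the recorded
    curve is lightly smoothed, both of which suppress the contact-shot
    noise that otherwise masks parameter sensitivity.

    ``free_params`` names the varied entries, each one of kappa0, eta0,
    kappa_nuc, eta_nuc, k12, lambda; the returned ``runner(x)`` accepts a
    vector in that order.  Noise is disabled (kT_eff = 0) so equal inputs
    give bit-equal outputs.
    """
    from . import scenarios
    from .model import (ParticleSystem, drag_array, nuclear_drag,
                        params_from_config, table_from_config)
    from .dynamics import BrownianIntegrator

    base_cfg = copy.deepcopy(config)
    p0 = params_from_config(base_cfg)
    sigma = base_cfg["ecm"]["sigma"]
    cell = scenarios.make_spread_cell(
        p0, base_cfg["cell"]["nuclear_fraction"],
        z_bottom=2 ** (1 / 6) * sigma, seed=seed)
    ecm = scenarios.build_ecm(scenarios.EcmPattern(
        "plane", plane_extent, spacing=p0.deq, margin=0.0))
    base = ParticleSystem.concatenate(cell, ecm)
    table0 = table_from_config(base_cfg, p0)
    drag0 = drag_array(base, p0, nuclear_drag(base_cfg, p0))
    BrownianIntegrator(base, table0, drag0, p0.deq, kT_eff=0.0, seed=0,
                       adaptive=True).step(relax_steps)
    if protocol is None:
        protocol = scenarios.IndentationProtocol(
            tip_radius=6.0, depth=3.5, hold_duration=1.5,
            sampling_interval=0.1)

    key_map = {"kappa0": ("sem", "kappa0"), "eta0": ("sem", "eta0"),
               "lambda": ("sem", "lambda"),
               "kappa_nuc": ("nucleus", "kappa"),
               "eta_nuc": ("nucleus", "eta"), "k12": ("nucleus", "k12")}

    def runner(x):
        cfg = copy.deepcopy(base_cfg)
        for name, value in zip(free_params, np.atleast_1d(x)):
            section, key = key_map[name]
            cfg[section][key] = float(value)
        p = params_from_config(cfg)
        table = table_from_config(cfg, p)
        system = base.copy()
        drag = drag_array(system, p, nuclear_drag(cfg, p))
        res = scenarios.run_indentation(
            system, table, p, drag, protocol, kT_eff=0.0,
            tip_stiffness=tip_stiffness_factor * p.u0 / p.deq**3)
        curve = res.force_curve.copy()
        if smooth and smooth > 1:
            curve["force"] = curve["force"].rolling(
                smooth, center=True, min_periods=1).mean()
        return curve

    return runner


@dataclass
class FitResult:
    x: np.ndarray
    rmse: float
    rmse_trace: list[float]      # best-so-far per evaluation
    converged: bool
    n_evaluations: int
    xatol: float
    fatol: float


def fit_parameters(runner, target, x0, *, xatol=1e-4, fatol=1e-4,
                   maxiter=None, scale=None) -> FitResult:
    """Nelder–Mead minimization of the force-curve RMSE.

    ``runner(x) -> force curve`` must be deterministic (fixed simulation
    seed).  A runner failure at a simplex vertex is penalized with +inf and
    logged; the optimization continues.  ``scale`` (defaults to |x0|)
    normalizes the search variables so the tolerances act on relative
    parameter changes.
    """
    x0 = np.asarray(x0, dtype=float)
    if scale is None:
        scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    scale = np.asarray(scale, dtype=float)
    trace: list[float] = []
    best = [np.inf]

    def cost(u):
        x = u * scale
        try:
            curve = runner(x)
            value = rmse_cost(curve, target)
        except Exception as err:   # penalized vertex
            warnings.warn(f"runner failed at {x}: {err}")
            value = np.inf
        best[0] = min(best[0], value)
        trace.append(best[0])
        return value

    options = {"xatol": xatol, "fatol": fatol}
    if maxiter is not None:
        options["maxiter"] = maxiter
    res = minimize(cost, x0 / scale, method="Nelder-Mead", options=options)
    return FitResult(x=res.x * scale, rmse=float(res.fun), rmse_trace=trace,
                     converged=bool(res.success), n_evaluations=len(trace),
                     xatol=xatol, fatol=fatol)
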