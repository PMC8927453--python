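"""Veronda-Westmann hyperelastic model for uniaxial tension.

The model describes soft collagenous tissue (originally ex vivo cat skin)
with a two-parameter strain energy density

    Psi(I1b, I2b) = (mu/gamma) * (exp(gamma*(I1b - 3)) - 1) - mu * (I2b - 3)

where ``mu`` (MPa) sets the stress scale and ``gamma`` (dimensionless)
controls the exponential stiffening that produces the J-shaped toe of the
stress-strain curve.  Under incompressible uniaxial extension with principal
stretch ``lam = 1 + strain`` the deviatoric invariants reduce to
``I1b = lam**2 + 2/lam`` and ``I2b = 2*lam + 1/lam**2``, and the nominal
(first Piola-Kirchhoff) stress along the loading axis is

    sigma(lam) = 2*mu*(1 - lam**-3) * (lam*exp(gamma*(I1b - 3)) - 1)

which is exactly d(Psi)/d(lam) under those kinematics.  Both parameters are
identified from a measured nominal stress-strain curve by deterministic
multi-start nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateCurveError, EnergyOverflowError, FitFailureError, InvalidSpecificationError

# exp argument above this would overflow float64 (exp(710) == inf)
_EXP_GUARD = 700.0

# Deterministic multi-start grids for the least-squares fit (MPa, -)
_MU_STARTS = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
_GAMMA_STARTS = (0.5, 2.0, 8.0, 20.0, 50.0)


@dataclass(frozen=True)
class VWParameters:
    """Material coefficients of the Veronda-Westmann law."""

    mu: float  # MPa
    gamma: float  # dimensionless

    def __post_init__(self):
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise InvalidSpecificationError(f"mu must be finite and > 0, got {self.mu}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise InvalidSpecificationError(f"gamma must be finite and > 0, got {self.gamma}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares parameter identification."""

    params: VWParameters
    r_squared: float
    residual_norm: float  # MPa, sqrt of the sum of squared residuals
    n_points_used: int
    converged: bool


def uniaxial_invariants(stretch):
    """Deviatoric invariants (I1bar, I2bar) of incompressible uniaxial extension.

    Parameters
    ----------
    stretch
        Principal stretch ``lam > 0`` along the loading axis (scalar or array).

    Returns
    -------
    tuple of ndarray
        ``I1bar = lam**2 + 2/lam`` and ``I2bar = 2*lam + 1/lam**2``.  Both are
        >= 3 for every positive stretch, with equality only at ``lam = 1``.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise InvalidSpecificationError("principal stretch must be finite and > 0")
    return lam**2 + 2.0 / lam, 2.0 * lam + 1.0 / lam**2


def strain_energy(params: VWParameters, i1bar, i2bar):
    """Strain energy density Psi (MPa) at the given deviatoric invariants."""
    i1 = np.asarray(i1bar, dtype=float)
    i2 = np.asarray(i2bar, dtype=float)
    arg = params.gamma * (i1 - 3.0)
    if np.any(arg > _EXP_GUARD):
        raise EnergyOverflowError(
            f"gamma*(I1-3) reaches {float(np.max(arg)):.3g} > {_EXP_GUARD:g}; "
            "the exponential would overflow"
        )
    return (params.mu / params.gamma) * np.expm1(arg) - params.mu * (i2 - 3.0)


def nominal_stress(params: VWParameters, strain):
    """Nominal uniaxial stress sigma (MPa) at nominal strain(s) ``strain``.

    ``strain`` must exceed -1 so that the stretch ``lam = 1 + strain`` stays
    positive.  Raises :class:`EnergyOverflowError` when the exponential term
    would overflow rather than returning infinity.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps <= -1) or not np.all(np.isfinite(eps)):
        raise InvalidSpecificationError("nominal strain must be finite and > -1")
    lam = 1.0 + eps
    i1, _ = uniaxial_invariants(lam)
    arg = params.gamma * (i1 - 3.0)
    if np.any(arg > _EXP_GUARD):
        raise EnergyOverflowError(
            f"gamma*(I1-3) reaches {float(np.max(arg)):.3g} > {_EXP_GUARD:g} at "
            f"strain {float(eps.flat[int(np.argmax(arg))]):.4g}"
        )
    return 2.0 * params.mu * (1.0 - lam**-3) * (lam * np.exp(arg) - 1.0)


def _stress_and_jac(log_mu: float, log_gamma: float, lam: np.ndarray):
    """Model stress and its Jacobian w.r.t. (log mu, log gamma), overflow-saturated.

    The saturation keeps the optimizer finite while it wanders; the public
    :func:`nominal_stress` keeps the hard guard.
    """
    mu = np.exp(log_mu)
    gamma = np.exp(log_gamma)
    i1 = lam**2 + 2.0 / lam
    # saturate well below the float64 limit so arg*exp(arg) stays finite too
    arg = np.minimum(gamma * (i1 - 3.0), 500.0)
    e = np.exp(arg)
    pref = 2.0 * mu * (1.0 - lam**-3)
    sigma = pref * (lam * e - 1.0)
    # d sigma / d log(mu) = sigma; d sigma / d log(gamma) = pref*lam*e*arg
    jac = np.column_stack([sigma, pref * lam * e * arg])
    return sigma, jac


def fit(strain, stress=None, *, mu_starts=_MU_STARTS, gamma_starts=_GAMMA_STARTS,
        n_refine: int = 4, ftol: float = 1e-12, max_nfev: int = 200) -> FitResult:
    """Identify (mu, gamma) from a nominal stress-strain curve.

    Only points up to and including the ultimate (peak-stress) point enter the
    residual, because the model cannot represent post-peak softening.  The
    parameters are optimized in log space (enforcing positivity) from a
    deterministic grid of starts: every start is screened by its initial sum
    of squared residuals and the ``n_refine`` most promising ones are polished
    with :func:`scipy.optimize.least_squares`; the best final residual wins,
    ties broken toward smaller gamma.

    Parameters
    ----------
    strain, stress
        Nominal strain (dimensionless) and nominal stress (MPa) samples; a
        single object with ``.strain`` and ``.stress`` attributes (e.g. a
        ``StressStrainCurve``) may be passed instead.
    mu_starts, gamma_starts
        Multi-start grids in MPa and dimensionless units.
    n_refine
        Number of screened starts that get a full optimizer run.
    ftol
        Relative tolerance on the cost decrease.
    max_nfev
        Function-evaluation budget per start.

    Returns
    -------
    FitResult
        Best parameters, coefficient of determination R^2 over the fitted
        range, residual norm, number of points used and convergence flag.
    """
    if stress is None:
        stress = strain.stress
        strain = strain.strain
    eps = np.asarray(strain, dtype=float)
    sig = np.asarray(stress, dtype=float)
    if eps.shape != sig.shape or eps.ndim != 1:
        raise InvalidSpecificationError("strain and stress must be 1-D arrays of equal length")
    # restrict to the rising branch: up to the first occurrence of the peak
    peak = int(np.argmax(sig))
    eps_fit = eps[: peak + 1]
    sig_fit = sig[: peak + 1]
    if eps_fit.size < 5:
        raise DegenerateCurveError(
            f"need >= 5 points up to the ultimate point, got {eps_fit.size}"
        )
    if np.all(sig_fit == 0):
        raise DegenerateCurveError("all-zero stress curve cannot be fitted")
    lam = 1.0 + eps_fit

    def residuals(theta):
        return _stress_and_jac(theta[0], theta[1], lam)[0] - sig_fit

    def jacobian(theta):
        return _stress_and_jac(theta[0], theta[1], lam)[1]

    # screen the full grid by initial cost, deterministically ordered
    starts = []
    for g0 in gamma_starts:
        for m0 in mu_starts:
            theta0 = (np.log(m0), np.log(g0))
            cost = float(np.sum(residuals(np.array(theta0)) ** 2))
            starts.append((cost, g0, m0, theta0))
    starts.sort(key=lambda s: (s[0], s[1], s[2]))

    best = None
    diagnostics = []
    for cost0, g0, m0, theta0 in starts[:n_refine]:
        try:
            sol = least_squares(residuals, np.asarray(theta0), jac=jacobian,
                                method="lm", ftol=ftol, xtol=1e-14, gtol=1e-14,
                                max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": (m0, g0), "error": repr(exc)})
            continue
        gamma_hat = float(np.exp(sol.x[1]))
        diagnostics.append({"start": (m0, g0), "cost": float(sol.cost),
                            "status": int(sol.status)})
        if sol.status <= 0:
            continue
        key = (float(sol.cost), gamma_hat)
        if best is None or key < (best[0], best[1]):
            best = (float(sol.cost), gamma_hat, sol)
    if best is None:
        raise FitFailureError("no multi-start converged", diagnostics)

    sol = best[2]
    mu_hat = float(np.exp(sol.x[0]))
    gamma_hat = float(np.exp(sol.x[1]))
    ss_res = 2.0 * float(sol.cost)
    ss_tot = float(np.sum((sig_fit - sig_fit.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(
        params=VWParameters(mu=mu_hat, gamma=gamma_hat),
        r_squared=r2,
        residual_norm=float(np.sqrt(ss_res)),
        n_points_used=int(eps_fit.size),
        converged=True,
    )
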