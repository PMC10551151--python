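"""Non-rectangular hyperbola (NRH) light response model.

The NRH describes net leaf photosynthesis ``A_N`` as a function of incident
photosynthetically active radiation (PAR, ``I``) through four parameters:

* ``a_max`` — light-saturated gross assimilation rate (µmol CO₂ m⁻² s⁻¹),
* ``alpha`` — apparent quantum yield, the initial slope of the curve
  (µmol CO₂ µmol photon⁻¹),
* ``r_d`` — mitochondrial (dark) respiration (µmol CO₂ m⁻² s⁻¹),
* ``theta`` — unitless curvature parameter in (0, 1].

Gross assimilation is the smaller root ``z`` of the quadratic

    theta·z² − (alpha·I + a_max)·z + alpha·I·a_max = 0,

and the net rate is ``z − r_d``.  At ``theta → 0`` the curve degenerates to a
rectangular hyperbola, at ``theta = 1`` to the Blackman two-line response
``min(alpha·I, a_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LrcParameters",
    "nrh_mean",
    "nrh_mean_theta_zero",
    "validate_params",
    "PARAM_NAMES",
]

#: Canonical ordering of the four curve parameters throughout the package.
PARAM_NAMES = ("a_max", "alpha", "r_d", "theta")

# Below this curvature the quadratic root is evaluated as its theta->0
# closed form to avoid 0/0 cancellation.
_THETA_EPS = 1e-6

# Discriminants more negative than this signal invalid parameters rather
# than round-off and raise.
_DISC_TOL = -1e-10


@dataclass(frozen=True)
class LrcParameters:
    """Light-response-curve parameters for a single plant.

    Invariants: ``a_max > 0``, ``alpha > 0``, ``r_d >= 0``, ``0 < theta <= 1``.
    """

    a_max: float
    alpha: float
    r_d: float
    theta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a_max, self.alpha, self.r_d, self.theta], dtype=float)


def validate_params(params: LrcParameters) -> list[str]:
    """Return the list of violated parameter invariants (empty iff valid).

    Total function: never raises, reports every violation.
    """
    violations: list[str] = []
    if not np.isfinite(params.a_max) or params.a_max <= 0:
        violations.append("a_max must be finite and > 0")
    if not np.isfinite(params.alpha) or params.alpha <= 0:
        violations.append("alpha must be finite and > 0")
    if not np.isfinite(params.r_d) or params.r_d < 0:
        violations.append("r_d must be finite and >= 0")
    if not np.isfinite(params.theta) or not (0 < params.theta <= 1):
        violations.append("theta must be finite and in (0, 1]")
    return violations


def _check(params: LrcParameters, par) -> np.ndarray:
    bad = validate_params(params)
    if bad:
        raise ValueError("invalid LrcParameters: " + "; ".join(bad))
    par = np.asarray(par, dtype=float)
    if not np.all(np.isfinite(par)) or np.any(par < 0):
        raise ValueError("par must be finite and >= 0")
    return par


def nrh_mean(params: LrcParameters, par) -> np.ndarray | float:
    """Mean net photosynthesis rate µ(PAR) under the NRH model.

    Accepts a scalar or array of irradiances; vectorised over ``par``.
    Slightly negative discriminants (round-off) are clamped to zero; larger
    negatives raise, since they indicate invalid parameters.
    """
    par = _check(params, par)
    if params.theta < _THETA_EPS:
        return nrh_mean_theta_zero(params, par)
    s = params.alpha * par + params.a_max
    disc = s * s - 4.0 * params.theta * params.alpha * par * params.a_max
    if np.any(disc < _DISC_TOL):
        raise ValueError("negative discriminant: parameters outside model domain")
    disc = np.maximum(disc, 0.0)
    mu = (s - np.sqrt(disc)) / (2.0 * params.theta) - params.r_d
    return float(mu) if mu.ndim == 0 else mu


def nrh_mean_theta_zero(params: LrcParameters, par) -> np.ndarray | float:
    """Rectangular-hyperbola limit of :func:`nrh_mean` as theta -> 0.

    µ = alpha·I·a_max / (alpha·I + a_max) − r_d.  ``params.theta`` is ignored.
    """
    par = np.asarray(par, dtype=float)
    if params.alpha <= 0 or params.a_max <= 0:
        raise ValueError("alpha and a_max must be > 0")
    if not np.all(np.isfinite(par)) or np.any(par < 0):
        raise ValueError("par must be finite and >= 0")
    denom = params.alpha * par + params.a_max
    mu = params.alpha * par * params.a_max / denom - params.r_d
    return float(mu) if mu.ndim == 0 else mu


def nrh_mean_arrays(theta_mat: np.ndarray, par: np.ndarray) -> np.ndarray:
    """Vectorised NRH mean for an (n, 4) parameter matrix and matching PAR.

    Rows of ``theta_mat`` are (a_max, alpha, r_d, theta) per observation.
    Used by the inference machinery; performs no validation.
    """
    a_max, alpha, r_d, theta = theta_mat.T
    s = alpha * par + a_max
    disc = np.maximum(s * s - 4.0 * theta * alpha * par * a_max, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * theta) - r_d
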