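"""Closed-form receptor response models.

Everything in this module is a pure function of scalar/array inputs.
Concentrations are handled on the log10 molar scale throughout; responses
and occupancies are fractions in [0, 1] (conversion to percent happens at
the I/O boundary only).

The central model describes fractional response as a hyperbolic function of
ligand concentration with explicit parameters for binding affinity (Kd),
receptor-activation efficacy (eps, capped at 1), signal amplification gain
(gamma; >1 left-shifts the response relative to occupancy, <1 right-shifts
it), constitutive activity (eps_r0) and a Hill slope (n):

    E/Emax = (eps*g*L^n + eps_r0*g*Kd^n)
             / ((eps*g - eps + 1)*L^n + (eps_r0*g - eps_r0 + 1)*Kd^n)

Reduced forms (no constitutive activity, n = 1; gamma = 1 -> Clark) and the
companion occupancy/shift algebra (Kobs, emax, kappa) are provided alongside
the classic Hill and operational (Black & Leff) comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SABREParameters",
    "HillParameters",
    "OperationalParameters",
    "ShiftKappa",
    "response_general",
    "response_simplified",
    "occupancy",
    "k_obs",
    "e_max_pred",
    "kappa_from_shift",
    "kappa_from_params",
    "response_from_occupancy",
    "response_from_occupancy_generic",
    "hill_response",
    "operational_response",
    "cheng_prusoff",
]

#: below this |kappa - 1| the occupancy->response map is evaluated at its
#: removable-singularity limit f_resp = e_max * f_occup (the "unity line")
KAPPA_UNITY_TOL = 1e-9

# exponent clip keeping 10**x finite in double precision
_EXP_CLIP = 300.0


def _pow10(x):
    return np.power(10.0, np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def _check_finite(name, value):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def _scalar_like(result, *inputs):
    """Return a python float when every array input was scalar."""
    if all(np.ndim(x) == 0 for x in inputs):
        return float(result)
    return result


@dataclass(frozen=True)
class SABREParameters:
    """Full five-parameter description of one ligand-pathway pair.

    Parameters
    ----------
    log_kd : float
        log10 of the equilibrium dissociation constant (molar).
    efficacy : float
        Receptor-activation efficacy ``eps`` in [0, 1]; 1 = full agonist.
    gain : float
        Signal amplification ``gamma`` (> 0). ``gamma > 1`` amplification,
        ``gamma < 1`` attenuation/loss, ``gamma = 1`` neutral.
    efficacy_r0 : float, default 0
        Constitutive-activity efficacy in [0, 1] (activation of unoccupied
        receptors); 0 = no basal signalling.
    hill : float, default 1
        Hill coefficient ``n`` (> 0) applied to both the ligand and Kd
        terms.
    """

    log_kd: float
    efficacy: float
    gain: float
    efficacy_r0: float = 0.0
    hill: float = 1.0

    def __post_init__(self):
        _check_finite("log_kd", self.log_kd)
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError(f"efficacy must be in [0, 1], got {self.efficacy}")
        if not self.gain > 0.0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if not 0.0 <= self.efficacy_r0 <= 1.0:
            raise ValueError(
                f"efficacy_r0 must be in [0, 1], got {self.efficacy_r0}"
            )
        if not self.hill > 0.0:
            raise ValueError(f"hill must be > 0, got {self.hill}")


@dataclass(frozen=True)
class HillParameters:
    """Empirical sigmoid: log EC50 (molar), fractional e_max, Hill slope."""

    log_ec50: float
    e_max: float
    hill: float = 1.0

    def __post_init__(self):
        _check_finite("log_ec50", self.log_ec50)
        if not 0.0 < self.e_max <= 1.0:
            raise ValueError(f"e_max must be in (0, 1], got {self.e_max}")
        if not self.hill > 0.0:
            raise ValueError(f"hill must be > 0, got {self.hill}")


@dataclass(frozen=True)
class OperationalParameters:
    """Black & Leff operational model: log K_D (molar) and transducer tau."""

    log_KD: float
    tau: float

    def __post_init__(self):
        _check_finite("log_KD", self.log_KD)
        if not self.tau > 0.0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class ShiftKappa:
    """Fold shift Kd/EC50 between occupancy and response midpoints.

    ``kappa > 1`` means the response is left-shifted versus occupancy (more
    concentration-sensitive); ``kappa < 1`` right-shifted; 1 means the two
    half-maxima coincide.
    """

    kappa: float

    def __post_init__(self):
        if not self.kappa > 0.0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")

    @property
    def left_shifted(self) -> bool:
        return self.kappa > 1.0

    @property
    def right_shifted(self) -> bool:
        return self.kappa < 1.0


def response_general(logL, p: SABREParameters):
    """Fractional response of the full five-parameter model.

    Parameters
    ----------
    logL : float or array_like
        log10 molar ligand concentration(s).
    p : SABREParameters

    Returns
    -------
    float or ndarray
        ``E/Emax`` in [0, 1]; monotone nondecreasing in L whenever
        ``efficacy >= efficacy_r0``.
    """
    logL = _check_finite("logL", logL)
    eps, g, e0, n = p.efficacy, p.gain, p.efficacy_r0, p.hill
    # work with r = (L/Kd)^n to avoid overflow at extreme concentrations
    r = _pow10(n * (logL - p.log_kd))
    num = g * (eps * r + e0)
    den = (eps * g - eps + 1.0) * r + (e0 * g - e0 + 1.0)
    return _scalar_like(num / den, logL)


def response_simplified(logL, log_kd, efficacy, gain):
    """Three-parameter reduced response (no constitutive activity, n = 1).

    ``E/Emax = eps*g*L / ((eps*g - eps + 1)*L + Kd)``; for ``gain == 1``
    this is the Clark equation with ``e_max = efficacy``.
    """
    p = SABREParameters(log_kd=log_kd, efficacy=efficacy, gain=gain)
    return response_general(logL, p)


def occupancy(logL, log_kd, hill=1.0):
    """Fractional receptor occupancy ``L^n / (L^n + Kd^n)``.

    Always saturates at 1 and equals 0.5 at ``L = Kd`` for any Hill slope.
    """
    logL = _check_finite("logL", logL)
    _check_finite("log_kd", log_kd)
    if not hill > 0.0:
        raise ValueError(f"hill must be > 0, got {hill}")
    r = _pow10(hill * (logL - log_kd))
    return _scalar_like(r / (r + 1.0), logL)


def _shift_factor(efficacy, gain):
    """kappa = eps*gamma - eps + 1, validated positive."""
    if not gain > 0.0:
        raise ValueError(f"gain must be > 0, got {gain}")
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError(f"efficacy must be in [0, 1], got {efficacy}")
    kappa = efficacy * gain - efficacy + 1.0
    if not kappa > 0.0:
        raise ValueError(
            f"eps*gamma - eps + 1 = {kappa} must be > 0 "
            f"(efficacy={efficacy}, gain={gain})"
        )
    return kappa


def k_obs(log_kd, efficacy, gain):
    """log10 of the apparent EC50: ``Kobs = Kd / (eps*gamma - eps + 1)``.

    A full agonist (eps = 1) has ``Kobs = Kd/gamma``; with no amplification
    (gamma = 1) the observed EC50 coincides with the binding Kd.
    """
    _check_finite("log_kd", log_kd)
    return float(log_kd) - np.log10(_shift_factor(efficacy, gain))


def e_max_pred(efficacy, gain):
    """Maximal fractional response ``eps*gamma / (eps*gamma - eps + 1)``."""
    return efficacy * gain / _shift_factor(efficacy, gain)


def kappa_from_shift(log_kd, log_ec50) -> ShiftKappa:
    """Shift computed from the two midpoints: ``kappa = 10**(logKd - logEC50)``."""
    _check_finite("log_kd", log_kd)
    _check_finite("log_ec50", log_ec50)
    return ShiftKappa(float(10.0 ** (log_kd - log_ec50)))


def kappa_from_params(efficacy, gain) -> ShiftKappa:
    """Shift in model parameters: ``kappa = eps*gamma - eps + 1``.

    Equals ``gain`` for a full agonist and 1 when ``gain == 1``.
    """
    return ShiftKappa(_shift_factor(efficacy, gain))


def response_from_occupancy_generic(f_occup, e_max, kappa):
    """Response as a hyperbolic function of occupancy.

    ``f_resp = e_max * kappa/(kappa-1) * f_occup / (f_occup + 1/(kappa-1))``
    with occupancy saturating at 1. The ``kappa -> 1`` singularity is
    removable and evaluated as the linear limit ``e_max * f_occup``.
    """
    f = np.asarray(f_occup, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)) or not np.all(np.isfinite(f)):
        raise ValueError(f"f_occup must lie in [0, 1], got {f_occup!r}")
    if not kappa > 0.0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if not 0.0 < e_max <= 1.0:
        raise ValueError(f"e_max must be in (0, 1], got {e_max}")
    if abs(kappa - 1.0) < KAPPA_UNITY_TOL:
        return _scalar_like(e_max * f, f_occup)
    km1 = kappa - 1.0
    out = e_max * kappa / km1 * f / (f + 1.0 / km1)
    return _scalar_like(out, f_occup)


def response_from_occupancy(f_occup, efficacy, gain):
    """Occupancy->response map of the three-parameter model.

    Identical to :func:`response_from_occupancy_generic` evaluated at
    ``kappa = eps*gamma - eps + 1`` and ``e_max = eps*gamma/kappa``, i.e.

        f_resp = gamma/(gamma-1) * f_occup / (f_occup + 1/(eps*(gamma-1)))

    and therefore agrees with :func:`response_simplified` composed with the
    inverse of :func:`occupancy` at every occupancy in (0, 1).
    """
    kappa = _shift_factor(efficacy, gain)
    if abs(kappa - 1.0) < KAPPA_UNITY_TOL:
        # gamma == 1 (or eps == 0): response tracks occupancy linearly
        f = np.asarray(f_occup, dtype=float)
        if np.any((f < 0.0) | (f > 1.0)):
            raise ValueError(f"f_occup must lie in [0, 1], got {f_occup!r}")
        return _scalar_like(efficacy * f, f_occup)
    # guard the 1-ulp overshoot of eps*gamma/kappa for full agonists
    return response_from_occupancy_generic(
        f_occup, e_max=min(efficacy * gain / kappa, 1.0), kappa=kappa
    )


def hill_response(logL, hp: HillParameters):
    """Classic Hill sigmoid ``e_max * L^n / (L^n + EC50^n)``."""
    logL = _check_finite("logL", logL)
    r = _pow10(hp.hill * (logL - hp.log_ec50))
    return _scalar_like(hp.e_max * r / (r + 1.0), logL)


def operational_response(logL, op: OperationalParameters):
    """Operational (Black & Leff) response ``tau*L / ((tau+1)*L + K_D)``.

    Apparent maximum is ``tau/(tau+1)`` and apparent EC50 is
    ``K_D/(tau+1)``; full agonism requires ``tau -> inf``.
    """
    logL = _check_finite("logL", logL)
    r = _pow10(logL - op.log_KD)  # L / K_D
    return _scalar_like(op.tau * r / ((op.tau + 1.0) * r + 1.0), logL)


def cheng_prusoff(ic50, radioligand_conc, radioligand_kd):
    """Competition-binding correction: Kd from an IC50.

    ``Kd = IC50 / (1 + [radioligand]/Kd_radioligand)``; all inputs molar,
    returns log10 Kd (molar).
    """
    for name, v in (
        ("ic50", ic50),
        ("radioligand_conc", radioligand_conc),
        ("radioligand_kd", radioligand_kd),
    ):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
    if ic50 <= 0 or radioligand_kd <= 0:
        raise ValueError("ic50 and radioligand_kd must be > 0")
    return float(np.log10(ic50 / (1.0 + radioligand_conc / radioligand_kd)))
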