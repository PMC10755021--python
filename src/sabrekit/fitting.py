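"""Constrained global nonlinear least-squares fitting of response panels.

A *panel* is a list of :class:`ResponseCurve` objects (one ligand x pathway
x concentration grid each). The global fitter shares parameters across
curves according to a :class:`ConstraintSpec`: each of the five model
parameters (``log_kd``, ``efficacy``, ``gain``, ``efficacy_r0``, ``hill``)
is either fixed, shared within a group (globally, per ligand, per pathway),
or free per curve.

Optimisation runs on transformed coordinates — log10 for ``gain`` and
``hill``, a scaled logit for the efficacies, ``log_kd`` as-is — so the
positivity/box constraints are built into the geometry and the strong
``efficacy * gain`` coupling is better conditioned. A deterministic
Latin-hypercube multistart (seeded) guards against local minima.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit
from scipy.stats import qmc

from .model import SABREParameters, HillParameters, hill_response, response_general

__all__ = [
    "ResponseCurve",
    "Fixed",
    "Shared",
    "Free",
    "ConstraintSpec",
    "FitResult",
    "ModelComparison",
    "IdentifiabilityError",
    "fit_hill_per_curve",
    "fit_sabre_global",
    "model_metrics",
    "compare_models",
    "aicc_least_squares",
]

PARAM_NAMES = ("log_kd", "efficacy", "gain", "efficacy_r0", "hill")

RESPONSE_MIN, RESPONSE_MAX = -0.05, 1.10

#: curves whose largest observed response is below this carry the
#: ``low_information`` flag (EC50/e_max poorly constrained)
LOW_INFORMATION_EMAX = 0.1

#: fitted e_max below 30% marks EC50-derived quantities unreliable
UNRELIABLE_EMAX = 0.3


class IdentifiabilityError(ValueError):
    """Raised when a constraint configuration cannot be resolved by the data."""


@dataclass
class ResponseCurve:
    """One ligand x pathway concentration-response series (fraction scale)."""

    ligand_id: str
    pathway_id: str
    log_conc: np.ndarray
    response: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self):
        self.log_conc = np.asarray(self.log_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.log_conc.ndim != 1 or self.log_conc.shape != self.response.shape:
            raise ValueError(
                f"curve {self.key}: log_conc and response must be 1-D and of "
                f"equal length ({self.log_conc.shape} vs {self.response.shape})"
            )
        if not np.all(np.isfinite(self.log_conc)):
            raise ValueError(f"curve {self.key}: non-finite log_conc")
        if np.any(self.response < RESPONSE_MIN) or np.any(self.response > RESPONSE_MAX):
            raise ValueError(
                f"curve {self.key}: responses must lie in "
                f"[{RESPONSE_MIN}, {RESPONSE_MAX}] (fraction scale); "
                f"got range [{self.response.min():.3g}, {self.response.max():.3g}]"
            )
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)
            if self.weight.shape != self.response.shape or np.any(self.weight < 0):
                raise ValueError(f"curve {self.key}: invalid weights")

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand_id, self.pathway_id)

    def __len__(self) -> int:
        return self.log_conc.size


# ---------------------------------------------------------------------------
# constraint rules


@dataclass(frozen=True)
class Fixed:
    """Pin a parameter. ``value`` may be a scalar or a mapping keyed by
    ligand id, pathway id, or ``(ligand, pathway)`` tuple."""

    value: float | Mapping

    def resolve(self, ligand: str, pathway: str) -> float:
        if isinstance(self.value, Mapping):
            for key in ((ligand, pathway), ligand, pathway):
                if key in self.value:
                    return float(self.value[key])
            raise KeyError(
                f"fixed-value mapping has no entry for ligand={ligand!r} "
                f"pathway={pathway!r}"
            )
        return float(self.value)


_SCOPES = ("global", "per-ligand", "per-pathway", "per-curve", "custom")


@dataclass(frozen=True)
class Shared:
    """Estimate one value per sharing group.

    scope: "global" (single value), "per-ligand", "per-pathway",
    "per-curve" (one value per ligand-pathway pair), or "custom" with an
    explicit ``groups`` mapping from ``(ligand, pathway)`` tuples, ligand
    ids or pathway ids to group labels (lets e.g. one suspect ligand take
    pathway-specific values while the rest share per ligand).
    """

    scope: str = "global"
    bounds: tuple[float, float] | None = None
    initial: float | None = None
    groups: Mapping | None = None

    def __post_init__(self):
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}, got {self.scope!r}")
        if (self.scope == "custom") != (self.groups is not None):
            raise ValueError("groups must be given exactly when scope='custom'")

    def group_key(self, ligand: str, pathway: str):
        if self.scope == "global":
            return "*"
        if self.scope == "per-ligand":
            return ligand
        if self.scope == "per-pathway":
            return pathway
        if self.scope == "custom":
            for key in ((ligand, pathway), ligand, pathway):
                if key in self.groups:
                    return self.groups[key]
            raise KeyError(
                f"custom sharing groups have no entry for ligand={ligand!r} "
                f"pathway={pathway!r}"
            )
        return (ligand, pathway)


def Free(bounds=None, initial=None) -> Shared:
    """One independent value per ligand-pathway pair."""
    return Shared("per-curve", bounds=bounds, initial=initial)


@dataclass(frozen=True)
class ConstraintSpec:
    """Per-parameter fixed/shared/free rules driving the global fit."""

    log_kd: Fixed | Shared
    efficacy: Fixed | Shared = field(default_factory=lambda: Shared("per-ligand"))
    gain: Fixed | Shared = field(default_factory=lambda: Shared("per-pathway"))
    efficacy_r0: Fixed | Shared = Fixed(0.0)
    hill: Fixed | Shared = Fixed(1.0)

    def rule(self, name: str) -> Fixed | Shared:
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def replace(self, **rules) -> "ConstraintSpec":
        from dataclasses import replace as _replace

        return _replace(self, **rules)

    @classmethod
    def default(cls, log_kd_by_ligand: Mapping[str, float]) -> "ConstraintSpec":
        """The common design: known Kd per ligand, one efficacy per ligand
        (shared across pathways), one gain per pathway."""
        return cls(log_kd=Fixed(dict(log_kd_by_ligand)))


# ---------------------------------------------------------------------------
# parameter transforms


class _Transform:
    def to_internal(self, theta: float) -> float:
        raise NotImplementedError

    def to_external(self, t: float) -> float:
        raise NotImplementedError

    def dext_dint(self, t: float) -> float:
        """Jacobian d(theta)/d(t) for delta-method standard errors."""
        raise NotImplementedError


class _Identity(_Transform):
    def __init__(self, lo=-np.inf, hi=np.inf):
        self.lo, self.hi = lo, hi

    def to_internal(self, theta):
        return float(theta)

    def to_external(self, t):
        return float(t)

    def dext_dint(self, t):
        return 1.0

    def internal_bounds(self):
        return self.lo, self.hi


class _Log10(_Transform):
    def __init__(self, lo, hi):
        self.lo, self.hi = lo, hi

    def to_internal(self, theta):
        return float(np.log10(theta))

    def to_external(self, t):
        return float(10.0**t)

    def dext_dint(self, t):
        return float(10.0**t * np.log(10.0))

    def internal_bounds(self):
        return np.log10(self.lo), np.log10(self.hi)


class _ScaledLogit(_Transform):
    """theta = lo + (hi - lo) * expit(t); t clipped to +/-16."""

    TMAX = 16.0

    def __init__(self, lo, hi):
        self.lo, self.hi = lo, hi

    def to_internal(self, theta):
        u = (float(theta) - self.lo) / (self.hi - self.lo)
        u = min(max(u, expit(-self.TMAX)), expit(self.TMAX))
        return float(logit(u))

    def to_external(self, t):
        return float(self.lo + (self.hi - self.lo) * expit(t))

    def dext_dint(self, t):
        s = expit(t)
        return float((self.hi - self.lo) * s * (1.0 - s))

    def internal_bounds(self):
        return -self.TMAX, self.TMAX


DEFAULT_BOUNDS = {
    "log_kd": (-12.0, -3.0),
    "efficacy": (1e-3, 1.0),
    "gain": (1e-2, 1e3),
    "efficacy_r0": (1e-6, 1.0),
    "hill": (0.2, 5.0),
}

DEFAULT_INITIAL = {
    "log_kd": -7.0,
    "efficacy": 0.5,
    "gain": 1.0,
    "efficacy_r0": 1e-3,
    "hill": 1.0,
}


def _transform_for(name: str, bounds=None) -> _Transform:
    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS[name]
    if not lo < hi:
        raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
    if name == "log_kd":
        return _Identity(lo, hi)
    if name in ("gain", "hill"):
        if lo <= 0:
            raise ValueError(f"{name} lower bound must be > 0, got {lo}")
        return _Log10(lo, hi)
    # efficacies live on a bounded interval
    return _ScaledLogit(lo, hi)


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Outcome of a (possibly multi-curve) least-squares fit.

    ``estimates`` has one row per resolved parameter — free/shared ones
    carry standard errors, fixed ones are included for completeness with
    ``kind == "fixed"``. ``curve_params`` maps each ``(ligand, pathway)``
    to its fully resolved parameter dict.
    """

    model: str
    estimates: pd.DataFrame
    residuals: pd.DataFrame
    sse: float
    aicc: float | None
    n_params: int
    n_obs: int
    converged: bool
    seed: int | None
    curve_params: dict
    flags: dict = field(default_factory=dict)
    scale_indeterminate: bool = False
    obs_fingerprint: str = ""
    messages: list = field(default_factory=list)

    def params_for(self, ligand_id: str, pathway_id: str) -> dict:
        try:
            return self.curve_params[(ligand_id, pathway_id)]
        except KeyError:
            raise KeyError(
                f"no fitted curve for ligand={ligand_id!r} pathway={pathway_id!r}"
            ) from None

    def sabre_params_for(self, ligand_id: str, pathway_id: str) -> SABREParameters:
        p = self.params_for(ligand_id, pathway_id)
        # fitted efficacies may graze the upper bound by rounding
        return SABREParameters(
            log_kd=p["log_kd"],
            efficacy=min(p["efficacy"], 1.0),
            gain=p["gain"],
            efficacy_r0=min(p["efficacy_r0"], 1.0),
            hill=p["hill"],
        )


@dataclass(frozen=True)
class ModelComparison:
    """Head-to-head comparison of two fits of the same observations."""

    delta_sse: float  # sse_a - sse_b
    delta_aicc: float  # aicc_a - aicc_b
    akaike_weight_a: float
    akaike_weight_b: float
    preferred: str  # "a" | "b" | "tie"


def _fingerprint(panel: Sequence[ResponseCurve]) -> str:
    h = hashlib.sha256()
    for c in sorted(panel, key=lambda c: c.key):
        h.update(repr(c.key).encode())
        h.update(np.round(c.log_conc, 9).tobytes())
        h.update(np.round(c.response, 9).tobytes())
    return h.hexdigest()


def _validate_panel(panel: Sequence[ResponseCurve], min_points: int):
    if not panel:
        raise ValueError("panel is empty")
    seen = set()
    for c in panel:
        if not isinstance(c, ResponseCurve):
            raise TypeError(f"panel entries must be ResponseCurve, got {type(c)}")
        if c.key in seen:
            raise ValueError(f"duplicate curve for {c.key}")
        seen.add(c.key)
        if len(c) < min_points:
            raise ValueError(
                f"curve {c.key} has {len(c)} points; >= {min_points} required"
            )


# ---------------------------------------------------------------------------
# per-curve Hill fits


def _fit_one_hill(curve: ResponseCurve, fix_hill_at_one: bool):
    logc, y = curve.log_conc, curve.response
    w = np.sqrt(curve.weight) if curve.weight is not None else 1.0

    emax_tr = _ScaledLogit(1e-4, 1.0)
    ec50_lo, ec50_hi = logc.min() - 3.0, logc.max() + 3.0
    hill_tr = _Log10(0.2, 5.0)

    def unpack(t):
        e_max = emax_tr.to_external(t[0])
        log_ec50 = t[1]
        n = 1.0 if fix_hill_at_one else hill_tr.to_external(t[2])
        return e_max, log_ec50, n

    def resid(t):
        e_max, log_ec50, n = unpack(t)
        pred = hill_response(logc, HillParameters(log_ec50, e_max, n))
        return w * (pred - y)

    ymax = float(np.clip(y.max(), 5e-3, 0.999))
    half = 0.5 * ymax
    log_ec50_0 = float(logc[np.argmin(np.abs(y - half))])
    t0 = [emax_tr.to_internal(ymax), log_ec50_0]
    lo, hi = [-emax_tr.TMAX, ec50_lo], [emax_tr.TMAX, ec50_hi]
    if not fix_hill_at_one:
        t0.append(hill_tr.to_internal(1.0))
        b = hill_tr.internal_bounds()
        lo.append(b[0])
        hi.append(b[1])

    sol = least_squares(
        resid, t0, bounds=(lo, hi), method="trf",
        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=10_000,
    )
    e_max, log_ec50, n = unpack(sol.x)

    k = sol.x.size
    dof = max(len(curve) - k, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    jtj = sol.jac.T @ sol.jac
    cov_t = s2 * np.linalg.pinv(jtj)
    se_t = np.sqrt(np.clip(np.diag(cov_t), 0.0, np.inf))
    se = [se_t[0] * abs(emax_tr.dext_dint(sol.x[0])), se_t[1]]
    if not fix_hill_at_one:
        se.append(se_t[2] * abs(hill_tr.dext_dint(sol.x[2])))

    pred = hill_response(logc, HillParameters(log_ec50, e_max, n))
    return {
        "e_max": e_max,
        "log_ec50": log_ec50,
        "hill": n,
        "se": dict(zip(["e_max", "log_ec50", "hill"], se + [0.0] * (3 - len(se)))),
        "pred": pred,
        "sse": float(np.sum((pred - y) ** 2)),
        "converged": bool(sol.success),
        "status": sol.message,
        "n_params": k,
    }


def fit_hill_per_curve(
    panel: Sequence[ResponseCurve], fix_hill_at_one: bool = True
) -> FitResult:
    """Fit every curve independently with the empirical Hill sigmoid.

    Each curve contributes 2 parameters (EC50, e_max) to ``n_params`` — or
    3 when the Hill slope is freed. Curves whose responses never exceed
    ``LOW_INFORMATION_EMAX`` are flagged ``low_information``; fitted
    ``e_max < UNRELIABLE_EMAX`` flags EC50-derived quantities unreliable.
    Non-convergence is reported per curve in ``flags`` and ``messages``,
    never silently dropped.
    """
    _validate_panel(panel, min_points=4 if fix_hill_at_one else 5)

    rows, resid_rows, curve_params, flags, messages = [], [], {}, {}, []
    n_params = 0
    sse = 0.0
    all_ok = True
    for c in panel:
        out = _fit_one_hill(c, fix_hill_at_one)
        n_params += out["n_params"]
        sse += out["sse"]
        curve_flags = []
        if not out["converged"]:
            all_ok = False
            curve_flags.append("not_converged")
            messages.append(f"{c.key}: {out['status']}")
        if c.response.max() < LOW_INFORMATION_EMAX:
            curve_flags.append("low_information")
        if out["e_max"] < UNRELIABLE_EMAX:
            curve_flags.append("unreliable_ec50")
        if curve_flags:
            flags[c.key] = curve_flags
        curve_params[c.key] = {
            "e_max": out["e_max"],
            "log_ec50": out["log_ec50"],
            "hill": out["hill"],
        }
        for name in ("e_max", "log_ec50") + (() if fix_hill_at_one else ("hill",)):
            rows.append(
                {
                    "parameter": name,
                    "group": f"{c.ligand_id}|{c.pathway_id}",
                    "value": out[name],
                    "stderr": out["se"][name],
                    "kind": "free",
                }
            )
        for lc, obs, pr in zip(c.log_conc, c.response, out["pred"]):
            resid_rows.append(
                {
                    "ligand": c.ligand_id,
                    "pathway": c.pathway_id,
                    "log_conc_M": lc,
                    "observed": obs,
                    "predicted": pr,
                    "residual": pr - obs,
                }
            )

    n_obs = sum(len(c) for c in panel)
    aicc = _maybe_aicc(sse, n_obs, n_params)
    return FitResult(
        model="hill-per-curve",
        estimates=pd.DataFrame(rows),
        residuals=pd.DataFrame(resid_rows),
        sse=sse,
        aicc=aicc,
        n_params=n_params,
        n_obs=n_obs,
        converged=all_ok,
        seed=None,
        curve_params=curve_params,
        flags=flags,
        obs_fingerprint=_fingerprint(panel),
        messages=messages,
    )


# ---------------------------------------------------------------------------
# global fit


class _ParameterPlan:
    """Resolve a ConstraintSpec against a panel into a flat free vector."""

    def __init__(self, panel: Sequence[ResponseCurve], constraints: ConstraintSpec):
        self.entries = []  # (param_name, group_key, transform)
        self.index = {}  # (param_name, group_key) -> position
        self.slots = {}  # curve key -> {param: ("fixed", val) | ("free", pos)}
        for c in panel:
            slot = {}
            for name in PARAM_NAMES:
                rule = constraints.rule(name)
                if isinstance(rule, Fixed):
                    slot[name] = ("fixed", rule.resolve(c.ligand_id, c.pathway_id))
                else:
                    gkey = rule.group_key(c.ligand_id, c.pathway_id)
                    pos = self.index.get((name, gkey))
                    if pos is None:
                        pos = len(self.entries)
                        self.index[(name, gkey)] = pos
                        self.entries.append(
                            (name, gkey, _transform_for(name, rule.bounds), rule)
                        )
                    slot[name] = ("free", pos)
            self.slots[c.key] = slot

    @property
    def n_free(self) -> int:
        return len(self.entries)

    def internal_bounds(self):
        lo, hi = [], []
        for _, _, tr, _ in self.entries:
            b = tr.internal_bounds()
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def initial_internal(self, panel):
        t0 = []
        grid_centre = float(np.median(np.concatenate([c.log_conc for c in panel])))
        for name, _, tr, rule in self.entries:
            theta0 = rule.initial
            if theta0 is None:
                theta0 = grid_centre if name == "log_kd" else DEFAULT_INITIAL[name]
            t0.append(tr.to_internal(theta0))
        lo, hi = self.internal_bounds()
        return np.clip(np.array(t0), lo, hi)

    def external(self, t: np.ndarray) -> list[float]:
        return [tr.to_external(t[i]) for i, (_, _, tr, _) in enumerate(self.entries)]

    def curve_params(self, key, t: np.ndarray) -> dict:
        out = {}
        for name, (kind, v) in self.slots[key].items():
            if kind == "fixed":
                out[name] = v
            else:
                out[name] = self.entries[v][2].to_external(t[v])
        return out

    def curve_params_external(self, key, theta: np.ndarray) -> dict:
        out = {}
        for name, (kind, v) in self.slots[key].items():
            out[name] = v if kind == "fixed" else theta[v]
        return out

    def external_bounds(self):
        lo = np.array([tr.lo for _, _, tr, _ in self.entries])
        hi = np.array([tr.hi for _, _, tr, _ in self.entries])
        return lo, hi


def _check_identifiability(panel, plan: _ParameterPlan):
    """Reject configurations the epsilon*gamma coupling makes hopeless and
    flag scale-indeterminate ones."""
    # group sizes: how many curves feed each free entry
    counts = np.zeros(plan.n_free, dtype=int)
    for key in plan.slots:
        for name, (kind, v) in plan.slots[key].items():
            if kind == "free":
                counts[v] += 1
    for c in panel:
        slot = plan.slots[c.key]
        core = [slot[n] for n in ("log_kd", "efficacy", "gain")]
        if all(kind == "free" for kind, _ in core) and all(
            counts[pos] == 1 for _, pos in core
        ):
            raise IdentifiabilityError(
                f"curve {c.key}: log_kd, efficacy and gain are all free and "
                "informed by this single curve only; a lone sigmoid determines "
                "just two quantities (EC50 = Kd/(eps*gamma-eps+1) and "
                "e_max = eps*gamma/(eps*gamma-eps+1)), so the eps*gamma "
                "coupling leaves the triple unidentifiable. Fix or share at "
                "least one of them (typically log_kd from binding data)."
            )
    # log_kd free for a ligand represented by a single curve: warn
    ligand_curves = {}
    for c in panel:
        ligand_curves.setdefault(c.ligand_id, []).append(c)
    for (name, gkey), pos in plan.index.items():
        if name == "log_kd" and counts[pos] < 2:
            warnings.warn(
                f"log_kd is free for group {gkey!r} but only {counts[pos]} curve "
                "informs it; the estimate may be poorly identified",
                stacklevel=3,
            )
    any_kd_fixed = any(
        slot["log_kd"][0] == "fixed" for slot in plan.slots.values()
    )
    gain_free = any(name == "gain" for name, _, _, _ in plan.entries)
    kd_free = any(name == "log_kd" for name, _, _, _ in plan.entries)
    return (not any_kd_fixed) and gain_free and kd_free


def fit_sabre_global(
    panel: Sequence[ResponseCurve],
    constraints: ConstraintSpec,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit all curves of a panel simultaneously under shared constraints.

    Parameters
    ----------
    panel : sequence of ResponseCurve
    constraints : ConstraintSpec
        Fixed/shared/free rule per model parameter.
    n_starts : int
        Number of Latin-hypercube multistart points (in addition to the
        heuristic centre start); the best solution by SSE wins.
    seed : int
        Seeds the multistart sampler; recorded in the result.

    Returns
    -------
    FitResult
        With per-group estimates, delta-method standard errors, residuals,
        SSE/AICc, and the resolved per-curve parameter sets.

    Raises
    ------
    IdentifiabilityError
        If ``log_kd``, ``efficacy`` and ``gain`` are simultaneously free on
        a curve that alone informs them.
    """
    _validate_panel(panel, min_points=4)
    plan = _ParameterPlan(panel, constraints)
    if plan.n_free == 0:
        raise ValueError("constraints leave no adjustable parameters")
    scale_indeterminate = _check_identifiability(panel, plan)

    y = np.concatenate([c.response for c in panel])
    w = np.concatenate(
        [
            np.sqrt(c.weight) if c.weight is not None else np.ones(len(c))
            for c in panel
        ]
    )

    def resid(t):
        pred = []
        for c in panel:
            p = plan.curve_params(c.key, t)
            pred.append(
                response_general(
                    c.log_conc,
                    SABREParameters(
                        log_kd=p["log_kd"],
                        efficacy=min(max(p["efficacy"], 0.0), 1.0),
                        gain=p["gain"],
                        efficacy_r0=min(max(p["efficacy_r0"], 0.0), 1.0),
                        hill=p["hill"],
                    ),
                )
            )
        return w * (np.concatenate(pred) - y)

    lo, hi = plan.internal_bounds()
    starts = [plan.initial_internal(panel)]
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=plan.n_free, seed=seed)
        unit = sampler.random(n_starts)
        span_lo = np.where(np.isfinite(lo), lo, -16.0)
        span_hi = np.where(np.isfinite(hi), hi, 16.0)
        starts.extend(span_lo + unit * (span_hi - span_lo))

    best = None
    for t0 in starts:
        sol = least_squares(
            resid, t0, bounds=(lo, hi), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=10_000,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    t = best.x
    sse = float(np.sum(resid(t) ** 2))
    n_obs = y.size
    k = plan.n_free

    # Standard errors from a finite-difference Jacobian in *external*
    # coordinates. The chain rule through the logit/log transforms is exact
    # in the interior but degenerates when an estimate sits on a bound
    # (d theta/d t -> 0 gives a spurious zero SE for e.g. a full agonist's
    # efficacy pegged at 1), whereas the external-space curvature stays
    # honest there.
    def resid_ext(theta):
        pred = []
        for c in panel:
            p = plan.curve_params_external(c.key, theta)
            pred.append(
                response_general(
                    c.log_conc,
                    SABREParameters(
                        log_kd=p["log_kd"],
                        efficacy=min(max(p["efficacy"], 0.0), 1.0),
                        gain=p["gain"],
                        efficacy_r0=min(max(p["efficacy_r0"], 0.0), 1.0),
                        hill=p["hill"],
                    ),
                )
            )
        return w * (np.concatenate(pred) - y)

    theta_hat = np.array(plan.external(t))
    lo_ext, hi_ext = plan.external_bounds()
    jac_ext = np.empty((n_obs, k))
    for i in range(k):
        h = 1e-6 * max(abs(theta_hat[i]), 1e-3)
        up = min(theta_hat[i] + h, hi_ext[i])
        dn = max(theta_hat[i] - h, lo_ext[i])
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[i], tm[i] = up, dn
        jac_ext[:, i] = (resid_ext(tp) - resid_ext(tm)) / (up - dn)

    dof = max(n_obs - k, 1)
    s2 = float(np.sum(best.fun**2)) / dof
    cov = s2 * np.linalg.pinv(jac_ext.T @ jac_ext)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    rows = []
    for i, (name, gkey, tr, _) in enumerate(plan.entries):
        rows.append(
            {
                "parameter": name,
                "group": gkey if isinstance(gkey, str) else f"{gkey[0]}|{gkey[1]}",
                "value": theta_hat[i],
                "stderr": se[i],
                "kind": "free",
            }
        )
    fixed_seen = set()
    for c in panel:
        for name, (kind, v) in plan.slots[c.key].items():
            if kind == "fixed" and (name, c.key) not in fixed_seen:
                fixed_seen.add((name, c.key))
                rows.append(
                    {
                        "parameter": name,
                        "group": f"{c.ligand_id}|{c.pathway_id}",
                        "value": v,
                        "stderr": np.nan,
                        "kind": "fixed",
                    }
                )

    resid_rows = []
    curve_params = {}
    flags = {}
    for c in panel:
        p = plan.curve_params(c.key, t)
        curve_params[c.key] = p
        pred = response_general(
            c.log_conc,
            SABREParameters(
                p["log_kd"],
                min(p["efficacy"], 1.0),
                p["gain"],
                min(p["efficacy_r0"], 1.0),
                p["hill"],
            ),
        )
        curve_flags = []
        if c.response.max() < LOW_INFORMATION_EMAX:
            curve_flags.append("low_information")
        eg = p["efficacy"] * p["gain"]
        emax_hat = eg / (eg - p["efficacy"] + 1.0)
        if emax_hat < UNRELIABLE_EMAX:
            curve_flags.append("unreliable_ec50")
        if curve_flags:
            flags[c.key] = curve_flags
        for lc, obs, pr in zip(c.log_conc, c.response, pred):
            resid_rows.append(
                {
                    "ligand": c.ligand_id,
                    "pathway": c.pathway_id,
                    "log_conc_M": lc,
                    "observed": obs,
                    "predicted": pr,
                    "residual": pr - obs,
                }
            )

    messages = []
    if scale_indeterminate:
        messages.append(
            "no ligand has a fixed log_kd while gain is free: only "
            "eps*gamma products and eps*gamma-eps+1 shifts are reliable"
        )

    return FitResult(
        model="sabre-global",
        estimates=pd.DataFrame(rows),
        residuals=pd.DataFrame(resid_rows),
        sse=sse,
        aicc=_maybe_aicc(sse, n_obs, k),
        n_params=k,
        n_obs=n_obs,
        converged=bool(best.success),
        seed=seed,
        curve_params=curve_params,
        flags=flags,
        scale_indeterminate=scale_indeterminate,
        obs_fingerprint=_fingerprint(panel),
        messages=messages,
    )


# ---------------------------------------------------------------------------
# metrics


def aicc_least_squares(sse: float, n_obs: int, n_params: int) -> float:
    """Corrected AIC in the Gaussian least-squares form.

    ``AICc = n*ln(SSE/n) + 2k + 2k(k+1)/(n-k-1)`` with ``k`` counting only
    mean-model parameters (the residual-variance parameter is excluded, as
    in common curve-fitting software).
    """
    if sse < 0:
        raise ValueError(f"SSE must be >= 0, got {sse}")
    if sse == 0:
        raise ValueError(
            "SSE is exactly 0: AICc is degenerate (-inf) for a perfect fit"
        )
    k = n_params
    if n_obs - k - 1 <= 0:
        raise ValueError(
            f"AICc undefined: need n_obs - k - 1 > 0 (n_obs={n_obs}, k={k})"
        )
    return float(
        n_obs * np.log(sse / n_obs) + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)
    )


def model_metrics(result: FitResult) -> tuple[float, float]:
    """Return ``(SSE, AICc)`` of a fit; raises if AICc is undefined."""
    return result.sse, aicc_least_squares(result.sse, result.n_obs, result.n_params)


def _maybe_aicc(sse, n_obs, k):
    try:
        return aicc_least_squares(sse, n_obs, k)
    except ValueError:
        return None


def compare_models(a: FitResult, b: FitResult) -> ModelComparison:
    """Compare two fits of the *same* observations by SSE and AICc.

    Akaike weights are computed from the AICc difference; the preferred
    model is the one with the lower AICc.
    """
    if a.obs_fingerprint != b.obs_fingerprint or a.n_obs != b.n_obs:
        raise ValueError(
            "fits were made on different observation sets; comparison is "
            "meaningless"
        )
    _, aicc_a = model_metrics(a)
    _, aicc_b = model_metrics(b)
    d = aicc_a - aicc_b
    # weights on a common scale
    rel = np.exp(-0.5 * np.array([aicc_a - min(aicc_a, aicc_b),
                                  aicc_b - min(aicc_a, aicc_b)]))
    wa, wb = rel / rel.sum()
    preferred = "tie" if d == 0 else ("a" if d < 0 else "b")
    return ModelComparison(
        delta_sse=a.sse - b.sse,
        delta_aicc=d,
        akaike_weight_a=float(wa),
        akaike_weight_b=float(wb),
        preferred=preferred,
    )
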