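"""Synthetic concentration-response panels for testing and demonstration.

Generates multi-ligand, multi-pathway panels from known ground-truth
parameters with optional additive Gaussian noise, plus occupancy-threshold
curves (response proportional to a power of occupancy). Built-in presets
cover the canonical scenarios used throughout the package:

``fig1``
    One full agonist read out through one strongly amplified and one
    strongly attenuated pathway (anchors: 20% occupancy -> ~90% response in
    pathway 1; 80% occupancy -> ~15% response in pathway 2).
``fig4``
    Three compounds x two amplified pathways (gains 15 and 5): a balanced
    full agonist, a biased agonist (pathway efficacies 0.8 vs 0.2), and a
    weak balanced agonist (0.25).
``fig5``
    Same compounds but the second pathway right-shifted (gain 0.15).
``mopr_mcpherson`` / ``mopr_hothersall`` / ``mopr_pedersen``
    DAMGO + morphine two-pathway panels (G-protein activation left-shifted,
    beta-arrestin2 recruitment right-shifted) at published fit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .fitting import ResponseCurve, RESPONSE_MIN, RESPONSE_MAX
from .model import SABREParameters, occupancy, response_general

__all__ = [
    "LigandSpec",
    "PathwaySpec",
    "GridSpec",
    "ScenarioSpec",
    "ThresholdSpec",
    "generate_panel",
    "generate_threshold_panel",
    "generate_mopr_like",
    "scenario_preset",
    "PRESET_NAMES",
    "MOPR_PRESETS",
]


@dataclass(frozen=True)
class LigandSpec:
    """Ground truth for one ligand: binding affinity and per-pathway efficacy."""

    id: str
    log_kd: float
    efficacy: dict  # pathway id -> eps

    def __post_init__(self):
        if not np.isfinite(self.log_kd):
            raise ValueError(f"ligand {self.id!r}: log_kd must be finite")
        for pw, e in self.efficacy.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(
                    f"ligand {self.id!r}, pathway {pw!r}: efficacy {e} not in [0, 1]"
                )


@dataclass(frozen=True)
class PathwaySpec:
    id: str
    gain: float

    def __post_init__(self):
        if not self.gain > 0:
            raise ValueError(f"pathway {self.id!r}: gain must be > 0")


@dataclass(frozen=True)
class GridSpec:
    """Concentration grid. Centred on each ligand's log Kd by default
    (span log-units either side); set ``start``/``stop`` for an absolute
    grid shared by all ligands."""

    points: int = 9
    span: float = 3.0
    start: float | None = None
    stop: float | None = None

    def __post_init__(self):
        if self.points < 2:
            raise ValueError("grid needs >= 2 points")
        if (self.start is None) != (self.stop is None):
            raise ValueError("set both start and stop, or neither")
        if self.start is not None and not self.start < self.stop:
            raise ValueError("grid start must be < stop")

    def log_conc(self, log_kd: float) -> np.ndarray:
        if self.start is not None:
            return np.linspace(self.start, self.stop, self.points)
        return np.linspace(log_kd - self.span, log_kd + self.span, self.points)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full ground-truth panel description; same spec -> identical panel."""

    ligands: tuple
    pathways: tuple
    grid: GridSpec = GridSpec()
    noise_sigma: float = 0.0
    seed: int = 0
    hill: float = 1.0
    efficacy_r0: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        if not self.ligands:
            raise ValueError("scenario needs >= 1 ligand")
        if not self.pathways:
            raise ValueError("scenario needs >= 1 pathway")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        pw_ids = {p.id for p in self.pathways}
        for lig in self.ligands:
            missing = pw_ids - set(lig.efficacy)
            if missing:
                raise ValueError(
                    f"ligand {lig.id!r}: no efficacy for pathway(s) {sorted(missing)}"
                )

    def true_params(self, ligand_id: str, pathway_id: str) -> SABREParameters:
        lig = next(l for l in self.ligands if l.id == ligand_id)
        pw = next(p for p in self.pathways if p.id == pathway_id)
        return SABREParameters(
            log_kd=lig.log_kd,
            efficacy=lig.efficacy[pathway_id],
            gain=pw.gain,
            efficacy_r0=self.efficacy_r0,
            hill=self.hill,
        )

    def log_kd_by_ligand(self) -> dict:
        return {l.id: l.log_kd for l in self.ligands}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ThresholdSpec:
    """Co-occupancy threshold curve: response ~ occupancy**nu.

    ``nu`` is the number of receptors that must be simultaneously occupied
    to trigger the response; ``nu = 1`` reduces to plain occupancy.
    """

    nu: int = 2
    log_kd: float = -7.0
    grid: GridSpec = GridSpec(points=61, span=3.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.nu, (int, np.integer)) and self.nu >= 1):
            raise ValueError(f"nu must be an integer >= 1, got {self.nu!r}")


def generate_panel(spec: ScenarioSpec) -> list[ResponseCurve]:
    """Noisy panel realisation of a scenario.

    Responses are the exact model curves plus iid Gaussian noise on the
    fraction scale, clipped to the admissible response range. One curve per
    ligand-pathway pair, in (ligand, pathway) declaration order.
    """
    rng = np.random.default_rng(spec.seed)
    panel = []
    for lig in spec.ligands:
        logc = spec.grid.log_conc(lig.log_kd)
        for pw in spec.pathways:
            y = response_general(logc, spec.true_params(lig.id, pw.id))
            if spec.noise_sigma > 0:
                y = y + rng.normal(0.0, spec.noise_sigma, size=y.shape)
            y = np.clip(y, RESPONSE_MIN, RESPONSE_MAX)
            panel.append(
                ResponseCurve(
                    ligand_id=lig.id,
                    pathway_id=pw.id,
                    log_conc=logc,
                    response=y,
                )
            )
    return panel


def generate_threshold_panel(tspec: ThresholdSpec) -> ResponseCurve:
    """Single curve with response = occupancy**nu, normalised to its grid
    maximum, plus noise. The proportionality constant is fixed by the
    normalisation, so the result depends (mildly) on the grid span."""
    logc = tspec.grid.log_conc(tspec.log_kd)
    f = occupancy(logc, tspec.log_kd) ** tspec.nu
    f = f / f.max()
    if tspec.noise_sigma > 0:
        rng = np.random.default_rng(tspec.seed)
        f = f + rng.normal(0.0, tspec.noise_sigma, size=f.shape)
    f = np.clip(f, RESPONSE_MIN, RESPONSE_MAX)
    return ResponseCurve(
        ligand_id=f"threshold_nu{tspec.nu}",
        pathway_id="P1",
        log_conc=logc,
        response=f,
    )


# ---------------------------------------------------------------------------
# presets

_GPRT, _BARR = "Gprt", "bArr"

#: published two-pathway fit parameters for the three DAMGO/morphine studies
MOPR_PRESETS = {
    "mopr_mcpherson": {
        "gains": {_GPRT: 30.84, _BARR: 0.669},
        "ligands": {
            "DAMGO": {"log_kd": -6.64, "efficacy": 1.000},
            "morphine": {"log_kd": -6.60, "efficacy": 0.178},
        },
    },
    "mopr_hothersall": {
        "gains": {_GPRT: 9.88, _BARR: 0.193},
        "ligands": {
            "DAMGO": {"log_kd": -6.62, "efficacy": 0.948},
            "morphine": {"log_kd": -6.76, "efficacy": 0.375},
        },
    },
    "mopr_pedersen": {
        "gains": {_GPRT: 15.51, _BARR: 0.059},
        "ligands": {
            "DAMGO": {"log_kd": -7.34, "efficacy": 0.999},
            "morphine": {"log_kd": -7.02, "efficacy": 0.823},
        },
    },
}


def _cpd_tst_scenario(gamma_p2: float, name: str, **kw) -> ScenarioSpec:
    return ScenarioSpec(
        ligands=(
            LigandSpec("CpdTst1", -7.0, {"P1": 1.0, "P2": 1.0}),
            LigandSpec("CpdTst2", -6.5, {"P1": 0.8, "P2": 0.2}),
            LigandSpec("CpdTst3", -8.0, {"P1": 0.25, "P2": 0.25}),
        ),
        pathways=(PathwaySpec("P1", 15.0), PathwaySpec("P2", gamma_p2)),
        name=name,
        **kw,
    )


def scenario_preset(name: str, noise_sigma: float = 0.0, seed: int = 0,
                    grid: GridSpec | None = None) -> ScenarioSpec:
    """Build a named scenario (see module docstring for the catalogue)."""
    kw = {"noise_sigma": noise_sigma, "seed": seed}
    if grid is not None:
        kw["grid"] = grid
    if name == "fig4":
        return _cpd_tst_scenario(5.0, name, **kw)
    if name == "fig5":
        return _cpd_tst_scenario(0.15, name, **kw)
    if name == "fig1":
        # gains chosen so occupancy 20% -> response ~90% (amplified) and
        # occupancy 80% -> response ~15% (attenuated) for the full agonist
        return ScenarioSpec(
            ligands=(LigandSpec("Agonist", -7.0, {"R1": 1.0, "R2": 1.0}),),
            pathways=(PathwaySpec("R1", 36.0), PathwaySpec("R2", 3.0 / 68.0)),
            name=name,
            **kw,
        )
    if name in MOPR_PRESETS:
        cfg = MOPR_PRESETS[name]
        return ScenarioSpec(
            ligands=tuple(
                LigandSpec(
                    lid,
                    entry["log_kd"],
                    {pw: entry["efficacy"] for pw in cfg["gains"]},
                )
                for lid, entry in cfg["ligands"].items()
            ),
            pathways=tuple(PathwaySpec(pw, g) for pw, g in cfg["gains"].items()),
            name=name,
            **kw,
        )
    raise ValueError(
        f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
    )


PRESET_NAMES = ("fig1", "fig4", "fig5") + tuple(MOPR_PRESETS) + ("threshold",)


def generate_mopr_like(
    preset: str,
    grid: GridSpec | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[ResponseCurve]:
    """Two-pathway DAMGO/morphine panel for one of the three study presets."""
    if preset not in MOPR_PRESETS:
        raise ValueError(
            f"unknown study preset {preset!r}; available: "
            f"{', '.join(MOPR_PRESETS)}"
        )
    spec = scenario_preset(preset, noise_sigma=noise_sigma, seed=seed, grid=grid)
    return generate_panel(spec)
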