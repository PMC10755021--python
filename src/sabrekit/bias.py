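"""Biased-agonism diagnostics.

A ligand is *biased* when its pathway-specific efficacies differ after
system-level effects (pathway amplification) are accounted for. The main
entry point refits a two-pathway panel allowing each ligand a separate
efficacy per pathway (gains stay shared per pathway) and compares the two
efficacies; the conventional delta-delta-log(Emax/EC50) comparator against
a reference ligand is provided alongside, as are bias-plot tables
(response in one pathway versus the other at matched concentrations).

Decision rule (documented, configurable): the efficacy difference is
called significant when |delta| > z * SE(delta) with z = 2 by default; if
the difference is not significant but the interval is too wide to have
detected a moderate difference, the verdict is "indeterminate" rather
than "balanced".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import (
    ConstraintSpec,
    FitResult,
    Fixed,
    ResponseCurve,
    Shared,
    fit_hill_per_curve,
    fit_sabre_global,
)
from .model import SABREParameters, response_general

__all__ = [
    "BiasAssessment",
    "fit_pathway_efficacies",
    "bias_plot_data",
    "ddlog_emax_ec50",
    "assessments_to_frame",
]

#: z-multiplier for the significance rule on the efficacy difference
DEFAULT_Z = 2.0

#: widest acceptable z*SE for a confident "balanced" call; wider intervals
#: yield "indeterminate"
DEFAULT_BALANCED_HALFWIDTH = 0.3


@dataclass(frozen=True)
class BiasAssessment:
    """Per-ligand verdict on pathway bias."""

    ligand_id: str
    efficacy_by_pathway: dict
    stderr_by_pathway: dict
    delta_efficacy: float
    delta_stderr: float
    ddlog: float | None
    verdict: str  # "balanced" | "biased" | "indeterminate"
    flags: tuple = ()


def _pathway_pair(panel: Sequence[ResponseCurve]) -> tuple[str, str]:
    pathways = []
    for c in panel:
        if c.pathway_id not in pathways:
            pathways.append(c.pathway_id)
    if len(pathways) < 2:
        raise ValueError(
            f"bias assessment needs >= 2 pathways, panel has {pathways}"
        )
    if len(pathways) > 2:
        raise ValueError(
            f"bias assessment currently compares exactly 2 pathways, "
            f"panel has {pathways}"
        )
    return pathways[0], pathways[1]


def fit_pathway_efficacies(
    panel: Sequence[ResponseCurve],
    constraints: ConstraintSpec,
    z: float = DEFAULT_Z,
    balanced_halfwidth: float = DEFAULT_BALANCED_HALFWIDTH,
    reference_ligand: str | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[list[BiasAssessment], FitResult]:
    """Refit with pathway-specific efficacies and test each ligand for bias.

    The efficacy rule of ``constraints`` is overridden to "one value per
    ligand-pathway pair"; all other rules (typically fixed log Kd, gain
    shared per pathway) are kept. If the refit is scale-indeterminate
    (no fixed Kd anchors the gain), per-pathway efficacies are not
    separately meaningful and the comparison falls back to the
    eps*gamma products (requires ``reference_ligand``).

    Returns the per-ligand assessments and the underlying refit.
    """
    p1, p2 = _pathway_pair(panel)
    refit = fit_sabre_global(
        panel,
        constraints.replace(efficacy=Shared("per-curve")),
        n_starts=n_starts,
        seed=seed,
    )
    est = refit.estimates
    eff = est[(est.parameter == "efficacy") & (est.kind == "free")]
    by_group = {row.group: (row.value, row.stderr) for row in eff.itertuples()}

    ddlogs = {}
    if reference_ligand is not None:
        try:
            hill = fit_hill_per_curve(panel)
            ddlogs = {
                r.ligand_id: r.ddlog
                for r in ddlog_emax_ec50(hill, reference_ligand).itertuples()
            }
        except ValueError:
            ddlogs = {}

    ligands = []
    for c in panel:
        if c.ligand_id not in ligands:
            ligands.append(c.ligand_id)

    out = []
    for lig in ligands:
        flags = []
        for pw in (p1, p2):
            flags.extend(
                f"{pw}:{f}" for f in refit.flags.get((lig, pw), ())
            )
        if refit.scale_indeterminate:
            # efficacies are only identified up to the gain scale; compare
            # eps*gamma products instead
            e1 = refit.params_for(lig, p1)
            e2 = refit.params_for(lig, p2)
            eg1, eg2 = e1["efficacy"] * e1["gain"], e2["efficacy"] * e2["gain"]
            out.append(
                BiasAssessment(
                    ligand_id=lig,
                    efficacy_by_pathway={p1: np.nan, p2: np.nan},
                    stderr_by_pathway={p1: np.nan, p2: np.nan},
                    delta_efficacy=np.nan,
                    delta_stderr=np.nan,
                    ddlog=ddlogs.get(lig),
                    verdict="indeterminate",
                    flags=tuple(
                        flags
                        + [
                            "scale_indeterminate",
                            f"egamma_products:{eg1:.4g}|{eg2:.4g}",
                        ]
                    ),
                )
            )
            continue

        v1, se1 = by_group[f"{lig}|{p1}"]
        v2, se2 = by_group[f"{lig}|{p2}"]
        delta = v1 - v2
        se = float(np.hypot(se1, se2))
        if abs(delta) > z * se:
            verdict = "biased"
        elif z * se <= balanced_halfwidth:
            verdict = "balanced"
        else:
            verdict = "indeterminate"
        out.append(
            BiasAssessment(
                ligand_id=lig,
                efficacy_by_pathway={p1: v1, p2: v2},
                stderr_by_pathway={p1: se1, p2: se2},
                delta_efficacy=float(delta),
                delta_stderr=se,
                ddlog=ddlogs.get(lig),
                verdict=verdict,
                flags=tuple(flags),
            )
        )
    return out, refit


def bias_plot_data(
    params: Mapping[str, Mapping[str, SABREParameters]],
    logL: np.ndarray,
) -> pd.DataFrame:
    """Paired response series for bias plots.

    Parameters
    ----------
    params : mapping ligand -> {pathway -> SABREParameters}
        Exactly two pathways per ligand.
    logL : array_like
        Common log10 molar concentration grid.

    Returns
    -------
    DataFrame with columns ligand, log_conc_M, pathway ids as response
    columns ``resp_<pathway>``; the parametric (resp1, resp2) trace runs
    from (0, 0) toward the two asymptotic maxima.
    """
    logL = np.asarray(logL, dtype=float)
    frames = []
    for lig, per_pathway in params.items():
        if len(per_pathway) != 2:
            raise ValueError(
                f"ligand {lig!r}: bias plots need exactly 2 pathways, "
                f"got {list(per_pathway)}"
            )
        cols = {"ligand": lig, "log_conc_M": logL}
        for pw, p in per_pathway.items():
            cols[f"resp_{pw}"] = response_general(logL, p)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def ddlog_emax_ec50(hill_fits: FitResult, reference_ligand: str) -> pd.DataFrame:
    """Conventional bias comparator: delta-delta-log10(Emax/EC50).

    For each ligand and pathway, log10(e_max/EC50) is taken from the
    per-curve sigmoid fits; the reference ligand's value is subtracted
    within each pathway, and the two pathways are differenced. The
    reference ligand's ddlog is identically 0, and the quantity is
    invariant to rescaling all concentrations.
    """
    per = {}
    for (lig, pw), p in hill_fits.curve_params.items():
        per.setdefault(lig, {})[pw] = np.log10(p["e_max"]) - p["log_ec50"]
    if reference_ligand not in per:
        raise ValueError(
            f"reference ligand {reference_ligand!r} not in the fitted panel "
            f"(have {sorted(per)})"
        )
    pathways = sorted({pw for d in per.values() for pw in d})
    if len(pathways) != 2:
        raise ValueError(f"ddlog needs exactly 2 pathways, got {pathways}")
    p1, p2 = pathways
    ref = per[reference_ligand]
    if p1 not in ref or p2 not in ref:
        raise ValueError(
            f"reference ligand {reference_ligand!r} lacks a fit in both pathways"
        )
    rows = []
    for lig, d in per.items():
        if p1 not in d or p2 not in d:
            continue
        dlog1 = d[p1] - ref[p1]
        dlog2 = d[p2] - ref[p2]
        rows.append(
            {
                "ligand_id": lig,
                f"log_emax_ec50_{p1}": d[p1],
                f"log_emax_ec50_{p2}": d[p2],
                f"dlog_{p1}": dlog1,
                f"dlog_{p2}": dlog2,
                "ddlog": dlog1 - dlog2,
            }
        )
    return pd.DataFrame(rows)


def assessments_to_frame(assessments: Sequence[BiasAssessment]) -> pd.DataFrame:
    """Flatten assessments into the CSV-friendly bias table."""
    rows = []
    for a in assessments:
        pws = list(a.efficacy_by_pathway)
        rows.append(
            {
                "ligand_id": a.ligand_id,
                **{f"efficacy_{pw}": a.efficacy_by_pathway[pw] for pw in pws},
                **{f"stderr_{pw}": a.stderr_by_pathway[pw] for pw in pws},
                "delta_efficacy": a.delta_efficacy,
                "delta_stderr": a.delta_stderr,
                "ddlog": np.nan if a.ddlog is None else a.ddlog,
                "verdict": a.verdict,
                "flags": ";".join(a.flags),
            }
        )
    return pd.DataFrame(rows)
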