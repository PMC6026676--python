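"""Per-subsystem (pathway) sensitivity to reaction blocking.

For each blocking scenario, the fraction of a subsystem's reactions whose
flux changes beyond a threshold relative to the unblocked reference state
is computed, either from a single parsimonious FBA flux vector (FBA mode)
or from flux variability ranges (FVA mode). Reactions without a subsystem
annotation are kept in the model but excluded from the report.

Scenarios that abolish growth cannot support a biomass-optimal flux state;
for those the comparison uses a feasibility-relaxed state (objective
constraint dropped, total flux parsimoniously minimized) and the row is
flagged ``lethal``. This relaxation is a documented interpretive choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional

import pandas as pd

from .errors import ValidationError
from .fba import FluxSolution, block, fba, fva, min_norm_state
from .lethality import GROWTH_THRESHOLD
from .model import MetabolicModel


@dataclass(frozen=True)
class BlockScenario:
    blocked_ids: FrozenSet[str]
    mode: str = "full"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= len(self.blocked_ids) <= 2):
            raise ValidationError("a scenario blocks at most 2 reactions")
        if not self.label:
            object.__setattr__(self, "label", "|".join(sorted(self.blocked_ids)) or "none")


@dataclass
class PathwaySensitivityReport:
    mode: str  # "fba" | "fva"
    threshold: float
    threshold_mode: str  # "absolute" | "relative"
    rows: List[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["scenario", "subsystem", "n_reactions", "n_altered",
                "fraction_altered", "lethal", "mode"]
        if self.mode == "fva":
            cols += ["mean_midpoint", "mean_width"]
        return pd.DataFrame(self.rows, columns=cols)

    def matrix(self) -> pd.DataFrame:
        """Scenario x subsystem matrix of fraction_altered (heatmap-ready)."""
        df = self.to_frame()
        if df.empty:
            return df
        return df.pivot_table(
            index="scenario", columns="subsystem", values="fraction_altered"
        ).sort_index()

    def altered_sets(self) -> Dict[str, set]:
        """Per scenario label, the set of individual altered reaction ids."""
        out: Dict[str, set] = {}
        for row in self.rows:
            out.setdefault(row["scenario"], set()).update(row.get("_altered_ids", ()))
        return out


def _subsystem_map(model: MetabolicModel) -> Dict[str, List[str]]:
    subsys: Dict[str, List[str]] = {}
    for rxn in model.reactions:
        name = (rxn.subsystem or "").strip()
        if not name or name.lower() == "unclassified":
            continue
        subsys.setdefault(name, []).append(rxn.id)
    return subsys


def reference_fluxes(model: MetabolicModel, solver: str = "highs") -> FluxSolution:
    """Parsimonious FBA optimum of the unblocked model."""
    sol = fba(model, tie_break="parsimonious", solver=solver)
    if not sol.optimal:
        from .errors import InfeasibleModelError

        raise InfeasibleModelError(f"reference model is {sol.status}")
    return sol


def _is_altered(v: float, v_ref: float, threshold: float, threshold_mode: str) -> bool:
    if threshold_mode == "absolute":
        return abs(v - v_ref) > threshold
    if threshold_mode == "relative":
        if abs(v_ref) > 1e-9:
            return abs(v - v_ref) > threshold * abs(v_ref)
        return abs(v) > 1e-6
    raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")


def sensitivity_fba(
    model: MetabolicModel,
    scenarios: Iterable[BlockScenario],
    threshold: float = 0.01,
    threshold_mode: str = "absolute",
    growth_threshold: float = GROWTH_THRESHOLD,
    reference: Optional[FluxSolution] = None,
    solver: str = "highs",
) -> PathwaySensitivityReport:
    """Fraction of each subsystem's reactions with flux changes beyond
    ``threshold`` (mmol/gDW/h absolute, or relative) under each scenario."""
    if reference is None:
        reference = reference_fluxes(model, solver)
    subsys = _subsystem_map(model)
    report = PathwaySensitivityReport("fba", threshold, threshold_mode)

    for scen in scenarios:
        blocked = block(model, scen.blocked_ids, scen.mode)
        sol = fba(blocked, tie_break="parsimonious", solver=solver)
        lethal = (not sol.optimal) or sol.objective_value < growth_threshold
        if lethal:
            sol = min_norm_state(blocked, solver=solver)
        for name in sorted(subsys):
            rids = subsys[name]
            altered = [
                rid
                for rid in rids
                if _is_altered(
                    sol.fluxes.get(rid, 0.0),
                    reference.fluxes.get(rid, 0.0),
                    threshold,
                    threshold_mode,
                )
            ]
            report.rows.append(
                {
                    "scenario": scen.label,
                    "subsystem": name,
                    "n_reactions": len(rids),
                    "n_altered": len(altered),
                    "fraction_altered": len(altered) / len(rids),
                    "lethal": lethal,
                    "mode": "fba",
                    "_altered_ids": altered,
                }
            )
    return report


def sensitivity_fva(
    model: MetabolicModel,
    scenarios: Iterable[BlockScenario],
    fraction: float = 0.90,
    threshold: float = 0.01,
    threshold_mode: str = "absolute",
    growth_threshold: float = GROWTH_THRESHOLD,
    solver: str = "highs",
) -> PathwaySensitivityReport:
    """FVA-mode sensitivity: flux ranges at >= ``fraction`` of each scenario's
    own optimum, compared to the unblocked reference ranges.

    A reaction counts as altered when its range midpoint shifts, or its range
    width changes, by more than the threshold -- this reduces to the FBA rule
    when ranges collapse to points.
    """
    subsys = _subsystem_map(model)
    classified = sorted({rid for rids in subsys.values() for rid in rids})
    ref_ranges = fva(model, fraction=fraction, reaction_ids=classified, solver=solver)
    report = PathwaySensitivityReport("fva", threshold, threshold_mode)

    for scen in scenarios:
        blocked = block(model, scen.blocked_ids, scen.mode)
        sol = fba(blocked, solver=solver)
        lethal = (not sol.optimal) or sol.objective_value < growth_threshold
        ranges = fva(
            blocked,
            fraction=fraction,
            reaction_ids=classified,
            solver=solver,
            require_growth=not lethal,
        )
        for name in sorted(subsys):
            rids = subsys[name]
            altered = []
            mids, widths = [], []
            for rid in rids:
                lo, hi = ranges[rid]
                rlo, rhi = ref_ranges[rid]
                mid, width = 0.5 * (lo + hi), hi - lo
                rmid, rwidth = 0.5 * (rlo + rhi), rhi - rlo
                mids.append(mid)
                widths.append(width)
                shifted = _is_altered(mid, rmid, threshold, threshold_mode)
                reshaped = _is_altered(width, rwidth, threshold, threshold_mode)
                if shifted or reshaped:
                    altered.append(rid)
            report.rows.append(
                {
                    "scenario": scen.label,
                    "subsystem": name,
                    "n_reactions": len(rids),
                    "n_altered": len(altered),
                    "fraction_altered": len(altered) / len(rids),
                    "lethal": lethal,
                    "mode": "fva",
                    "mean_midpoint": sum(mids) / len(mids),
                    "mean_width": sum(widths) / len(widths),
                    "_altered_ids": altered,
                }
            )
    return report
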