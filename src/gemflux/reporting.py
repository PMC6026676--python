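"""Report writers and cross-organism aggregation.

All outputs are plain TSV/JSON with sorted keys and fixed float formatting,
so re-running a pipeline with the same configuration and inputs reproduces
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd

from . import lethality as _lethality
from . import nutrients as _nutrients
from . import secretion as _secretion
from . import sensitivity as _sensitivity
from .config import AnalysisConfig
from .errors import ValidationError
from .lethality import LethalityResult
from .model import MediumSpec, MetabolicModel, apply_medium, detect_exchanges, oxygen_exchange_ids

log = logging.getLogger("gemflux")

_FLOAT_FMT = "%.10g"


def _fmt(value) -> str:
    if isinstance(value, float):
        return _FLOAT_FMT % (value + 0.0)  # normalizes -0.0
    return str(value)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: _FLOAT_FMT % (v + 0.0))
    df.to_csv(path, sep="\t", index=False)


def write_json(data: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# per-stage writers
# ---------------------------------------------------------------------------


def lethality_tables(
    result: LethalityResult, model: MetabolicModel
) -> Dict[str, pd.DataFrame]:
    exchanges = detect_exchanges(model)
    singles = pd.DataFrame(
        [
            {
                "reaction_id": rid,
                "is_exchange": rid in exchanges,
                "subsystem": model.reaction(rid).subsystem or "",
            }
            for rid in sorted(result.single_lethals)
        ],
        columns=["reaction_id", "is_exchange", "subsystem"],
    )
    pairs = pd.DataFrame(
        [
            {
                "id_a": a,
                "id_b": b,
                "n_exchange_members": sum(r in exchanges for r in (a, b)),
            }
            for a, b in result.sorted_pairs()
        ],
        columns=["id_a", "id_b", "n_exchange_members"],
    )
    return {"singles": singles, "pairs": pairs}


def lethality_summary(result: LethalityResult) -> dict:
    return {
        "wild_type_growth": result.wild_type_growth,
        "n_single_lethals": len(result.single_lethals),
        "n_exchange_single_lethals": len(result.exchange_single_lethals),
        "n_double_lethals": len(result.double_lethals),
        "n_pairs_with_exchange": len(result.pairs_with_exchange),
        "n_pairs_two_exchanges": len(result.pairs_two_exchanges),
        "n_conditions_tested": result.n_conditions_tested,
    }


def compare_organisms(results: Dict[str, LethalityResult]) -> dict:
    """Shared / exclusive lethal sets across organisms."""
    names = sorted(results)
    if not names:
        raise ValidationError("no organisms to compare")
    single_sets = {n: results[n].single_lethals for n in names}
    exch_sets = {n: results[n].exchange_single_lethals for n in names}
    pair_sets = {n: results[n].double_lethals for n in names}
    pair_exch = {n: results[n].pairs_with_exchange for n in names}

    def _shared(sets: dict) -> set:
        vals = list(sets.values())
        if len(vals) < 2:
            return set()
        out = set(vals[0])
        for s in vals[1:]:
            out &= s
        return out

    def _exclusive(sets: dict) -> dict:
        out = {}
        for n in names:
            others = set().union(*(sets[m] for m in names if m != n)) if len(names) > 1 else set()
            out[n] = sorted(
                x if isinstance(x, str) else "|".join(sorted(x))
                for x in (sets[n] - others)
            )
        return out

    shared_pairs = _shared(pair_sets)
    return {
        "organisms": names,
        "shared_single_lethals": sorted(_shared(single_sets)),
        "n_shared_single_lethals": len(_shared(single_sets)),
        "exclusive_single_lethals": {n: len(v) for n, v in _exclusive(single_sets).items()},
        "shared_essential_exchanges": sorted(_shared(exch_sets)),
        "n_shared_essential_exchanges": len(_shared(exch_sets)),
        "shared_double_lethals": sorted("|".join(sorted(p)) for p in shared_pairs),
        "n_shared_double_lethals": len(shared_pairs),
        "n_shared_pairs_with_exchange": len(_shared(pair_exch)),
        "per_organism": {n: lethality_summary(results[n]) for n in names},
    }


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class OrganismInput:
    name: str
    model: MetabolicModel
    medium: Optional[MediumSpec] = None


def run_pipeline(
    config: AnalysisConfig, inputs: List[OrganismInput], outdir: Optional[str] = None
) -> dict:
    """Lethality -> pathway sensitivity -> nutrient search -> secretion,
    per organism, then cross-organism aggregation. Deterministic given
    config + inputs; returns the aggregate summary dict."""
    config.validate()
    if not inputs:
        raise ValidationError("run_pipeline needs at least one organism")
    outdir = outdir or config.output_dir
    os.makedirs(outdir, exist_ok=True)

    lethality_results: Dict[str, LethalityResult] = {}
    profiles = []
    for org in inputs:
        org_dir = os.path.join(outdir, org.name)
        os.makedirs(org_dir, exist_ok=True)
        model = org.model
        if org.medium is not None:
            model = apply_medium(model, org.medium)

        log.info("[%s] lethality: %d reactions", org.name, len(model.reactions))
        result = _lethality.analyze(
            model,
            threshold=config.growth_threshold,
            cutoff_mode=config.lethality_cutoff_mode,
            solver=config.solver,
        )
        lethality_results[org.name] = result
        tables = lethality_tables(result, model)
        write_tsv(tables["singles"], os.path.join(org_dir, "singles.tsv"))
        write_tsv(tables["pairs"], os.path.join(org_dir, "pairs.tsv"))
        write_json(lethality_summary(result), os.path.join(org_dir, "lethality.json"))

        # sensitivity: each single lethal and each non-essential exchange
        exchanges = detect_exchanges(model)
        scen_ids = sorted(result.single_lethals) + sorted(
            exchanges - result.single_lethals
        )
        scenarios = [
            _sensitivity.BlockScenario(blocked_ids=frozenset((rid,))) for rid in scen_ids
        ]
        log.info("[%s] sensitivity: %d scenarios (FBA mode)", org.name, len(scenarios))
        report = _sensitivity.sensitivity_fba(
            model,
            scenarios,
            threshold=config.flux_change_threshold,
            threshold_mode="absolute",
            growth_threshold=config.growth_threshold,
            solver=config.solver,
        )
        frame = report.to_frame()
        write_tsv(frame, os.path.join(org_dir, "sensitivity_fba.tsv"))
        matrix = report.matrix()
        if not matrix.empty:
            write_tsv(matrix.reset_index(), os.path.join(org_dir, "sensitivity_fba_matrix.tsv"))
        if config.include_fva:
            log.info("[%s] sensitivity: FVA mode", org.name)
            report_fva = _sensitivity.sensitivity_fva(
                model,
                scenarios,
                fraction=config.fva_fraction,
                threshold=config.flux_change_threshold,
                growth_threshold=config.growth_threshold,
                solver=config.solver,
            )
            write_tsv(report_fva.to_frame(), os.path.join(org_dir, "sensitivity_fva.tsv"))

        # nutrient search, anaerobic always; aerobic too when oxygen exists
        state = _nutrients.base_state(
            model,
            result.exchange_single_lethals,
            growth_threshold=config.growth_threshold,
            solver=config.solver,
        )
        regimes = ["anaerobic"]
        if oxygen_exchange_ids(model):
            regimes.append("aerobic")
        combo_rows = []
        for regime in regimes:
            log.info("[%s] nutrient search: regime=%s k_max=%d", org.name, regime, config.k_max)
            combos = _nutrients.search_combos(
                state,
                k_max=config.k_max,
                regime=regime,
                growth_threshold=config.growth_threshold,
                combo_cap=config.combo_cap,
                solver=config.solver,
            )
            combo_rows += [
                {
                    "combo_members": "|".join(c.sorted_members()),
                    "k": c.k,
                    "regime": c.regime,
                    "growth": c.growth,
                    "grows": c.grows,
                    "minimal": c.minimal,
                }
                for c in combos
            ]
        write_tsv(
            pd.DataFrame(
                combo_rows,
                columns=["combo_members", "k", "regime", "growth", "grows", "minimal"],
            ),
            os.path.join(org_dir, "nutrient_combos.tsv"),
        )

        # secretion profile needs a medium
        if org.medium is not None:
            log.info("[%s] secretion profile", org.name)
            prof = _secretion.profile(
                org.model, org.medium, organism=org.name, solver=config.solver
            )
            profiles.append(prof)
            write_tsv(prof.to_frame(), os.path.join(org_dir, "secretion.tsv"))

    summary = {
        "config": config.to_dict(),
        "comparison": compare_organisms(lethality_results),
    }
    if len(profiles) >= 2:
        matrix = _secretion.build_interaction_matrix(profiles)
        write_tsv(matrix.to_frame(), os.path.join(outdir, "interaction_matrix.tsv"))
        codes = matrix.code_matrix([p.organism for p in profiles])
        write_tsv(codes.reset_index(names="metabolite_id"),
                  os.path.join(outdir, "interaction_codes.tsv"))
        summary["interaction"] = {
            met: e["classification"] for met, e in matrix.entries.items()
        }
    write_json(summary, os.path.join(outdir, "summary.json"))
    return summary
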