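"""Linear-programming core: FBA, parsimonious tie-breaking, FVA, blocking.

Two interchangeable LP backends are supported: ``highs`` (scipy's dual
simplex) and ``glpk`` (via swiglpk). Results agree to 1e-6 by contract;
solver feasibility/optimality tolerances are ~1e-9, assertions downstream
use 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import spearmanr

from .errors import InfeasibleModelError, SolverError, ValidationError
from .model import MetabolicModel

#: fluxes below this magnitude are treated as zero (support detection).
FLUX_EPS = 1e-9

SOLVERS = ("highs", "glpk")

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    """One LP solution: status, objective value, and a full flux vector.

    ``objective_value`` is the raw LP optimum -- 1/h for a biomass objective,
    mmol/gDW/h for metabolite exchange objectives (source models label
    biomass flux in mmol/gDW/h; we report the raw value either way).
    """

    status: str
    objective_value: Optional[float]
    fluxes: Dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def support(self, eps: float = FLUX_EPS) -> Set[str]:
        return {rid for rid, v in self.fluxes.items() if abs(v) > eps}


# ---------------------------------------------------------------------------
# backend-neutral LP solve
# ---------------------------------------------------------------------------


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sparse.spmatrix],
    b_eq: Optional[np.ndarray],
    bounds: Sequence[Tuple[Optional[float], Optional[float]]],
    A_ub: Optional[sparse.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
    maximize: bool = False,
    solver: str = "highs",
) -> Tuple[str, Optional[float], Optional[np.ndarray]]:
    if solver == "highs":
        return _solve_scipy(c, A_eq, b_eq, bounds, A_ub, b_ub, maximize)
    if solver == "glpk":
        return _solve_glpk(c, A_eq, b_eq, bounds, A_ub, b_ub, maximize)
    raise ValidationError(f"unknown solver {solver!r}; supported: {SOLVERS}")


def _solve_scipy(c, A_eq, b_eq, bounds, A_ub, b_ub, maximize):
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(bounds),
        method="highs-ds",
    )
    if res.status == 0:
        return OPTIMAL, sign * res.fun, res.x
    if res.status == 2:
        return INFEASIBLE, None, None
    if res.status == 3:
        return UNBOUNDED, None, None
    raise SolverError(f"HiGHS returned status {res.status}: {res.message}")


def _solve_glpk(c, A_eq, b_eq, bounds, A_ub, b_ub, maximize):
    import swiglpk as glp

    glp.glp_term_out(glp.GLP_OFF)
    lp = glp.glp_create_prob()
    try:
        glp.glp_set_obj_dir(lp, glp.GLP_MAX if maximize else glp.GLP_MIN)
        n = len(c)
        glp.glp_add_cols(lp, n)
        for j in range(n):
            lo, hi = bounds[j]
            if lo is None and hi is None:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FR, 0.0, 0.0)
            elif lo is None:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_UP, 0.0, float(hi))
            elif hi is None:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, float(lo), 0.0)
            elif lo == hi:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, float(lo), float(hi))
            else:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_DB, float(lo), float(hi))
            if c[j] != 0:
                glp.glp_set_obj_coef(lp, j + 1, float(c[j]))

        blocks = []
        if A_eq is not None and A_eq.shape[0]:
            blocks.append((A_eq, b_eq, "eq"))
        if A_ub is not None and A_ub.shape[0]:
            blocks.append((A_ub, b_ub, "ub"))
        n_rows = sum(b[0].shape[0] for b in blocks)
        if n_rows:
            glp.glp_add_rows(lp, n_rows)
            row0 = 0
            entries: List[Tuple[int, int, float]] = []
            for A, b, kind in blocks:
                coo = sparse.coo_matrix(A)
                for i in range(A.shape[0]):
                    if kind == "eq":
                        glp.glp_set_row_bnds(
                            lp, row0 + i + 1, glp.GLP_FX, float(b[i]), float(b[i])
                        )
                    else:
                        glp.glp_set_row_bnds(
                            lp, row0 + i + 1, glp.GLP_UP, 0.0, float(b[i])
                        )
                for i, j, v in zip(coo.row, coo.col, coo.data):
                    entries.append((row0 + int(i) + 1, int(j) + 1, float(v)))
                row0 += A.shape[0]
            nnz = len(entries)
            ia = glp.intArray(nnz + 1)
            ja = glp.intArray(nnz + 1)
            ar = glp.doubleArray(nnz + 1)
            for k, (i, j, v) in enumerate(entries, start=1):
                ia[k] = i
                ja[k] = j
                ar[k] = v
            glp.glp_load_matrix(lp, nnz, ia, ja, ar)

        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        parm.presolve = glp.GLP_ON
        ret = glp.glp_simplex(lp, parm)
        if ret == glp.GLP_ENOPFS:
            return INFEASIBLE, None, None
        if ret == glp.GLP_ENODFS:
            return UNBOUNDED, None, None
        if ret != 0:
            raise SolverError(f"GLPK simplex returned code {ret}")
        status = glp.glp_get_status(lp)
        if status == glp.GLP_OPT:
            x = np.array([glp.glp_get_col_prim(lp, j + 1) for j in range(n)])
            return OPTIMAL, glp.glp_get_obj_val(lp), x
        if status == glp.GLP_NOFEAS:
            return INFEASIBLE, None, None
        if status == glp.GLP_UNBND:
            return UNBOUNDED, None, None
        raise SolverError(f"GLPK status {status}")
    finally:
        glp.glp_delete_prob(lp)


# ---------------------------------------------------------------------------
# model-level problems
# ---------------------------------------------------------------------------


def _bounds_list(model: MetabolicModel):
    out = []
    for r in model.reactions:
        lo = None if np.isinf(r.lower_bound) else float(r.lower_bound)
        hi = None if np.isinf(r.upper_bound) else float(r.upper_bound)
        out.append((lo, hi))
    return out


def _fluxes_dict(model: MetabolicModel, x: np.ndarray) -> Dict[str, float]:
    return {r.id: (float(x[j]) if abs(x[j]) > 1e-12 else 0.0) for j, r in enumerate(model.reactions)}


def fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    direction: str = "max",
    tie_break: str = "none",
    solver: str = "highs",
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction flux at steady state.

    With ``tie_break='parsimonious'``, a second LP selects -- among the
    optimal solutions -- the flux vector minimizing total absolute flux,
    which makes downstream flux comparisons deterministic.
    """
    if objective_id is None:
        objective_id = model.objective_reaction_id
    if not model.has_reaction(objective_id):
        raise ValidationError(f"objective reaction {objective_id!r} not in model")
    if direction not in ("max", "min"):
        raise ValidationError(f"direction must be 'max' or 'min', got {direction!r}")

    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    b_eq = np.zeros(S.shape[0])
    bounds = _bounds_list(model)
    c = np.zeros(n)
    c[model._rxn_index[objective_id]] = 1.0

    status, obj, x = solve_lp(
        c, S, b_eq, bounds, maximize=(direction == "max"), solver=solver
    )
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=None, fluxes={})
    obj = float(obj) + 0.0  # normalize -0.0
    if tie_break == "none":
        return FluxSolution(OPTIMAL, obj, _fluxes_dict(model, x))
    if tie_break != "parsimonious":
        raise ValidationError(f"unknown tie_break {tie_break!r}")

    x2 = _parsimonious_stage(model, S, bounds, c, obj, direction, solver)
    return FluxSolution(OPTIMAL, obj, _fluxes_dict(model, x2))


def _parsimonious_stage(model, S, bounds, c, optimum, direction, solver):
    """Among objective-optimal solutions, minimize sum |v| via split aux vars."""
    n = len(model.reactions)
    eye = sparse.identity(n, format="csr")
    A_eq = sparse.hstack([S, sparse.csr_matrix(S.shape)], format="csr")
    b_eq = np.zeros(S.shape[0])
    #  v - t <= 0 ; -v - t <= 0 ; objective pinned at its optimum
    rows = [
        sparse.hstack([eye, -eye], format="csr"),
        sparse.hstack([-eye, -eye], format="csr"),
    ]
    eps = 1e-9 * max(1.0, abs(optimum))
    c_row = sparse.csr_matrix(c)
    zero_row = sparse.csr_matrix((1, n))
    if direction == "max":
        rows.append(sparse.hstack([-c_row, zero_row], format="csr"))
        b_extra = -(optimum - eps)
    else:
        rows.append(sparse.hstack([c_row, zero_row], format="csr"))
        b_extra = optimum + eps
    A_ub = sparse.vstack(rows, format="csr")
    b_ub = np.concatenate([np.zeros(2 * n), [b_extra]])
    t_bounds = []
    for lo, hi in bounds:
        cap = max(abs(lo) if lo is not None else np.inf,
                  abs(hi) if hi is not None else np.inf)
        t_bounds.append((0.0, None if np.isinf(cap) else cap))
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    status, _, x = solve_lp(
        c2, A_eq, b_eq, list(bounds) + t_bounds, A_ub, b_ub, maximize=False, solver=solver
    )
    if status != OPTIMAL:
        raise SolverError(f"parsimonious stage unexpectedly {status}")
    return x[:n]


def min_norm_state(model: MetabolicModel, solver: str = "highs") -> FluxSolution:
    """Feasibility-relaxed flux state: minimize sum |v| with no objective."""
    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    bounds = _bounds_list(model)
    eye = sparse.identity(n, format="csr")
    A_eq = sparse.hstack([S, sparse.csr_matrix(S.shape)], format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])], format="csr"
    )
    t_bounds = [(0.0, None)] * n
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    status, obj, x = solve_lp(
        c2, A_eq, np.zeros(S.shape[0]), bounds + t_bounds,
        A_ub, np.zeros(2 * n), maximize=False, solver=solver,
    )
    if status != OPTIMAL:
        return FluxSolution(status, None, {})
    return FluxSolution(OPTIMAL, float(obj), _fluxes_dict(model, x[:n]))


def fva(
    model: MetabolicModel,
    fraction: float = 1.0,
    reaction_ids: Optional[Iterable[str]] = None,
    solver: str = "highs",
    require_growth: bool = True,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability: per-reaction min/max at >= ``fraction`` of the optimum.

    With ``require_growth=False`` the objective constraint is dropped and
    the raw feasible flux ranges are returned (used for lethal scenarios).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fva fraction must be in (0, 1], got {fraction}")
    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    else:
        reaction_ids = list(reaction_ids)
        for rid in reaction_ids:
            if not model.has_reaction(rid):
                raise ValidationError(f"unknown reaction {rid!r}")

    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    b_eq = np.zeros(S.shape[0])
    bounds = _bounds_list(model)

    A_ub = None
    b_ub = None
    if require_growth:
        ref = fba(model, solver=solver)
        if not ref.optimal:
            raise InfeasibleModelError(
                f"cannot run FVA: biomass FBA is {ref.status}"
            )
        optimum = ref.objective_value
        c_obj = np.zeros(n)
        c_obj[model._rxn_index[model.objective_reaction_id]] = 1.0
        floor = fraction * optimum - 1e-9 * max(1.0, abs(optimum))
        A_ub = sparse.csr_matrix(-c_obj)
        b_ub = np.array([-floor])

    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in reaction_ids:
        j = model._rxn_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo_st, lo, _ = solve_lp(c, S, b_eq, bounds, A_ub, b_ub, maximize=False, solver=solver)
        hi_st, hi, _ = solve_lp(c, S, b_eq, bounds, A_ub, b_ub, maximize=True, solver=solver)
        if lo_st == INFEASIBLE or hi_st == INFEASIBLE:
            raise InfeasibleModelError(
                f"FVA infeasible under objective >= {fraction} x optimum (reaction {rid})"
            )
        lo = -np.inf if lo_st == UNBOUNDED else float(lo)
        hi = np.inf if hi_st == UNBOUNDED else float(hi)
        if lo > hi:  # numerical crossing at a vertex
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return ranges


def block(
    model: MetabolicModel, reaction_ids: Iterable[str], mode: str = "full"
) -> MetabolicModel:
    """Copy of the model with the given reactions blocked.

    ``full`` zeroes both bounds; ``uptake_only`` raises the lower bound to 0
    and is only valid for exchange reactions.
    """
    ids = set(reaction_ids)
    for rid in ids:
        if not model.has_reaction(rid):
            raise ValidationError(f"cannot block unknown reaction {rid!r}")
    out = model.copy()
    for rid in ids:
        rxn = out.reaction(rid)
        if mode == "full":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        elif mode == "uptake_only":
            if not model.reaction(rid).is_exchange:
                raise ValidationError(
                    f"uptake_only blocking applies to exchange reactions; "
                    f"{rid!r} is not one"
                )
            rxn.lower_bound = max(0.0, rxn.lower_bound)
        else:
            raise ValidationError(f"unknown blocking mode {mode!r}")
    out._flag_exchanges()
    return out


def flux_spearman(
    sol_a: FluxSolution, sol_b: FluxSolution, eps: float = FLUX_EPS
) -> Tuple[float, int]:
    """Spearman rank correlation over reactions non-null in both solutions."""
    if not (sol_a.optimal and sol_b.optimal):
        raise ValidationError("flux_spearman requires two optimal solutions")
    shared = sorted(set(sol_a.fluxes) & set(sol_b.fluxes))
    pairs = [
        (sol_a.fluxes[rid], sol_b.fluxes[rid])
        for rid in shared
        if abs(sol_a.fluxes[rid]) > eps and abs(sol_b.fluxes[rid]) > eps
    ]
    n = len(pairs)
    if n < 3:
        raise ValidationError(f"flux_spearman needs >= 3 jointly non-null fluxes, got {n}")
    a, b = zip(*pairs)
    rho = float(spearmanr(a, b).statistic)
    return rho, n


def mass_balance_residual(model: MetabolicModel, sol: FluxSolution) -> float:
    """Max |S.v| over metabolites; ~0 for any valid steady-state solution."""
    S = model.stoichiometric_matrix()
    v = np.array([sol.fluxes.get(r.id, 0.0) for r in model.reactions])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0
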