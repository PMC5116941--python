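"""Flux balance analysis: maximize c'v subject to Sv = 0, bounds and flux
couplings, with a secondary total-flux minimization.

The LP is built on split non-negative flux variables v = p − q so that
absolute-value terms (|v| in couplings, the L1 secondary objective) stay
linear; scipy's HiGHS solver does the work. The secondary stage fixes the
primary objective at its optimum (within ``tol_fix``) and minimizes Σ|vᵢ|
(``l1``, the default, a pure LP) or Σvᵢ² (``l2``, a small QP solved with
SLSQP), suppressing needlessly high fluxes and futile cycles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicModel

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

_LINPROG_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}


@dataclass
class FluxSolution:
    """Result of an FBA optimization.

    ``objective_value`` is in the objective reaction's units (h⁻¹ for
    biomass); ``fluxes`` maps reaction id to mmol·gDCW⁻¹·h⁻¹.
    ``total_free_energy`` (kJ·gDCW⁻¹·h⁻¹) is populated by the thermo
    ledger's GIBBS drain when the model has been augmented.
    """

    status: str
    objective_value: float = 0.0
    fluxes: dict[str, float] = field(default_factory=dict)
    total_free_energy: float | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


def _assemble(model: MetabolicModel):
    S, mids, rids = model.stoichiometric_matrix()
    n = len(rids)
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    # split variables: x = [p; q], v = p - q, p >= 0 carries forward flux.
    p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    q_lo, q_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    bounds = list(zip(p_lo, p_hi)) + list(zip(q_lo, q_hi))
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    rows, ubs = [], []
    for coupling in model.couplings:
        row = np.zeros(2 * n)
        for rid, a in coupling.abs_terms.items():
            j = rids.index(rid)
            row[j] += a
            row[n + j] += a
        for rid, b in coupling.lin_terms.items():
            j = rids.index(rid)
            row[j] += b
            row[n + j] -= b
        rows.append(row)
        ubs.append(coupling.ub)
    A_ub = np.array(rows) if rows else None
    b_ub = np.array(ubs) if ubs else None
    return S, rids, bounds, A_eq, b_eq, A_ub, b_ub


def optimize(
    model: MetabolicModel,
    secondary: str = "l1",
    tol: float = 1e-9,
    tol_fix: float = 1e-6,
    objective_id: str | None = None,
    maximize: bool = True,
) -> FluxSolution:
    """Two-stage FBA.

    Stage 1 maximizes (or minimizes) the objective reaction flux; stage 2
    re-solves at the fixed optimum minimizing total flux. ``secondary`` is
    "none", "l1" (default) or "l2". Infeasible/unbounded problems are
    reported in ``status``, never as silent zeros.
    """
    if secondary not in ("none", "l1", "l2"):
        raise ValueError(f"unknown secondary objective {secondary!r}")
    obj_id = objective_id or model.objective_id
    if obj_id is None or obj_id not in model.reactions:
        raise ValueError(f"objective reaction {obj_id!r} not in model")
    S, rids, bounds, A_eq, b_eq, A_ub, b_ub = _assemble(model)
    n = len(rids)
    j = rids.index(obj_id)
    c = np.zeros(2 * n)
    sign = -1.0 if maximize else 1.0
    c[j], c[n + j] = sign, -sign

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": tol,
                           "dual_feasibility_tolerance": tol})
    status = _LINPROG_STATUS.get(res.status, STATUS_INFEASIBLE)
    if status != STATUS_OPTIMAL:
        return FluxSolution(status=status)
    opt = res.x[j] - res.x[n + j]

    x = res.x
    if secondary == "l1":
        # fix the primary objective within tol_fix, minimize sum(p + q)
        fix_row = np.zeros(2 * n)
        if maximize:
            fix_row[j], fix_row[n + j] = -1.0, 1.0  # -v_obj <= -(opt - tol_fix)
            fix_rhs = -(opt - tol_fix)
        else:
            fix_row[j], fix_row[n + j] = 1.0, -1.0
            fix_rhs = opt + tol_fix
        A2 = fix_row[None, :] if A_ub is None else np.vstack([A_ub, fix_row])
        b2 = np.array([fix_rhs]) if b_ub is None else np.append(b_ub, fix_rhs)
        # bookkeeping (pseudo) fluxes such as ledger drains are excluded
        # from the total-flux objective — their magnitude is not flux.
        w = np.array([0.0 if model.reactions[r].kind == "pseudo" else 1.0
                      for r in rids])
        res2 = linprog(np.concatenate([w, w]), A_ub=A2, b_ub=b2, A_eq=A_eq,
                       b_eq=b_eq, bounds=bounds, method="highs")
        if res2.status == 0:
            x = res2.x
    elif secondary == "l2":
        x = _l2_stage(model, rids, bounds, A_eq, A_ub, b_ub, j, n, opt,
                      maximize, tol_fix, x)

    v = x[:n] - x[n:]
    fluxes = {rid: float(v[k]) for k, rid in enumerate(rids)}
    # the reported optimum is the stage-1 value; the stage-2 flux vector
    # realises it within tol_fix by construction
    return FluxSolution(STATUS_OPTIMAL, float(opt), fluxes)


def _l2_stage(model, rids, bounds, A_eq, A_ub, b_ub, j, n, opt, maximize,
              tol_fix, x0):
    """Minimize Σvᵢ² at the fixed primary optimum (small dense QP)."""
    from scipy.optimize import minimize

    def fun(x):
        v = x[:n] - x[n:]
        return float(v @ v)

    def jac(x):
        v = x[:n] - x[n:]
        return np.concatenate([2 * v, -2 * v])

    cons = [{"type": "eq", "fun": lambda x: A_eq @ x}]
    s = 1.0 if maximize else -1.0
    cons.append({"type": "ineq",
                 "fun": lambda x: s * ((x[j] - x[n + j]) - opt) + tol_fix})
    if A_ub is not None:
        cons.append({"type": "ineq", "fun": lambda x: b_ub - A_ub @ x})
    res = minimize(fun, x0, jac=jac, bounds=bounds, constraints=cons,
                   method="SLSQP", options={"maxiter": 300, "ftol": 1e-12})
    return res.x if res.success else x0


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """max |S·v| over metabolites — should be ~0 for any optimal solution."""
    S, _, rids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in rids])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0


def fba_oracle_small(
    model: MetabolicModel, objective_id: str | None = None, max_reactions: int = 12
) -> FluxSolution:
    """Brute-force vertex enumeration of the flux polytope (test oracle).

    Enumerates all basic feasible solutions of {Sv = 0, l ≤ v ≤ u} by
    fixing every choice of (n − rank S) fluxes at a bound and solving for
    the rest, then returns the best objective value found. Exponential —
    guarded to ≤ ``max_reactions`` reactions, finite bounds only.
    """
    rids = model.reaction_ids()
    n = len(rids)
    if n > max_reactions:
        raise ValueError(f"oracle limited to {max_reactions} reactions, got {n}")
    obj_id = objective_id or model.objective_id
    S, _, _ = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle requires finite bounds")
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    jobj = rids.index(obj_id)
    best_v, best_obj = None, -np.inf
    tol = 1e-7

    for fixed_idx in itertools.combinations(range(n), n_fix):
        free_idx = [k for k in range(n) if k not in fixed_idx]
        A_free = S[:, free_idx]
        for choice in itertools.product(*[(lb[k], ub[k]) for k in fixed_idx]):
            v = np.empty(n)
            v[list(fixed_idx)] = choice
            rhs = -S[:, list(fixed_idx)] @ np.array(choice) if n_fix else np.zeros(S.shape[0])
            if free_idx:
                sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                v[free_idx] = sol
            if np.max(np.abs(S @ v)) > tol if S.size else False:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            bad = False
            fluxes = dict(zip(rids, v))
            for coupling in model.couplings:
                if coupling.residual(fluxes) > tol:
                    bad = True
                    break
            if bad:
                continue
            if v[jobj] > best_obj:
                best_obj, best_v = v[jobj], v.copy()
    if best_v is None:
        return FluxSolution(STATUS_INFEASIBLE)
    return FluxSolution(STATUS_OPTIMAL, float(best_obj),
                        {r: float(x) for r, x in zip(rids, best_v)})


def simulate_growth(
    model: MetabolicModel,
    medium=None,
    secondary: str = "l1",
    eha_fraction: float | None = 0.10,
    verbose: bool = False,
) -> FluxSolution:
    """Convenience wrapper: set medium, apply the default Eha/Ehb cap,
    optimize biomass with L1 flux minimization and report key fluxes."""
    from . import builder
    from .network import set_medium as _set_medium

    work = model
    if medium is not None:
        if isinstance(medium, str):
            medium = builder.medium_preset(medium)
        work = _set_medium(work, medium)
    if eha_fraction is not None and builder.EHA_ID in work.reactions:
        work = builder.apply_eha_coupling(work, eha_fraction)
    sol = optimize(work, secondary=secondary)
    if verbose:
        print(format_summary(sol))
    return sol


_SUMMARY_RXNS = [
    ("growth rate (1/h)", "biomass[c0]"),
    ("CH4 exchange", "EX_ch4[e0]"),
    ("H2 exchange", "EX_h2[e0]"),
    ("CO2 exchange", "EX_co2[e0]"),
    ("formate exchange", "EX_formate[e0]"),
    ("acetate exchange", "EX_acetate[e0]"),
    ("ATP synthase flux", "Atps[c0]"),
]


def format_summary(solution: FluxSolution) -> str:
    lines = [f"status: {solution.status}"]
    if solution.ok:
        for label, rid in _SUMMARY_RXNS:
            if rid in solution.fluxes:
                lines.append(f"{label:22s} {solution.fluxes[rid]: .6f}")
        if solution.total_free_energy is not None:
            lines.append(f"total free energy (kJ/gDCW/h) {solution.total_free_energy: .4f}")
    return "\n".join(lines)
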