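"""Constraint-based screening of overexpression / knockout targets.

The screening core couples three standard constraint-based operations:

* **FBA** -- maximize a biomass objective ``c'v`` over the steady-state flux
  polytope ``{v : S v = 0, lb <= v <= ub}`` (linear program, HiGHS).  Among
  alternate optima the reported flux vector additionally minimizes ``||v||_2``
  so that downstream quadratic programs have a deterministic reference.
* **MOMA** -- after a genetic perturbation, predict the mutant flux state as
  the Euclidean projection of the wild-type optimum onto the mutant polytope:
  ``min ||v - v_wt||^2`` subject to the mutant constraints (convex QP).
* **f_PH scoring** -- each perturbation is summarized by a weighted,
  dimensionless combination of its growth-rate ratio mu_mut/mu_wt and its
  product secretion ratio q_mut/q_wt; a no-op perturbation scores exactly 1
  and promising targets score above 1.

Fluxes are in mmol/(gDCW.h); the biomass flux is in 1/h.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import (ConfigurationError, NamedEntityError,
                         NormalizationError, ParameterError, SchemaError,
                         ValidationError)

_BIG = 1000.0


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    id: str
    name: str
    stoichiometry: dict[str, float]  # metabolite -> coefficient (<0 consumed)
    lower_bound: float = 0.0
    upper_bound: float = _BIG
    reversible: bool = False


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, bounded reactions, an objective."""

    metabolites: dict[str, str]            # id -> human-readable name
    reactions: dict[str, Reaction]
    objective_id: str
    rapamycin_exchange_id: str | None = None

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise SchemaError(
                        f"reaction '{rxn.id}' references undeclared metabolite '{met}'")
            if rxn.lower_bound > rxn.upper_bound:
                raise SchemaError(
                    f"reaction '{rxn.id}' has lower_bound > upper_bound "
                    f"({rxn.lower_bound} > {rxn.upper_bound})")
            if not rxn.reversible and rxn.lower_bound < 0:
                raise SchemaError(
                    f"irreversible reaction '{rxn.id}' has negative lower bound")
        if self.objective_id not in self.reactions:
            raise SchemaError(f"objective reaction '{self.objective_id}' not in model")
        if (self.rapamycin_exchange_id is not None
                and self.rapamycin_exchange_id not in self.reactions):
            raise SchemaError(
                f"rapamycin exchange '{self.rapamycin_exchange_id}' not in model")

    # -- matrix view --------------------------------------------------------

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Return (S, metabolite ids, reaction ids); S is metabolites x reactions."""
        mets = list(self.metabolites)
        rxns = self.reaction_ids()
        met_idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for met, coef in self.reactions[rid].stoichiometry.items():
                S[met_idx[met], j] = coef
        return S, mets, rxns

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()], float)
        ub = np.array([r.upper_bound for r in self.reactions.values()], float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=dict(self.metabolites),
            reactions={rid: replace(r, stoichiometry=dict(r.stoichiometry))
                       for rid, r in self.reactions.items()},
            objective_id=self.objective_id,
            rapamycin_exchange_id=self.rapamycin_exchange_id,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (self.metabolites == other.metabolites
                and self.objective_id == other.objective_id
                and self.rapamycin_exchange_id == other.rapamycin_exchange_id
                and {k: (r.name, r.stoichiometry, r.lower_bound, r.upper_bound,
                         r.reversible) for k, r in self.reactions.items()}
                == {k: (r.name, r.stoichiometry, r.lower_bound, r.upper_bound,
                        r.reversible) for k, r in other.reactions.items()})


@dataclass
class FluxDistribution:
    """A steady-state flux vector with its summary rates."""

    fluxes: pd.Series                # reaction id -> flux
    objective_value: float           # growth rate mu, 1/h
    rapamycin_rate: float            # q_rap, mmol/(gDCW.h)
    status: str                      # "optimal" | "infeasible"

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])


@dataclass
class TargetScore:
    reaction_id: str
    strategy: str                    # "overexpression" | "knockout"
    f_ph: float
    mu_ratio: float
    q_ratio: float
    weight: float
    status: str = "optimal"


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, path) -> None:
    model.validate()
    doc = {
        "metabolites": [{"id": mid, "name": name}
                        for mid, name in model.metabolites.items()],
        "reactions": [
            {"id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "reversible": r.reversible}
            for r in model.reactions.values()
        ],
        "objective": model.objective_id,
        "rapamycin_exchange": model.rapamycin_exchange_id,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_model(path) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    try:
        mets = {m["id"]: m.get("name", m["id"]) for m in doc["metabolites"]}
        rxns = {}
        for r in doc["reactions"]:
            rxns[r["id"]] = Reaction(
                id=r["id"], name=r.get("name", r["id"]),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                reversible=bool(r.get("reversible", False)),
            )
        model = MetabolicModel(metabolites=mets, reactions=rxns,
                               objective_id=doc["objective"],
                               rapamycin_exchange_id=doc.get("rapamycin_exchange"))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"missing or malformed field: {exc}") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# experimental constraints (measured uptake / secretion rates)
# ---------------------------------------------------------------------------

#: Measured specific rates used to constrain the model, mmol/(gDCW.h).
GLUCOSE_UPTAKE_MAX = 1.08
AMMONIUM_UPTAKE_MAX = 0.132
PHOSPHATE_UPTAKE_MAX = 0.0074
#: Measured specific rapamycin production rate, 0.021 umol/(gDCW.h) -> mmol.
RAPAMYCIN_RATE_MIN = 0.021e-3


def apply_experimental_constraints(
    model: MetabolicModel,
    glucose_id: str = "EX_glc",
    ammonium_id: str = "EX_nh3",
    phosphate_id: str = "EX_pi",
) -> MetabolicModel:
    """Return a copy with measured fermentation rates imposed as flux bounds.

    Uptake exchanges are written in the uptake direction (flux >= 0 brings the
    nutrient in), so the measured specific uptake rates cap their upper bounds;
    the measured rapamycin secretion rate becomes the lower bound of the
    rapamycin exchange.  Calling this twice is idempotent.
    """
    m = model.copy()
    for rid, cap in ((glucose_id, GLUCOSE_UPTAKE_MAX),
                     (ammonium_id, AMMONIUM_UPTAKE_MAX),
                     (phosphate_id, PHOSPHATE_UPTAKE_MAX)):
        if rid not in m.reactions:
            raise ConfigurationError(f"model lacks exchange reaction '{rid}'")
        m.reactions[rid].upper_bound = cap
    if m.rapamycin_exchange_id is None or m.rapamycin_exchange_id not in m.reactions:
        raise ConfigurationError("model lacks a rapamycin exchange reaction")
    m.reactions[m.rapamycin_exchange_id].lower_bound = RAPAMYCIN_RATE_MIN
    m.validate()
    return m


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _solve_qp(S, lb, ub, v_ref, A_eq_extra=None, b_eq_extra=None) -> np.ndarray | None:
    """Minimize ||v - v_ref||^2 over {S v = 0, extra equalities, box bounds}.

    The (redundant) equality rows are eliminated through an SVD nullspace
    basis, turning the problem into a low-dimensional Euclidean projection
    ``min ||z - z_bar||^2  s.t.  lo <= N z <= hi`` with orthonormal ``N``,
    which is solved exactly by a primal active-set method (KKT solves with
    multiplier-sign add/drop steps) started from a feasible LP point.  The
    returned vector satisfies ``S v = 0`` to the nullspace accuracy (~1e-12).
    """
    n = S.shape[1]
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    if A_eq_extra is not None:
        rows.append(np.atleast_2d(A_eq_extra))
        rhs.append(np.atleast_1d(b_eq_extra))
    A = np.vstack(rows)
    b = np.concatenate(rhs)

    res = linprog(np.zeros(n), A_eq=A, b_eq=b, bounds=list(zip(lb, ub)),
                  method="highs")
    if res.status != 0:
        return None
    v_feas = res.x

    # particular solution and orthonormal nullspace basis of the equalities
    U, sv, Vt = np.linalg.svd(A, full_matrices=True)
    tol_rank = max(A.shape) * (sv[0] if sv.size else 0.0) * np.finfo(float).eps
    rank = int(np.sum(sv > tol_rank))
    v0 = Vt[:rank].T @ ((U[:, :rank].T @ b) / sv[:rank])
    N = Vt[rank:].T                      # n x k, orthonormal columns
    k = N.shape[1]
    if k == 0:
        return v0 if (np.all(v0 >= lb - 1e-9)
                      and np.all(v0 <= ub + 1e-9)) else None

    lo, hi = lb - v0, ub - v0
    z_bar = N.T @ (v_ref - v0)
    z0 = N.T @ (v_feas - v0)
    z = _active_set_projection(N, lo, hi, z_bar, z0)
    return np.clip(v0 + N @ z, lb, ub)


def _active_set_projection(N, lo, hi, z_bar, z0, max_iter=500):
    """Exact projection of z_bar onto {z : lo <= N z <= hi} (z0 feasible).

    Classic primal active-set iteration: solve the equality-constrained
    projection on the working set, take the longest feasible step toward it
    (adding the blocking row), and once feasible drop any working constraint
    whose KKT multiplier has the wrong sign.
    """
    z = z0.copy()
    w = N @ z
    working: list[tuple[int, int]] = []       # (row, +1 upper / -1 lower)
    for i in range(len(lo)):
        if w[i] >= hi[i] - 1e-9:
            working.append((i, +1))
        elif w[i] <= lo[i] + 1e-9:
            working.append((i, -1))

    best = z.copy()
    best_obj = float((z - z_bar) @ (z - z_bar))
    for _ in range(max_iter):
        if working:
            idx = [i for i, _ in working]
            C = N[idx]
            d = np.array([hi[i] if s > 0 else lo[i] for i, s in working])
            G = C @ C.T
            lam, *_ = np.linalg.lstsq(G, C @ z_bar - d, rcond=None)
            z_star = z_bar - C.T @ lam
        else:
            lam = np.zeros(0)
            z_star = z_bar.copy()
        w_star = N @ z_star
        viol = max(float(np.max(w_star - hi)), float(np.max(lo - w_star)))
        if viol <= 1e-9:
            obj = float((z_star - z_bar) @ (z_star - z_bar))
            if obj < best_obj:
                best, best_obj = z_star.copy(), obj
            # optimality: upper-bound multipliers >= 0, lower-bound <= 0
            worst_j, worst_val = -1, -1e-10
            for j, (i, s) in enumerate(working):
                signed = lam[j] if s > 0 else -lam[j]
                if signed < worst_val:
                    worst_j, worst_val = j, signed
            if worst_j < 0:
                return z_star
            working.pop(worst_j)
            z = z_star
            w = N @ z
            continue
        # line search from z toward z_star; add the blocking row
        dz = z_star - z
        wd = N @ dz
        alpha, block = 1.0, None
        in_working = set(working)
        for i in range(len(lo)):
            if wd[i] > 1e-13 and (i, +1) not in in_working:
                a = (hi[i] - w[i]) / wd[i]
                if a < alpha:
                    alpha, block = max(a, 0.0), (i, +1)
            elif wd[i] < -1e-13 and (i, -1) not in in_working:
                a = (lo[i] - w[i]) / wd[i]
                if a < alpha:
                    alpha, block = max(a, 0.0), (i, -1)
        z = z + alpha * dz
        w = N @ z
        if block is not None:
            working.append(block)
        else:  # numerically stuck; accept the best feasible point so far
            break
    return best


def _distribution(model: MetabolicModel, v: np.ndarray, rxns: list[str],
                  status: str = "optimal") -> FluxDistribution:
    fluxes = pd.Series(v, index=rxns)
    obj = float(fluxes[model.objective_id])
    q = (float(fluxes[model.rapamycin_exchange_id])
         if model.rapamycin_exchange_id else math.nan)
    return FluxDistribution(fluxes=fluxes, objective_value=obj,
                            rapamycin_rate=q, status=status)


def _infeasible(model: MetabolicModel, rxns: list[str]) -> FluxDistribution:
    return FluxDistribution(
        fluxes=pd.Series(np.full(len(rxns), np.nan), index=rxns),
        objective_value=math.nan, rapamycin_rate=math.nan, status="infeasible")


def fba(model: MetabolicModel, objective_id: str | None = None) -> FluxDistribution:
    """Maximize the objective flux; tie-break alternate optima by min ||v||_2."""
    model.validate()
    obj_id = objective_id or model.objective_id
    if obj_id not in model.reactions:
        raise NamedEntityError(f"unknown objective reaction '{obj_id}'")
    S, _, rxns = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxns))
    c[rxns.index(obj_id)] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return _infeasible(model, rxns)
    opt = -res.fun
    # deterministic representative: minimum-norm flux at the optimal face
    row = np.zeros(len(rxns))
    row[rxns.index(obj_id)] = 1.0
    v = _solve_qp(S, lb, ub, np.zeros(len(rxns)),
                  A_eq_extra=row, b_eq_extra=np.array([opt]))
    if v is None:  # numerically infeasible face; fall back to the LP vertex
        v = res.x
    out = _distribution(model, v, rxns)
    out.objective_value = float(v[rxns.index(obj_id)])
    return out


def moma(model_mutant: MetabolicModel, v_wt: FluxDistribution) -> FluxDistribution:
    """Project the wild-type flux state onto the mutant flux polytope."""
    model_mutant.validate()
    S, _, rxns = model_mutant.stoichiometric_matrix()
    lb, ub = model_mutant.bounds_arrays()
    ref = v_wt.fluxes.reindex(rxns).to_numpy(float)
    if np.any(np.isnan(ref)):
        raise ValidationError("wild-type flux distribution does not cover the model")
    v = _solve_qp(S, lb, ub, ref)
    if v is None:
        return _infeasible(model_mutant, rxns)
    return _distribution(model_mutant, v, rxns)


# ---------------------------------------------------------------------------
# in-silico perturbations
# ---------------------------------------------------------------------------

def simulate_knockout(model: MetabolicModel, reaction_id: str,
                      v_wt: FluxDistribution) -> FluxDistribution:
    """Force the reaction's flux to zero, then predict the mutant with MOMA."""
    if reaction_id not in model.reactions:
        raise NamedEntityError(f"unknown reaction '{reaction_id}'")
    if reaction_id == model.objective_id:
        warnings.warn("knocking out the objective reaction itself")
    m = model.copy()
    m.reactions[reaction_id].lower_bound = 0.0
    m.reactions[reaction_id].upper_bound = 0.0
    return moma(m, v_wt)


OVEREXPRESSION_EPSILON = 1e-3  # mmol/(gDCW.h): floor for wild-type-silent reactions


def simulate_overexpression(model: MetabolicModel, reaction_id: str,
                            v_wt: FluxDistribution,
                            factor: float = 2.0) -> FluxDistribution:
    """Force at least ``factor x |v_wt|`` flux through the reaction (MOMA mutant).

    The bound is imposed in the wild-type flux direction; a reaction silent in
    the wild type is forced to ``factor x epsilon`` in its forward direction.
    """
    if reaction_id not in model.reactions:
        raise NamedEntityError(f"unknown reaction '{reaction_id}'")
    if not factor > 1.0:
        raise ParameterError("overexpression factor must exceed 1")
    m = model.copy()
    rxn = m.reactions[reaction_id]
    v0 = float(v_wt.fluxes[reaction_id])
    if v0 >= 0:
        target = factor * (v0 if v0 > 0 else OVEREXPRESSION_EPSILON)
        if target > rxn.upper_bound:
            warnings.warn(f"overexpression bound for '{reaction_id}' clipped "
                          f"to its upper bound {rxn.upper_bound}")
            target = rxn.upper_bound
        rxn.lower_bound = target
    else:
        target = -factor * abs(v0)
        if target < rxn.lower_bound:
            warnings.warn(f"overexpression bound for '{reaction_id}' clipped "
                          f"to its lower bound {rxn.lower_bound}")
            target = rxn.lower_bound
        rxn.upper_bound = target
    return moma(m, v_wt)


def f_ph(mut: FluxDistribution, wt: FluxDistribution, w: float = 0.5,
         variant: str = "arithmetic") -> float:
    """Weighted dimensionless combination of growth and production ratios.

    ``arithmetic``: w * mu_ratio + (1 - w) * q_ratio;
    ``geometric``:  mu_ratio^w * q_ratio^(1 - w).
    The wild-type itself scores exactly 1 under either variant.
    """
    if not (wt.objective_value > 0 and wt.rapamycin_rate > 0):
        raise NormalizationError("wild-type growth and production rates must be > 0")
    if not 0.0 <= w <= 1.0:
        raise ParameterError("weight w must lie in [0, 1]")
    mu_ratio = mut.objective_value / wt.objective_value
    q_ratio = mut.rapamycin_rate / wt.rapamycin_rate
    if variant == "arithmetic":
        return w * mu_ratio + (1.0 - w) * q_ratio
    if variant == "geometric":
        return float(max(mu_ratio, 0.0) ** w * max(q_ratio, 0.0) ** (1.0 - w))
    raise ParameterError(f"unknown f_PH variant '{variant}'")


def screen_targets(model: MetabolicModel,
                   candidates: list[tuple[str, str]],
                   w: float = 0.5,
                   factor: float = 2.0,
                   top_k: int = 10,
                   variant: str = "arithmetic") -> list[TargetScore]:
    """Rank (reaction, strategy) perturbations of a constrained model by f_PH.

    ``candidates`` is a list of ``(reaction_id, strategy)`` pairs with strategy
    in {"overexpression", "knockout"}.  The wild-type reference is the FBA
    optimum of ``model`` (minimum-norm representative).  Infeasible mutants are
    kept in the report with f_PH = 0 and status "infeasible".
    """
    if not candidates:
        raise ParameterError("empty candidate set")
    wt = fba(model)
    if wt.status != "optimal" or not wt.objective_value > 0:
        raise ConfigurationError("wild-type model is not feasible with positive growth")
    scores: list[TargetScore] = []
    for rid, strategy in candidates:
        if strategy == "knockout":
            mut = simulate_knockout(model, rid, wt)
        elif strategy == "overexpression":
            mut = simulate_overexpression(model, rid, wt, factor=factor)
        else:
            raise ParameterError(f"unknown strategy '{strategy}'")
        if mut.status != "optimal":
            scores.append(TargetScore(rid, strategy, 0.0, math.nan, math.nan,
                                      w, status="infeasible"))
            continue
        scores.append(TargetScore(
            reaction_id=rid, strategy=strategy,
            f_ph=f_ph(mut, wt, w=w, variant=variant),
            mu_ratio=mut.objective_value / wt.objective_value,
            q_ratio=mut.rapamycin_rate / wt.rapamycin_rate,
            weight=w))
    scores.sort(key=lambda s: (-s.f_ph, s.reaction_id))
    return scores[:top_k]


def steady_state_residual(model: MetabolicModel, dist: FluxDistribution) -> float:
    """Max-norm of S v -- the mass-conservation residual of a flux vector."""
    S, _, rxns = model.stoichiometric_matrix()
    v = dist.fluxes.reindex(rxns).to_numpy(float)
    return float(np.max(np.abs(S @ v)))
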