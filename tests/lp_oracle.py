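"""Independent LP oracle for the FBA layer.

Builds the stoichiometric matrix directly from a cobra model's structure and
solves with ``scipy.optimize.linprog`` (HiGHS) — a second, unrelated LP code
path against which the cobrapy/GLPK results are checked.  Only the model
*structure* (stoichiometry, bounds, gene lists) is read from cobra; all
optimization happens in scipy.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog


def structure(model):
    """Extract (S, reaction ids, bounds) from a cobra model."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_index), len(rxn_ids)))
    bounds = []
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    return S, rxn_ids, bounds


def maximize(model, objective_id: str, overrides: dict | None = None) -> float:
    """Maximize flux through one reaction subject to Sv=0 and bounds.

    ``overrides`` maps reaction id -> (lb, ub) replacing the model bounds
    for that solve only.  Returns NaN when infeasible.
    """
    S, rxn_ids, bounds = structure(model)
    bounds = list(bounds)
    if overrides:
        for rid, b in overrides.items():
            bounds[rxn_ids.index(rid)] = b
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if not res.success:
        return math.nan
    return -res.fun


def biomass_id(model) -> str:
    candidates = [r.id for r in model.reactions if r.objective_coefficient]
    assert len(candidates) == 1
    return candidates[0]


def max_production(model, demand_id: str, growth_fraction: float,
                   fix_growth: bool = False,
                   extra_overrides: dict | None = None) -> tuple[float, float]:
    """Two-step recipe re-implemented on the scipy path.

    Returns (max growth, production at the growth constraint).
    """
    overrides = dict(extra_overrides or {})
    mu = maximize(model, biomass_id(model), overrides)
    if math.isnan(mu):
        return mu, math.nan
    target = growth_fraction * mu
    ub = target if fix_growth else 1000.0
    overrides[biomass_id(model)] = (target, ub)
    return mu, maximize(model, demand_id, overrides)


def knockout_scan(model, demand_id: str, pathway_prefix: str | None = None,
                  growth_floor: float = 0.5, ko_growth_fraction: float = 0.999,
                  min_gain: float = 0.001) -> list[tuple[str, float, float, float]]:
    """Brute-force scan on the scipy path; mirrors the published recipe.

    Returns (reaction id, mutant growth, mutant production, relative gain)
    tuples sorted by decreasing gain then id.
    """
    bid = biomass_id(model)
    wt_mu = maximize(model, bid)
    _, wt_ref = max_production(model, demand_id, ko_growth_fraction,
                               fix_growth=True)
    out = []
    for rxn in model.reactions:
        if not rxn.genes or rxn.boundary or rxn.id in (bid, demand_id):
            continue
        if pathway_prefix and rxn.id.startswith(pathway_prefix):
            continue
        ko = {rxn.id: (0.0, 0.0)}
        mu_mut = maximize(model, bid, ko)
        if math.isnan(mu_mut) or mu_mut < growth_floor * wt_mu:
            continue
        _, production = max_production(model, demand_id, ko_growth_fraction,
                                       fix_growth=True, extra_overrides=ko)
        if math.isnan(production):
            continue
        gain = production / wt_ref - 1.0 if wt_ref > 0 else (
            math.inf if production > 0 else 0.0)
        if gain > min_gain:
            out.append((rxn.id, mu_mut, production, gain))
    out.sort(key=lambda t: (-t[3], t[0]))
    return out
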