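"""Constraint-based analysis: medium setup, growth-coupled production and
brute-force single-reaction knockout scanning.

All optimizations are flux balance analysis (FBA) linear programs solved
through cobrapy.  Only objective values are contracted (flux vectors are
solver-dependent); repeated solves agree to tight relative tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import cobra

#: paper-recipe defaults
GLUCOSE_UPTAKE = 0.8          # mmol gDW^-1 h^-1
GROWTH_FRACTION = 0.9         # production assessed at >=90% of max growth
KO_GROWTH_FRACTION = 0.999    # mutant production at 99.9% of its max growth
GROWTH_FLOOR = 0.5            # mutants below 50% of wild-type growth skipped
MIN_GAIN = 0.001              # report knockouts with >0.1% production gain
UNBOUNDED = 1000.0


class MediumError(KeyError):
    """A named exchange reaction does not exist in the model."""


class InfeasibleModelError(RuntimeError):
    """The FBA problem has no feasible solution."""


@dataclass
class MediumSpec:
    """Exchange-bound configuration (uptake = negative exchange flux)."""

    uptake_limits: dict[str, float] = field(default_factory=dict)
    unconstrained: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for ex, limit in self.uptake_limits.items():
            if limit < 0:
                raise ValueError(f"uptake limit for {ex} must be non-negative")


@dataclass
class ProductionResult:
    product_id: str
    wt_max_growth: float
    growth_fraction_used: float
    production_rate: float


@dataclass
class KnockoutCandidate:
    reaction_id: str
    mutant_max_growth: float
    mutant_production: float
    relative_increase: float


def minimal_glucose_medium(
    model: cobra.Model,
    glucose_exchange: str,
    glucose_uptake: float = GLUCOSE_UPTAKE,
    unconstrained: set[str] | None = None,
) -> MediumSpec:
    """Glucose/ammonium minimal medium: glucose capped, ions free, every
    other exchange closed for uptake."""
    if unconstrained is None:
        unconstrained = {
            ex.id
            for ex in model.exchanges
            if any(
                key in ex.id
                for key in ("nh4", "pi", "so4", "o2", "h2o", "_h_", "fe", "mg", "k_")
            )
            or ex.id.endswith(("_h_c", "_h_e"))
        }
    return MediumSpec(
        uptake_limits={glucose_exchange: glucose_uptake},
        unconstrained=unconstrained - {glucose_exchange},
    )


def set_medium(model: cobra.Model, medium: MediumSpec) -> cobra.Model:
    """Apply a medium in place: named uptakes capped, listed exchanges left
    unbounded, all other exchanges closed for uptake. Returns the model."""
    exchange_ids = {ex.id for ex in model.exchanges}
    for ex_id in list(medium.uptake_limits) + list(medium.unconstrained):
        if ex_id not in exchange_ids:
            raise MediumError(f"exchange {ex_id!r} not found in model")
    for ex in model.exchanges:
        if ex.id in medium.uptake_limits:
            ex.lower_bound = -medium.uptake_limits[ex.id]
        elif ex.id in medium.unconstrained:
            ex.lower_bound = -UNBOUNDED
        else:
            ex.lower_bound = 0.0
    return model


def _objective_value(model: cobra.Model) -> float:
    value = model.slim_optimize(error_value=math.nan)
    if math.isnan(value):
        raise InfeasibleModelError("FBA problem is infeasible")
    return value


def _biomass_reaction(model: cobra.Model) -> cobra.Reaction:
    candidates = [r for r in model.reactions if r.objective_coefficient]
    if len(candidates) != 1:
        raise ValueError(
            f"expected exactly one objective reaction, found {len(candidates)}"
        )
    return candidates[0]


def max_growth(model: cobra.Model) -> float:
    """Maximum growth rate under the current bounds."""
    with model:
        return _objective_value(model)


def max_production(
    model: cobra.Model,
    product_demand_id: str,
    growth_fraction: float = GROWTH_FRACTION,
    fix_growth: bool = False,
) -> ProductionResult:
    """Two-step FBA: maximize growth, then constrain growth to at least
    ``growth_fraction`` of that maximum (or fix it exactly when
    ``fix_growth``) and maximize flux through the product demand."""
    biomass = _biomass_reaction(model)
    demand = model.reactions.get_by_id(product_demand_id)
    with model:
        mu = _objective_value(model)
        target = growth_fraction * mu
        biomass.lower_bound = target
        if fix_growth:
            biomass.upper_bound = target
        model.objective = demand
        production = _objective_value(model)
    return ProductionResult(
        product_id=product_demand_id,
        wt_max_growth=mu,
        growth_fraction_used=growth_fraction,
        production_rate=max(production, 0.0),
    )


def knockout_scan(
    model: cobra.Model,
    product_demand_id: str,
    pathway_prefix: str | None = None,
    growth_floor: float = GROWTH_FLOOR,
    ko_growth_fraction: float = KO_GROWTH_FRACTION,
    min_gain: float = MIN_GAIN,
) -> list[KnockoutCandidate]:
    """Brute-force single-reaction knockout scan.

    Candidate reactions are gene-annotated, non-boundary and outside the
    inserted pathway.  Each is disabled in turn; mutants keeping at least
    ``growth_floor`` of wild-type growth are assessed for production with
    growth fixed at ``ko_growth_fraction`` of the mutant maximum, and
    reported when production exceeds the wild-type reference (same fixation
    on the unperturbed model) by more than ``min_gain``.
    """
    biomass = _biomass_reaction(model)
    wt_mu = max_growth(model)
    wt_ref = max_production(
        model, product_demand_id, ko_growth_fraction, fix_growth=True
    ).production_rate

    candidates: list[KnockoutCandidate] = []
    for rxn in model.reactions:
        if not rxn.genes:
            continue
        if rxn.boundary or rxn.id == biomass.id or rxn.id == product_demand_id:
            continue
        if pathway_prefix and rxn.id.startswith(pathway_prefix):
            continue
        with model:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            mu_mut = model.slim_optimize(error_value=math.nan)
            if math.isnan(mu_mut) or mu_mut < growth_floor * wt_mu:
                continue  # essential (or infeasible) under the 50% growth floor
            target = ko_growth_fraction * mu_mut
            biomass.lower_bound = target
            biomass.upper_bound = target
            model.objective = model.reactions.get_by_id(product_demand_id)
            production = model.slim_optimize(error_value=math.nan)
        if math.isnan(production):
            continue
        if wt_ref > 0:
            gain = production / wt_ref - 1.0
        else:
            gain = math.inf if production > 0 else 0.0
        if gain > min_gain:
            candidates.append(
                KnockoutCandidate(
                    reaction_id=rxn.id,
                    mutant_max_growth=mu_mut,
                    mutant_production=production,
                    relative_increase=gain,
                )
            )
    candidates.sort(key=lambda c: (-c.relative_increase, c.reaction_id))
    return candidates


def candidates_to_tsv(candidates: list[KnockoutCandidate]) -> str:
    lines = ["reaction_id\tmutant_growth\tmutant_production\trelative_gain"]
    for c in candidates:
        lines.append(
            f"{c.reaction_id}\t{c.mutant_max_growth:.6f}"
            f"\t{c.mutant_production:.6f}\t{c.relative_increase:.6f}"
        )
    return "\n".join(lines) + "\n"
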