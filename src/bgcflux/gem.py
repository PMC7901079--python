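"""Reference-model handling: load SBML, resolve metabolites, insert pathways.

The reference genome-scale model is used strictly as a library of metabolites
and reactions.  cobrapy provides the model container and SBML I/O; this
module adds id resolution against the library (exact match, then a curated
synonym table, then creation of a new species) and non-destructive pathway
insertion with a demand reaction on the final product.
"""

from __future__ import annotations

import cobra
import libsbml

from .metabolites import MetaboliteRef, SYNONYMS
from .pathway import PathwayReconstruction


class ModelValidationError(ValueError):
    """The SBML document is unusable as a reference model."""


def load_reference_model(path: str) -> cobra.Model:
    """Load an SBML Level-3 FBC model and validate the essentials.

    Requires FBC flux bounds and a non-empty objective; raises
    :class:`ModelValidationError` naming the deficiency otherwise.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(
            f"unreadable SBML: {err.getMessage().strip()} (line {err.getLine()})"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError("SBML document contains no model")
    if sbml_model.getLevel() >= 3 and sbml_model.getPlugin("fbc") is None:
        raise ModelValidationError("SBML Level 3 model lacks the FBC package (no flux bounds)")
    model = cobra.io.read_sbml_model(str(path))
    if not _objective_reactions(model):
        raise ModelValidationError("model defines no objective reaction")
    return model


def _objective_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    return [r for r in model.reactions if r.objective_coefficient]


def resolve_metabolite(
    ref: MetaboliteRef, model: cobra.Model
) -> tuple[cobra.Metabolite, bool]:
    """Resolve a canonical metabolite against the model library.

    Returns ``(metabolite, created)``: exact ``<id>_<compartment>`` match
    first, then the synonym table, else a newly created metabolite (default
    cytosolic compartment).
    """
    candidates = [ref.met_id] + SYNONYMS.get(ref.met_id, [])
    for base in candidates:
        full = f"{base}_{ref.compartment}"
        if full in model.metabolites:
            return model.metabolites.get_by_id(full), False
    met = cobra.Metabolite(
        f"{ref.met_id}_{ref.compartment}", name=ref.name, compartment=ref.compartment
    )
    return met, True


class PathwayCollisionError(ValueError):
    """A pathway reaction id already exists in the model."""


def insert_pathway(
    model: cobra.Model, rec: PathwayReconstruction
) -> tuple[cobra.Model, str]:
    """Return a copy of the model extended with the reconstruction.

    Adds every pathway reaction plus an irreversible demand on the final
    product (the production objective used downstream); the input model is
    left unmodified.  Returns ``(extended_model, demand_reaction_id)``.
    """
    if rec.final_product is None:
        raise ValueError("reconstruction has no final product")
    ext = model.copy()
    resolved: dict[str, cobra.Metabolite] = {}
    new_ids: list[str] = []
    for ref in rec.all_metabolites().values():
        met, created = resolve_metabolite(ref, ext)
        resolved[ref.met_id] = met
        if created:
            new_ids.append(met.id)

    reactions = []
    for spec in rec.reactions:
        if spec.rxn_id in ext.reactions:
            raise PathwayCollisionError(
                f"reaction id {spec.rxn_id} already present in the model"
            )
        rxn = cobra.Reaction(spec.rxn_id, name=spec.name)
        rxn.lower_bound, rxn.upper_bound = spec.bounds
        reactions.append((rxn, spec))
    demand_id = f"DM_{rec.final_product.met_id}"
    if demand_id in ext.reactions:
        raise PathwayCollisionError(f"demand reaction {demand_id} already present")

    for rxn, spec in reactions:
        ext.add_reactions([rxn])
        rxn.add_metabolites(
            {resolved[m.met_id]: coeff for m, coeff in spec.stoich.items()}
        )
        if spec.genes:
            rxn.gene_reaction_rule = " and ".join(spec.genes)
    demand = cobra.Reaction(demand_id, name=f"demand: {rec.final_product.name}")
    demand.lower_bound, demand.upper_bound = 0.0, 1000.0
    ext.add_reactions([demand])
    demand.add_metabolites({resolved[rec.final_product.met_id]: -1.0})
    return ext, demand_id


def validate_extended_model(model: cobra.Model) -> None:
    """Structural validation: metabolites exist and bounds are finite."""
    import math

    for rxn in model.reactions:
        if not rxn.metabolites:
            raise ModelValidationError(f"reaction {rxn.id} has no metabolites")
        if not (math.isfinite(rxn.lower_bound) and math.isfinite(rxn.upper_bound)):
            raise ModelValidationError(f"reaction {rxn.id} has non-finite bounds")
        for met in rxn.metabolites:
            if met.id not in model.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {met.id}"
                )
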