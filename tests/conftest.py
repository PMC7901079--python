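"""Shared fixtures: toy reference model, canonical pathway fixtures."""

from __future__ import annotations

import logging

import pytest

from bgcflux import fixtures as fx
from bgcflux.analysis import set_medium
from bgcflux.assembly import assemble_modules
from bgcflux.fixtures import DomainSpec, GeneSpec, SyntheticBGCSpec
from bgcflux.gem import insert_pathway
from bgcflux.ingest import parse_region
from bgcflux.pathway import build_pathway
from bgcflux.records import DomainKind as K

# cobra's boundary-compartment heuristic logs a warning for the deliberate
# single-compartment toy model; it is informational only
logging.getLogger("cobra.medium.boundary_types").setLevel(logging.ERROR)


def tripeptide_spec() -> SyntheticBGCSpec:
    """Three-module NRPS (gly-ala-ser, TE release) on one gene."""
    return SyntheticBGCSpec(
        cluster_id="nrpstoy",
        classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
             DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ser"),
             DomainSpec(K.PCP), DomainSpec(K.TE)],
        ])],
    )


def reconstruct_spec(spec: SyntheticBGCSpec):
    """spec -> (cluster, plan, reconstruction)."""
    cluster = parse_region(fx.write_synthetic_region(spec))
    plan = assemble_modules(cluster)
    return cluster, plan, build_pathway(plan, cluster)


@pytest.fixture
def toy_model():
    model = fx.build_toy_reference_model()
    set_medium(model, fx.toy_medium())
    return model


@pytest.fixture
def tripeptide_rec():
    _, _, rec = reconstruct_spec(tripeptide_spec())
    return rec


@pytest.fixture
def extended_toy(toy_model, tripeptide_rec):
    """Toy model with the tripeptide pathway inserted; (model, demand id)."""
    return insert_pathway(toy_model, tripeptide_rec)
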