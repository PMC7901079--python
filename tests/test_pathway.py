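"""Reaction-builder tests: per-domain golden stoichiometry, cofactor audit,
connectivity validation, rare monomers, fallbacks and serialization."""

from __future__ import annotations

import pytest

from bgcflux import fixtures as fx
from bgcflux.fixtures import DomainSpec, GeneSpec, SyntheticBGCSpec
from bgcflux.pathway import (
    cofactor_audit,
    pathway_from_json,
    pathway_to_json,
    reconstruct,
    validate_reconstruction,
)
from bgcflux.records import DomainKind as K
from conftest import reconstruct_spec, tripeptide_spec


def rec_for(spec):
    return reconstruct_spec(spec)[2]


def find(rec, provenance):
    matches = [r for r in rec.reactions if r.provenance == provenance]
    assert len(matches) == 1, f"expected one {provenance!r} reaction, got {len(matches)}"
    return matches[0]


def stoich(rxn):
    return {met.met_id: coeff for met, coeff in rxn.stoich.items()}


def nrps_spec(cid, extender_group, load_substrate="gly"):
    return SyntheticBGCSpec(
        cluster_id=cid, classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.A, substrate=load_substrate), DomainSpec(K.PCP)],
            extender_group,
        ])],
    )


def pks_spec(cid, extender_group, classes=("T1PKS",),
             load_group=None):
    load_group = load_group or [DomainSpec(K.AT, substrate="mal"),
                                DomainSpec(K.ACP)]
    return SyntheticBGCSpec(
        cluster_id=cid, classes=list(classes),
        genes=[GeneSpec("g1", modules=[load_group, extender_group])],
    )


# ---------------------------------------------------------------------------
# per-domain golden stoichiometries (one test per domain-calculus row)
# ---------------------------------------------------------------------------

def test_row_A_adenylation():
    rec = rec_for(nrps_spec("rowa", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    load = [r for r in rec.reactions if r.provenance == "A"][0]
    assert stoich(load) == {
        "atp": -1, "gly": -1, "rowa_carrier": -1,
        "rowa_chain_0": 1, "amp": 1, "ppi": 1,
    }


def test_row_AT_acyl_loading():
    rec = rec_for(pks_spec("rowat", [
        DomainSpec(K.KS), DomainSpec(K.AT, substrate="mmal"),
        DomainSpec(K.ACP), DomainSpec(K.TE)]))
    loads = [r for r in rec.reactions if r.provenance == "AT"]
    assert stoich(loads[0]) == {
        "malcoa": -1, "rowat_carrier": -1, "rowat_chain_0": 1, "coa": 1,
    }
    assert stoich(loads[1]) == {
        "mmcoa__R": -1, "rowat_carrier": -1, "rowat_acyl_m1": 1, "coa": 1,
    }


def test_row_C_condensation():
    rec = rec_for(nrps_spec("rowc", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    assert stoich(find(rec, "C")) == {
        "rowc_aminoacyl_m1": -1, "rowc_chain_0": -1,
        "rowc_chain_1": 1, "h2o": 1, "rowc_carrier": 1,
    }


def test_row_Cy_heterocyclization():
    rec = rec_for(nrps_spec("rowcy", [
        DomainSpec(K.CY), DomainSpec(K.A, substrate="cys"),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    assert stoich(find(rec, "Cy")) == {
        "rowcy_aminoacyl_m1": -1, "rowcy_chain_0": -1,
        "rowcy_chain_1": 1, "h2o": 1, "rowcy_carrier": 1,
    }


def test_row_KS_decarboxylative_condensation():
    rec = rec_for(pks_spec("rowks", [
        DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
        DomainSpec(K.ACP), DomainSpec(K.TE)]))
    assert stoich(find(rec, "KS")) == {
        "rowks_acyl_m1": -1, "rowks_chain_0": -1,
        "rowks_chain_1": 1, "co2": 1, "rowks_carrier": 1,
    }


def test_row_CAL_starter():
    rec = rec_for(SyntheticBGCSpec(
        cluster_id="rowcal", classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.CAL, substrate="gly"), DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
             DomainSpec(K.PCP), DomainSpec(K.TE)],
        ])],
    ))
    assert stoich(find(rec, "CAL")) == {
        "gly": -1, "rowcal_carrier": -1, "rowcal_chain_0": 1, "h2o": 1,
    }


def test_row_GNAT_load():
    rec = rec_for(pks_spec("rowgnat", [
        DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
        DomainSpec(K.ACP), DomainSpec(K.TE)],
        load_group=[DomainSpec(K.GNAT), DomainSpec(K.ACP)]))
    assert stoich(find(rec, "GNAT")) == {
        "malcoa": -1, "rowgnat_carrier": -1,
        "rowgnat_chain_0": 1, "coa": 1, "co2": 1,
    }


def test_row_FkbH_load():
    rec = rec_for(pks_spec("rowfkbh", [
        DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
        DomainSpec(K.ACP), DomainSpec(K.TE)],
        load_group=[DomainSpec(K.FKBH), DomainSpec(K.ACP)]))
    assert stoich(find(rec, "FkbH")) == {
        "13dpg": -1, "rowfkbh_carrier": -1, "rowfkbh_chain_0": 1, "pi": 2,
    }


@pytest.mark.parametrize("kind,prov", [
    (K.CMT, "cMT"), (K.NMT, "nMT"), (K.OMT, "oMT"),
])
def test_row_methyltransferases(kind, prov):
    cid = f"row{prov.lower()}"
    rec = rec_for(nrps_spec(cid, [
        DomainSpec(K.C), DomainSpec(K.A, substrate="ala"), DomainSpec(kind),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    assert stoich(find(rec, prov)) == {
        f"{cid}_chain_1": -1, "amet": -1,
        f"{cid}_chain_1_v1": 1, "ahcys": 1,
    }


def reductive_rec(cid):
    return rec_for(pks_spec(cid, [
        DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
        DomainSpec(K.KR, activity="active"), DomainSpec(K.DH),
        DomainSpec(K.ER), DomainSpec(K.ACP), DomainSpec(K.TE)]))


def test_row_KR_ketoreduction():
    rec = reductive_rec("rowkr")
    assert stoich(find(rec, "KR")) == {
        "rowkr_chain_1": -1, "nadph": -1, "h": -1,
        "rowkr_chain_1_v1": 1, "nadp": 1,
    }


def test_row_DH_dehydration():
    rec = reductive_rec("rowdh")
    assert stoich(find(rec, "DH")) == {
        "rowdh_chain_1_v1": -1, "rowdh_chain_1_v2": 1, "h2o": 1,
    }


def test_row_ER_enoylreduction():
    rec = reductive_rec("rower")
    assert stoich(find(rec, "ER")) == {
        "rower_chain_1_v2": -1, "nadph": -1, "h": -1,
        "rower_chain_1_v3": 1, "nadp": 1,
    }


def test_row_E_and_ECH_no_stoichiometric_change():
    rec = rec_for(nrps_spec("rowe", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="ala"), DomainSpec(K.E),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    assert stoich(find(rec, "E")) == {
        "rowe_chain_1": -1, "rowe_chain_1_v1": 1,
    }
    rec2 = rec_for(pks_spec("rowech", [
        DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
        DomainSpec(K.ECH), DomainSpec(K.ACP), DomainSpec(K.TE)]))
    assert stoich(find(rec2, "ECH")) == {
        "rowech_chain_1": -1, "rowech_chain_1_v1": 1,
    }


def test_row_TE_hydrolytic_release():
    rec = rec_for(nrps_spec("rowte", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    assert stoich(find(rec, "TE")) == {
        "h2o": -1, "rowte_chain_1": -1,
        "rowte_product": 1, "rowte_carrier": 1,
    }


def test_row_TD_reductive_release():
    rec = rec_for(nrps_spec("rowtd", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
        DomainSpec(K.PCP), DomainSpec(K.TD)]))
    assert stoich(find(rec, "TD")) == {
        "nadph": -1, "h": -1, "rowtd_chain_1": -1,
        "rowtd_product": 1, "nadp": 1, "rowtd_carrier": 1,
    }


def test_row_carriers_are_species_not_reactions():
    """ACP/PCP contribute the shared carrier species; they never emit a
    reaction of their own, and the carrier is exactly balanced."""
    rec = rec_for(tripeptide_spec())
    assert not any(r.provenance in ("ACP", "PCP") for r in rec.reactions)
    net = sum(r.coefficient("nrpstoy_carrier") for r in rec.reactions)
    assert net == 0


# ---------------------------------------------------------------------------
# audit, validation, fallbacks
# ---------------------------------------------------------------------------

def test_cofactor_audit_fig_style():
    _, plan, rec = reconstruct_spec(fx.fig_style_bridging_spec())
    audit = cofactor_audit(rec)
    assert audit["n_KS"] == 3 and audit["co2_KS"] == 3
    assert audit["n_KR"] == 2 and audit["nadph_red"] == 2
    assert audit["n_A"] == 0 and audit["atp_A"] == 0
    assert audit["carrier_net"] == 0
    assert audit["co2_other"] == 1  # GNAT load releases CO2 outside the KS tally


def test_validation_catches_dangling_chain():
    rec = rec_for(tripeptide_spec())
    rec.reactions = [r for r in rec.reactions if r.provenance != "TE"]
    with pytest.raises(AssertionError):
        validate_reconstruction(rec)


def test_rare_monomer_subpathway_emitted():
    rec = rec_for(nrps_spec("rare1", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="hpg"),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    synth = [r for r in rec.reactions if r.provenance == "precursor:hpg"]
    assert len(synth) == 1
    assert stoich(synth[0])["hpg"] == 1 and stoich(synth[0])["tyr__L"] == -1


def test_generic_amino_acid_fallback():
    rec = rec_for(nrps_spec("gen1", [
        DomainSpec(K.C), DomainSpec(K.A, substrate="X"),
        DomainSpec(K.PCP), DomainSpec(K.TE)]))
    pseudo = [r for r in rec.reactions if r.provenance == "pseudo:generic_aa"]
    assert len(pseudo) == 20  # one per proteinogenic amino acid
    assert all(stoich(r)["generic_aa"] == 1 for r in pseudo)


def test_c_acylated_load_uses_generic_fatty_acid():
    rec = rec_for(SyntheticBGCSpec(
        cluster_id="acyl1", classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ser"),
             DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
             DomainSpec(K.PCP), DomainSpec(K.TE)],
        ])],
    ))
    acyl = find(rec, "C-acyl")
    assert stoich(acyl)["generic_fa"] == -1
    assert stoich(acyl)["acyl1_chain_0"] == 1
    assert any(r.provenance == "pseudo:generic_fa" for r in rec.reactions)


def test_mxmal_gated_by_smcog():
    def spec(smcog):
        return SyntheticBGCSpec(
            cluster_id="mx1", classes=["T1PKS"],
            genes=[GeneSpec("g1", smcog_id=smcog, modules=[
                [DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP)],
                [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mxmal"),
                 DomainSpec(K.ACP), DomainSpec(K.TE)],
            ])],
        )

    gated = rec_for(spec(None))
    assert any("methoxymalonyl" in w for w in gated.warnings)
    assert not any(r.provenance == "precursor:mxmal" for r in gated.reactions)

    allowed = rec_for(spec("1256"))
    steps = [r for r in allowed.reactions if r.provenance == "precursor:mxmal"]
    assert len(steps) == 2
    ks = find(allowed, "KS")
    assert stoich(ks)["mxmal_acp"] == -1  # delivered carrier-bound, no AT load


def test_no_load_module_fallback():
    rec = rec_for(SyntheticBGCSpec(
        cluster_id="noload", classes=["T1PKS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
             DomainSpec(K.ACP), DomainSpec(K.TE)],
        ])],
    ))
    assert any("no load module" in w for w in rec.warnings)
    # single module: its monomer starts the chain, no condensation happens
    assert not any(r.provenance == "KS" for r in rec.reactions)
    assert rec.final_product is not None


def test_release_fallback_without_te_td():
    rec = rec_for(SyntheticBGCSpec(
        cluster_id="norel", classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
             DomainSpec(K.PCP)],
        ])],
    ))
    assert any(r.provenance == "release_fallback" for r in rec.reactions)
    assert any("implicit hydrolysis" in w for w in rec.warnings)


def test_smcog_tailoring_order_and_product():
    rec = rec_for(SyntheticBGCSpec(
        cluster_id="tail1", classes=["NRPS"],
        genes=[
            GeneSpec("g1", modules=[
                [DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
                [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
                 DomainSpec(K.PCP), DomainSpec(K.TE)],
            ]),
            GeneSpec("g2", smcog_id="1062", modules=[]),
            GeneSpec("g3", smcog_id="1002", modules=[]),
        ],
    ))
    tailor = [r for r in rec.reactions if r.provenance.startswith("smCOG")]
    assert [r.provenance for r in tailor] == ["smCOG:1062", "smCOG:1002"]
    assert stoich(tailor[0])["ndphex"] == -1            # glycosylation
    assert stoich(tailor[1])["atp"] == -1               # ATP-dependent ligation
    assert rec.final_product.met_id == "tail1_product_t2"


def test_pathway_json_round_trip_byte_identical():
    rec = rec_for(tripeptide_spec())
    text = pathway_to_json(rec)
    again = pathway_to_json(pathway_from_json(text))
    assert text == again


def test_reconstruct_convenience_matches_pipeline():
    text = fx.write_synthetic_region(tripeptide_spec())
    rec = reconstruct(text)
    assert pathway_to_json(rec) == pathway_to_json(rec_for(tripeptide_spec()))
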