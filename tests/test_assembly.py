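"""Module-assembly tests: grouping, bridging, activity heuristics, truncation."""

from __future__ import annotations

import copy

import pytest

from bgcflux import fixtures as fx
from bgcflux.assembly import (
    LOAD_C_ACYLATED_NRPS,
    LOAD_CAL,
    LOAD_FKBH,
    LOAD_GNAT,
    LOAD_NONE,
    LOAD_STANDARD_NRPS,
    LOAD_STANDARD_PKS,
    NoFunctionalModulesError,
    assemble_modules,
    decisions_to_tsv,
    detect_dhd,
    resolve_plan,
    resolve_reduction_activity,
)
from bgcflux.fixtures import DomainSpec, GeneSpec, SyntheticBGCSpec
from bgcflux.ingest import parse_region
from bgcflux.records import DomainKind as K


def plan_for(spec: SyntheticBGCSpec):
    return assemble_modules(parse_region(fx.write_synthetic_region(spec)))


def pks_spec(cluster_id, module_groups, classes=("T1PKS",)):
    return SyntheticBGCSpec(
        cluster_id=cluster_id, classes=list(classes),
        genes=[GeneSpec("g1", modules=module_groups)],
    )


def test_fig_style_bridging_plan():
    plan = plan_for(fx.fig_style_bridging_spec())
    assert plan.load_descriptor == LOAD_GNAT
    bridging = [m for m in plan.modules if m.is_bridging]
    assert len(bridging) == 1
    assert bridging[0].spans_gene_boundary and bridging[0].is_extending
    terminal = plan.modules[plan.terminal_index]
    assert terminal.is_terminating and not terminal.is_extending  # oMT rule
    assert plan.chain_length == 3


def test_dhd_module_inactive():
    spec = SyntheticBGCSpec(
        cluster_id="dhd1", classes=["transAT-PKS"],
        genes=[
            GeneSpec("gA", modules=[
                [DomainSpec(K.GNAT), DomainSpec(K.ACP)],
                [DomainSpec(K.KS)],
            ]),
            GeneSpec("gB", modules=[
                [DomainSpec(K.DH), DomainSpec(K.ACP)],
                [DomainSpec(K.KS), DomainSpec(K.ACP), DomainSpec(K.TE)],
            ]),
        ],
    )
    plan = plan_for(spec)
    dhd = [m for m in plan.modules if m.is_bridging]
    assert len(dhd) == 1
    assert detect_dhd(dhd[0], is_transat=True)
    assert not dhd[0].is_extending
    # the same arrangement is not a DHD call outside trans-AT clusters
    assert not detect_dhd(dhd[0], is_transat=False)


def test_omt_deactivates_pks_module_only():
    plan = plan_for(pks_spec("omt1", [
        [DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP)],
        [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
         DomainSpec(K.OMT), DomainSpec(K.ACP)],
        [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
         DomainSpec(K.ACP), DomainSpec(K.TE)],
    ]))
    assert [m.is_extending for m in plan.modules] == [False, False, True]
    # oMT in an NRPS module does not deactivate it
    nrps = SyntheticBGCSpec(
        cluster_id="omt2", classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
             DomainSpec(K.OMT), DomainSpec(K.PCP), DomainSpec(K.TE)],
        ])],
    )
    plan2 = plan_for(nrps)
    assert plan2.modules[1].is_extending


def test_kr_activity_cascade():
    def module_with(kr_activity):
        plan = plan_for(pks_spec("kr1", [
            [DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP)],
            [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
             DomainSpec(K.KR, activity=kr_activity), DomainSpec(K.DH),
             DomainSpec(K.ER), DomainSpec(K.ACP), DomainSpec(K.TE)],
        ]))
        return plan.modules[1]

    assert resolve_reduction_activity(module_with("inactive")) == set()
    assert resolve_reduction_activity(module_with("active")) == {K.KR, K.DH, K.ER}
    # unannotated KR defaults to active
    assert resolve_reduction_activity(module_with(None)) == {K.KR, K.DH, K.ER}


def test_dh_er_require_kr_presence():
    plan = plan_for(pks_spec("kr2", [
        [DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP)],
        [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
         DomainSpec(K.DH), DomainSpec(K.ER), DomainSpec(K.ACP),
         DomainSpec(K.TE)],
    ]))
    assert resolve_reduction_activity(plan.modules[1]) == set()


def test_inactive_ks_stops_extension():
    plan = plan_for(pks_spec("ks1", [
        [DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP)],
        [DomainSpec(K.KS, activity="inactive"),
         DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP),
         DomainSpec(K.TE)],
    ]))
    assert not plan.modules[1].is_extending


def test_midcluster_te_truncates():
    spec = SyntheticBGCSpec(
        cluster_id="te1", classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[
            [DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
             DomainSpec(K.PCP), DomainSpec(K.TE)],
            [DomainSpec(K.C), DomainSpec(K.A, substrate="ser"),
             DomainSpec(K.PCP), DomainSpec(K.TE)],
        ])],
    )
    plan = plan_for(spec)
    assert plan.terminal_index == 1
    assert not plan.modules[2].is_extending
    assert plan.chain_length == 1


@pytest.mark.parametrize("groups,classes,expected", [
    ([[DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
      [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
       DomainSpec(K.PCP), DomainSpec(K.TE)]], ["NRPS"], LOAD_STANDARD_NRPS),
    ([[DomainSpec(K.C), DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP)],
      [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
       DomainSpec(K.PCP), DomainSpec(K.TE)]], ["NRPS"], LOAD_C_ACYLATED_NRPS),
    ([[DomainSpec(K.AT, substrate="mal"), DomainSpec(K.ACP)],
      [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
       DomainSpec(K.ACP), DomainSpec(K.TE)]], ["T1PKS"], LOAD_STANDARD_PKS),
    ([[DomainSpec(K.GNAT), DomainSpec(K.ACP)],
      [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
       DomainSpec(K.ACP), DomainSpec(K.TE)]], ["T1PKS"], LOAD_GNAT),
    ([[DomainSpec(K.FKBH), DomainSpec(K.ACP)],
      [DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
       DomainSpec(K.ACP), DomainSpec(K.TE)]], ["T1PKS"], LOAD_FKBH),
    ([[DomainSpec(K.CAL, substrate="gly"), DomainSpec(K.PCP)],
      [DomainSpec(K.C), DomainSpec(K.A, substrate="ala"),
       DomainSpec(K.PCP), DomainSpec(K.TE)]], ["NRPS"], LOAD_CAL),
    ([[DomainSpec(K.KS), DomainSpec(K.AT, substrate="mal"),
       DomainSpec(K.ACP), DomainSpec(K.TE)]], ["T1PKS"], LOAD_NONE),
])
def test_load_module_variants(groups, classes, expected):
    plan = plan_for(SyntheticBGCSpec(
        cluster_id="load1", classes=classes,
        genes=[GeneSpec("g1", modules=copy.deepcopy(groups))],
    ))
    assert plan.load_descriptor == expected


def test_free_standing_domain_is_nonmodular():
    spec = SyntheticBGCSpec(
        cluster_id="free1", classes=["NRPS"],
        genes=[
            GeneSpec("g1", modules=[
                [DomainSpec(K.A, substrate="gly"), DomainSpec(K.PCP),
                 DomainSpec(K.TE)],
            ]),
            GeneSpec("g2", modules=[[DomainSpec(K.E)]]),
        ],
    )
    plan = plan_for(spec)
    assert [d.kind for d in plan.nonmodular] == [K.E]
    assert any(rule == "non_modular" for _, rule, _ in plan.decisions_log)


def test_no_functional_modules_raises():
    spec = SyntheticBGCSpec(
        cluster_id="none1", classes=["NRPS"],
        genes=[GeneSpec("g1", modules=[[DomainSpec(K.E)]])],
    )
    with pytest.raises(NoFunctionalModulesError):
        plan_for(spec)


def test_resolve_plan_idempotent():
    plan = plan_for(fx.fig_style_bridging_spec())
    snapshot = (
        [
            (m.module_kind, m.is_load, m.is_extending, m.is_terminating,
             m.is_bridging)
            for m in plan.modules
        ],
        plan.load_descriptor, plan.terminal_index, list(plan.decisions_log),
    )
    resolve_plan(plan)
    again = (
        [
            (m.module_kind, m.is_load, m.is_extending, m.is_terminating,
             m.is_bridging)
            for m in plan.modules
        ],
        plan.load_descriptor, plan.terminal_index, list(plan.decisions_log),
    )
    assert snapshot == again


def test_decisions_tsv_format():
    plan = plan_for(fx.fig_style_bridging_spec())
    table = decisions_to_tsv(plan)
    lines = table.strip().splitlines()
    assert lines[0] == "module_index\trule\toutcome"
    assert len(lines) > len(plan.modules)  # at least one entry per module
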