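"""Assembly-line module construction and activity heuristics.

Starting from the parsed cluster, this module groups free-standing domains
into functional modules, merges cross-gene bridging modules, detects inactive
dehydratase-docking (DHD) arrangements in trans-AT clusters, resolves which
modules actually extend the chain, and classifies the load module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    Activity,
    CARRIER_KINDS,
    CONDENSATION_KINDS,
    ClusterClass,
    ClusterRecord,
    DomainKind,
    DomainRecord,
    ModuleRecord,
    RELEASE_KINDS,
)

LOAD_CHEMISTRY = frozenset(
    {DomainKind.A, DomainKind.AT, DomainKind.CAL, DomainKind.GNAT, DomainKind.FKBH}
)

LOAD_NONE = "none"
LOAD_STANDARD_PKS = "standard_PKS"
LOAD_STANDARD_NRPS = "standard_NRPS"
LOAD_C_ACYLATED_NRPS = "C_acylated_NRPS"
LOAD_CAL = "CAL"
LOAD_GNAT = "GNAT"
LOAD_FKBH = "FkbH"


class NoFunctionalModulesError(ValueError):
    """No assemblable functional modules were found in the cluster."""


@dataclass
class AssemblyPlan:
    """Final ordered module list with resolved activity for one cluster."""

    cluster_id: str
    classes: set[ClusterClass]
    modules: list[ModuleRecord]
    load_descriptor: str = LOAD_NONE
    terminal_index: int | None = None
    nonmodular: list[DomainRecord] = field(default_factory=list)
    decisions_log: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def chain_length(self) -> int:
        return sum(1 for m in self.modules if m.is_extending)

    def log(self, index: int, rule: str, outcome: str) -> None:
        self.decisions_log.append((index, rule, outcome))


def _module_kind(module: ModuleRecord) -> str:
    has_pks = module.has(DomainKind.KS, DomainKind.AT, DomainKind.GNAT, DomainKind.FKBH)
    has_nrps = module.has(DomainKind.C, DomainKind.CY, DomainKind.A)
    if has_pks and has_nrps:
        # extension chemistry decides; KS wins ties (unique extension reaction)
        if module.has(DomainKind.KS):
            return "PKS"
        return "NRPS"
    if has_pks:
        return "PKS"
    if has_nrps:
        return "NRPS"
    if module.has(DomainKind.CAL):
        return "PKS" if module.has(DomainKind.ACP) else "NRPS"
    return "unknown"


def detect_dhd(module: ModuleRecord, is_transat: bool = True) -> bool:
    """Detect a dehydratase-docking arrangement split across two genes.

    True when the module crosses a gene boundary with KS as the last domain
    of the first gene and DH immediately followed by ACP opening the second.
    Such modules are typically catalytically inactive.
    """
    if not is_transat or not module.spans_gene_boundary:
        return False
    genes = module.gene_ids()
    first_gene, second_gene = genes[0], genes[1]
    first_part = [d for d in module.domains if d.gene_id == first_gene]
    second_part = [d for d in module.domains if d.gene_id == second_gene]
    if not first_part or len(second_part) < 2:
        return False
    return (
        first_part[-1].kind == DomainKind.KS
        and second_part[0].kind == DomainKind.DH
        and second_part[1].kind == DomainKind.ACP
    )


def resolve_extension_activity(
    module: ModuleRecord, cluster_classes: set[ClusterClass]
) -> bool:
    """Decide whether a candidate module performs a chain elongation."""
    is_transat = ClusterClass.TRANSAT_PKS in cluster_classes
    if detect_dhd(module, is_transat):
        return False
    kind = module.module_kind if module.module_kind != "unknown" else _module_kind(module)
    if kind == "PKS" and module.has(DomainKind.OMT):
        # O-methyltransferase-containing PKS modules carry inactive KS domains
        return False
    ks = module.get(DomainKind.KS)
    if ks is not None and ks.activity == Activity.INACTIVE:
        return False
    has_carrier = module.has(*CARRIER_KINDS)
    if kind == "PKS":
        if not (ks is not None and has_carrier):
            return False
        # cis-PKS needs an in-module AT; trans-AT relies on freestanding ATs
        if not is_transat and not module.has(DomainKind.AT):
            return False
        return True
    if kind == "NRPS":
        return (
            module.has(DomainKind.C, DomainKind.CY)
            and module.has(DomainKind.A, DomainKind.CAL)
            and has_carrier
        )
    return False


def resolve_reduction_activity(module: ModuleRecord) -> set[DomainKind]:
    """Active reductive domains of a PKS module, from the KR annotation.

    DH and ER act on the moiety produced by the preceding KR, so an inactive
    or absent KR silences them too; an unannotated KR defaults to active.
    """
    kr = module.get(DomainKind.KR)
    if kr is None or kr.activity == Activity.INACTIVE:
        return set()
    active = {DomainKind.KR}
    if module.has(DomainKind.DH):
        active.add(DomainKind.DH)
        if module.has(DomainKind.ER):
            active.add(DomainKind.ER)
    return active


def resolve_load_module(plan: AssemblyPlan) -> str:
    """Classify the first module of the plan as a load-module variant."""
    if not plan.modules:
        return LOAD_NONE
    m0 = plan.modules[0]
    if m0.has(DomainKind.GNAT):
        return LOAD_GNAT
    if m0.has(DomainKind.FKBH):
        return LOAD_FKBH
    if m0.has(DomainKind.CAL) and not m0.has(DomainKind.KS):
        return LOAD_CAL
    if m0.has(DomainKind.KS):
        return LOAD_NONE  # first module is a full extender; no load module
    if m0.has(DomainKind.AT) and m0.has(*CARRIER_KINDS):
        return LOAD_STANDARD_PKS
    if m0.has(DomainKind.A):
        # a C domain in the initiating NRPS module acylates the first residue
        if m0.has(DomainKind.C, DomainKind.CY):
            return LOAD_C_ACYLATED_NRPS
        return LOAD_STANDARD_NRPS
    return LOAD_NONE


def _split_groups(domains: list[DomainRecord]) -> list[list[DomainRecord]]:
    """Split a gene's leftover domains at each condensation-kind domain."""
    groups: list[list[DomainRecord]] = []
    current: list[DomainRecord] = []
    for dom in domains:
        if dom.kind in CONDENSATION_KINDS and current:
            groups.append(current)
            current = []
        current.append(dom)
    if current:
        groups.append(current)
    return groups


def _qualifies_as_module(domains: list[DomainRecord]) -> bool:
    kinds = {d.kind for d in domains}
    if kinds & (CONDENSATION_KINDS | RELEASE_KINDS):
        return True
    return bool(kinds & CARRIER_KINDS) and bool(kinds & LOAD_CHEMISTRY)


def _position_key(cluster: ClusterRecord, module: ModuleRecord):
    gene_order = {g.gene_id: i for i, g in enumerate(cluster.genes)}
    d0 = module.domains[0]
    return (gene_order[d0.gene_id], d0.order_index)


def assemble_modules(cluster: ClusterRecord) -> AssemblyPlan:
    """Build the final module list for a supported cluster.

    Annotated modules are kept as given; domains outside any annotated module
    are grouped by condensation-domain boundaries, merged across gene
    boundaries where a trailing KS meets a carrier-bearing head (bridging
    modules), and filtered into modules vs. logged non-modular leftovers.
    """
    plan = AssemblyPlan(
        cluster_id=cluster.cluster_id, classes=set(cluster.classes), modules=[]
    )
    in_annotated = {
        id(d) for m in cluster.annotated_modules for d in m.domains
    }

    raw_groups: list[list[DomainRecord]] = []
    for gene in cluster.genes:
        leftover = [d for d in gene.domains if id(d) not in in_annotated]
        raw_groups.extend(_split_groups(leftover))

    # cross-gene bridging merge: KS-only tail of one gene + carrier head of the next
    merged: list[tuple[list[DomainRecord], bool]] = []
    i = 0
    while i < len(raw_groups):
        group = raw_groups[i]
        bridging = False
        if i + 1 < len(raw_groups):
            nxt = raw_groups[i + 1]
            tail_kinds = {d.kind for d in group}
            head_kinds = {d.kind for d in nxt}
            crosses = group[-1].gene_id != nxt[0].gene_id
            if (
                crosses
                and group[-1].kind == DomainKind.KS
                and not tail_kinds & CARRIER_KINDS
                and head_kinds & CARRIER_KINDS
                and DomainKind.KS not in head_kinds
            ):
                group = group + nxt
                bridging = True
                i += 1
        merged.append((group, bridging))
        i += 1

    assembled: list[ModuleRecord] = []
    for group, bridging in merged:
        if _qualifies_as_module(group):
            assembled.append(
                ModuleRecord(domains=group, provenance="assembled", is_bridging=bridging)
            )
        else:
            plan.nonmodular.extend(group)

    modules = list(cluster.annotated_modules) + assembled
    modules.sort(key=lambda m: _position_key(cluster, m))

    # fold release-only stubs (bare TE/TD, possibly with a trailing carrier)
    # into the preceding module
    folded: list[ModuleRecord] = []
    for mod in modules:
        kinds = {d.kind for d in mod.domains}
        if (
            folded
            and kinds <= (RELEASE_KINDS | CARRIER_KINDS)
            and kinds & RELEASE_KINDS
            and not folded[-1].has(*RELEASE_KINDS)
        ):
            folded[-1].domains.extend(mod.domains)
        else:
            folded.append(mod)
    plan.modules = folded

    for dom in plan.nonmodular:
        plan.log(-1, "non_modular", f"{dom.kind.value}@{dom.gene_id}")
    if not plan.modules:
        raise NoFunctionalModulesError(
            f"cluster {cluster.cluster_id}: no functional modules or domains"
        )
    return resolve_plan(plan)


def resolve_plan(plan: AssemblyPlan) -> AssemblyPlan:
    """Resolve module kinds, flags and the load descriptor (idempotent)."""
    plan.decisions_log = [e for e in plan.decisions_log if e[1] == "non_modular"]
    is_transat = ClusterClass.TRANSAT_PKS in plan.classes

    for mod in plan.modules:
        mod.module_kind = _module_kind(mod)

    plan.load_descriptor = resolve_load_module(plan)
    if plan.modules:
        plan.modules[0].is_load = plan.load_descriptor != LOAD_NONE
    plan.log(0, "load_module", plan.load_descriptor)

    plan.terminal_index = None
    for i, mod in enumerate(plan.modules):
        mod.is_terminating = mod.has(*RELEASE_KINDS)
        past_terminal = plan.terminal_index is not None
        if past_terminal:
            mod.is_extending = False
            plan.log(i, "after_termination", "inactive")
        elif mod.is_load:
            mod.is_extending = False
            plan.log(i, "extension_activity", "load module")
        else:
            mod.is_extending = resolve_extension_activity(mod, plan.classes)
            reason = "active" if mod.is_extending else "inactive"
            if detect_dhd(mod, is_transat):
                reason = "inactive (DHD)"
            elif mod.module_kind == "PKS" and mod.has(DomainKind.OMT):
                reason = "inactive (oMT in PKS module)"
            plan.log(i, "extension_activity", reason)
        if mod.module_kind == "PKS":
            active_red = resolve_reduction_activity(mod)
            plan.log(
                i,
                "reduction_activity",
                ",".join(sorted(k.value for k in active_red)) or "none",
            )
        if mod.is_terminating and not past_terminal:
            plan.terminal_index = i
            plan.log(i, "termination", "chain released here")
    return plan


def decisions_to_tsv(plan: AssemblyPlan) -> str:
    """Serialize the decisions log as a tab-separated audit table."""
    lines = ["module_index\trule\toutcome"]
    for index, rule, outcome in plan.decisions_log:
        lines.append(f"{index}\t{rule}\t{outcome}")
    return "\n".join(lines) + "\n"
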