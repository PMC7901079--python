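"""Translate an assembly plan into an explicit stoichiometric pathway.

Every active module contributes a monomer-loading reaction, a condensation
reaction extending the lumped backbone species X_n -> X_{n+1}, and one
reaction per active in-module tailoring domain (methyltransferases, the
KR/DH/ER reductive loop, epimerase/isomerase no-ops).  The terminating
module releases the product hydrolytically (TE) or reductively (TD).
Rare-monomer subpathways, generic-monomer pseudo-reactions and smCOG-driven
post-release tailoring are appended afterwards.

Backbone intermediates are lumped pseudo-metabolites: no elemental formula is
tracked for them, and mass balance is asserted only for cofactors, carriers
and small molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import metabolites as M
from .assembly import (
    AssemblyPlan,
    LOAD_C_ACYLATED_NRPS,
    LOAD_CAL,
    LOAD_FKBH,
    LOAD_GNAT,
    LOAD_NONE,
    LOAD_STANDARD_NRPS,
    LOAD_STANDARD_PKS,
    resolve_reduction_activity,
)
from .metabolites import MetaboliteRef
from .records import (
    Activity,
    ClusterClass,
    ClusterRecord,
    DomainKind,
    ModuleRecord,
)

DEFAULT_BOUNDS = (0.0, 1000.0)
SCHEMA_VERSION = "1.0"


@dataclass
class ReactionSpec:
    """One stoichiometric reaction (negative coefficient = consumed)."""

    rxn_id: str
    name: str
    stoich: dict[MetaboliteRef, float]
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    genes: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ValueError(f"reaction {self.rxn_id} has empty stoichiometry")

    def coefficient(self, met_id: str) -> float:
        for met, coeff in self.stoich.items():
            if met.met_id == met_id:
                return coeff
        return 0.0


@dataclass
class PathwayReconstruction:
    """Ordered reaction chain plus new metabolites for one BGC."""

    cluster_id: str
    reactions: list[ReactionSpec] = field(default_factory=list)
    new_metabolites: set[MetaboliteRef] = field(default_factory=set)
    final_product: MetaboliteRef | None = None
    warnings: list[str] = field(default_factory=list)

    def all_metabolites(self) -> dict[str, MetaboliteRef]:
        out: dict[str, MetaboliteRef] = {}
        for rxn in self.reactions:
            for met in rxn.stoich:
                out[met.met_id] = met
        return out


def select_extender_unit(module: ModuleRecord) -> tuple[MetaboliteRef, str | None]:
    """Map a module's A/AT specificity code to an extender metabolite.

    Returns the metabolite plus an optional warning (fallback used).  The
    conservative fallback is a generic amino acid for NRPS modules and
    malonyl-CoA for PKS modules.
    """
    if module.module_kind == "PKS":
        at = module.get(DomainKind.AT)
        code = (at.substrate or "").lower() if at is not None else ""
        if code in M.PKS_EXTENDER_CODES:
            return M.PKS_EXTENDER_CODES[code], None
        if code in M.NONSPECIFIC_CODES:
            return M.MALCOA, None
        return M.MALCOA, f"unrecognized PKS extender code {code!r}; using malonyl-CoA"
    a_dom = module.get(DomainKind.A) or module.get(DomainKind.CAL)
    code = (a_dom.substrate or "").lower() if a_dom is not None else ""
    if code in M.NRPS_MONOMER_CODES:
        return M.NRPS_MONOMER_CODES[code], None
    if code in M.NONSPECIFIC_CODES:
        return M.GENERIC_AA, None
    return M.GENERIC_AA, f"unrecognized NRPS monomer code {code!r}; using generic amino acid"


class _Builder:
    """Stateful reaction emitter for one reconstruction."""

    def __init__(self, plan: AssemblyPlan, cluster: ClusterRecord):
        self.plan = plan
        self.cluster = cluster
        self.cid = cluster.cluster_id
        self.rec = PathwayReconstruction(cluster_id=self.cid)
        self.carrier = MetaboliteRef(
            f"{self.cid}_carrier", "free carrier protein (ACP/PCP)", "c", "cofactor"
        )
        self.chain: MetaboliteRef | None = None
        self.chain_index = 0
        self.variant = 0
        self.serial = 0
        self.rare_used: list[str] = []
        self.generic_aa_used = False
        self.generic_fa_used = False
        self.generic_starter_used = False

    # -- low-level helpers -----------------------------------------------
    def emit(
        self,
        tag: str,
        name: str,
        stoich: dict[MetaboliteRef, float],
        provenance: str,
        genes: list[str] | None = None,
    ) -> ReactionSpec:
        self.serial += 1
        rxn = ReactionSpec(
            rxn_id=f"{self.cid}_r{self.serial:03d}_{tag}",
            name=name,
            stoich=dict(stoich),
            genes=list(genes or []),
            provenance=provenance,
        )
        self.rec.reactions.append(rxn)
        return rxn

    def warn(self, message: str) -> None:
        self.rec.warnings.append(message)

    def new_chain(self, advance: bool) -> MetaboliteRef:
        """Next backbone species: X_{n+1} on condensation, a tailored
        variant of X_n otherwise."""
        if advance:
            self.chain_index += 1
            self.variant = 0
            met_id = f"{self.cid}_chain_{self.chain_index}"
        else:
            self.variant += 1
            met_id = f"{self.cid}_chain_{self.chain_index}_v{self.variant}"
        met = MetaboliteRef(met_id, f"backbone intermediate {met_id}", "c", "chain_intermediate")
        self.chain = met
        return met

    def _note_monomer(self, monomer: MetaboliteRef) -> None:
        if monomer is M.GENERIC_AA:
            self.generic_aa_used = True
        for code, met in M.RARE_AA.items():
            if met == monomer and code not in self.rare_used:
                self.rare_used.append(code)
        if monomer == M.MXMAL_ACP and "mxmal" not in self.rare_used:
            self.rare_used.append("mxmal")

    def _gate_mxmal(self, module: ModuleRecord) -> bool:
        return any(g.smcog_id == M.MXMAL_GATING_SMCOG for g in self.cluster.genes)

    # -- module reactions --------------------------------------------------
    def load_monomer(self, module: ModuleRecord, idx: int) -> MetaboliteRef:
        """Emit the loading reaction; return the carrier-bound monomer."""
        extender, warning = select_extender_unit(module)
        if warning:
            self.warn(f"module {idx}: {warning}")
        if extender == M.MXMAL_ACP and not self._gate_mxmal(module):
            self.warn(
                f"module {idx}: methoxymalonyl-ACP requested but no gene with "
                f"smCOG {M.MXMAL_GATING_SMCOG} present; using malonyl-CoA"
            )
            extender = M.MALCOA
        self._note_monomer(extender)
        genes = module.gene_ids()
        if module.module_kind == "PKS":
            if extender == M.MXMAL_ACP:
                # the subpathway delivers this unit already carrier-bound
                return M.MXMAL_ACP
            loaded = MetaboliteRef(
                f"{self.cid}_acyl_m{idx}", f"{extender.name} on carrier (module {idx})",
                "c", "chain_intermediate",
            )
            self.emit(
                f"at_m{idx}",
                f"AT loading of {extender.name} (module {idx})",
                {extender: -1, self.carrier: -1, loaded: 1, M.COA: 1},
                provenance="AT",
                genes=genes,
            )
            return loaded
        loaded = MetaboliteRef(
            f"{self.cid}_aminoacyl_m{idx}",
            f"{extender.name} on carrier (module {idx})",
            "c", "chain_intermediate",
        )
        self.emit(
            f"a_m{idx}",
            f"A-domain activation and loading of {extender.name} (module {idx})",
            {M.ATP: -1, extender: -1, self.carrier: -1, loaded: 1, M.AMP: 1, M.PPI: 1},
            provenance="A",
            genes=genes,
        )
        return loaded

    def condense(self, module: ModuleRecord, loaded: MetaboliteRef, idx: int) -> None:
        assert self.chain is not None
        prev = self.chain
        nxt = self.new_chain(advance=True)
        genes = module.gene_ids()
        if module.module_kind == "PKS":
            self.emit(
                f"ks_m{idx}",
                f"KS decarboxylative condensation (module {idx})",
                {loaded: -1, prev: -1, nxt: 1, M.CO2: 1, self.carrier: 1},
                provenance="KS",
                genes=genes,
            )
        else:
            cy = module.get(DomainKind.CY)
            kind = "Cy" if cy is not None and module.get(DomainKind.C) is None else "C"
            label = "condensation and cyclization" if kind == "Cy" else "condensation"
            self.emit(
                f"c_m{idx}",
                f"{kind}-domain peptide {label} (module {idx})",
                {loaded: -1, prev: -1, nxt: 1, M.H2O: 1, self.carrier: 1},
                provenance=kind,
                genes=genes,
            )

    def tailor_in_module(self, module: ModuleRecord, idx: int) -> None:
        genes = module.gene_ids()
        active_red = set()
        if module.module_kind == "PKS":
            active_red = resolve_reduction_activity(module)

        def transform(tag, name, extra, provenance):
            prev = self.chain
            nxt = self.new_chain(advance=False)
            stoich = {prev: -1, nxt: 1}
            stoich.update(extra)
            self.emit(tag, name, stoich, provenance, genes)

        for kind, prov in (
            (DomainKind.CMT, "cMT"),
            (DomainKind.NMT, "nMT"),
            (DomainKind.OMT, "oMT"),
        ):
            dom = module.get(kind)
            if dom is None or dom.activity == Activity.INACTIVE:
                continue
            if kind == DomainKind.OMT and module.module_kind == "PKS":
                continue  # such modules were already deactivated entirely
            transform(
                f"{prov.lower()}_m{idx}",
                f"{prov} methylation (module {idx})",
                {M.SAM: -1, M.SAH: 1},
                prov,
            )
        if DomainKind.KR in active_red:
            transform(
                f"kr_m{idx}", f"KR ketoreduction (module {idx})",
                {M.NADPH: -1, M.H: -1, M.NADP: 1}, "KR",
            )
        if DomainKind.DH in active_red:
            transform(
                f"dh_m{idx}", f"DH dehydration (module {idx})", {M.H2O: 1}, "DH",
            )
        if DomainKind.ER in active_red:
            transform(
                f"er_m{idx}", f"ER enoylreduction (module {idx})",
                {M.NADPH: -1, M.H: -1, M.NADP: 1}, "ER",
            )
        if module.has(DomainKind.E):
            transform(f"e_m{idx}", f"epimerization (module {idx})", {}, "E")
        if module.has(DomainKind.ECH):
            transform(f"ech_m{idx}", f"enoyl-CoA isomerization (module {idx})", {}, "ECH")

    # -- load module -------------------------------------------------------
    def build_load(self) -> None:
        descriptor = self.plan.load_descriptor
        modules = self.plan.modules
        m0 = modules[0] if modules else None
        if descriptor == LOAD_NONE:
            return  # first active extender doubles as start (see build())
        genes = m0.gene_ids() if m0 else []
        chain0 = MetaboliteRef(
            f"{self.cid}_chain_0", "starter unit on carrier (X_0)",
            "c", "chain_intermediate",
        )
        self.chain = chain0
        self.chain_index = 0
        self.variant = 0
        if descriptor == LOAD_STANDARD_PKS:
            at = m0.get(DomainKind.AT) if m0 else None
            code = (at.substrate or "").lower() if at is not None else ""
            starter = M.PKS_EXTENDER_CODES.get(code, M.MALCOA)
            if starter == M.MXMAL_ACP:
                starter = M.MALCOA
            self.emit(
                "load_at",
                f"AT loading of starter {starter.name}",
                {starter: -1, self.carrier: -1, chain0: 1, M.COA: 1},
                provenance="AT",
                genes=genes,
            )
        elif descriptor in (LOAD_STANDARD_NRPS, LOAD_C_ACYLATED_NRPS):
            extender, warning = select_extender_unit(m0)
            if warning:
                self.warn(f"load module: {warning}")
            self._note_monomer(extender)
            if descriptor == LOAD_STANDARD_NRPS:
                self.emit(
                    "load_a",
                    f"A-domain loading of starter {extender.name}",
                    {M.ATP: -1, extender: -1, self.carrier: -1, chain0: 1,
                     M.AMP: 1, M.PPI: 1},
                    provenance="A",
                    genes=genes,
                )
            else:
                loaded = MetaboliteRef(
                    f"{self.cid}_aminoacyl_load",
                    f"{extender.name} on carrier (load module)",
                    "c", "chain_intermediate",
                )
                self.emit(
                    "load_a",
                    f"A-domain loading of starter {extender.name}",
                    {M.ATP: -1, extender: -1, self.carrier: -1, loaded: 1,
                     M.AMP: 1, M.PPI: 1},
                    provenance="A",
                    genes=genes,
                )
                self.generic_fa_used = True
                self.emit(
                    "load_acyl",
                    "C-domain N-acylation of the starter residue with a generic fatty acid",
                    {M.GENERIC_FA: -1, loaded: -1, chain0: 1, M.COA: 1},
                    provenance="C-acyl",
                    genes=genes,
                )
        elif descriptor == LOAD_CAL:
            cal = m0.get(DomainKind.CAL) if m0 else None
            code = (cal.substrate or "").lower() if cal is not None else ""
            starter = M.NRPS_MONOMER_CODES.get(code)
            if starter is None:
                starter = M.GENERIC_STARTER
                self.generic_starter_used = True
            else:
                self._note_monomer(starter)
            self.emit(
                "load_cal",
                f"CAL incorporation of starter {starter.name}",
                {starter: -1, self.carrier: -1, chain0: 1, M.H2O: 1},
                provenance="CAL",
                genes=genes,
            )
        elif descriptor == LOAD_GNAT:
            self.emit(
                "load_gnat",
                "GNAT decarboxylation of malonyl-CoA onto the carrier",
                {M.MALCOA: -1, self.carrier: -1, chain0: 1, M.COA: 1, M.CO2: 1},
                provenance="GNAT",
                genes=genes,
            )
        elif descriptor == LOAD_FKBH:
            self.emit(
                "load_fkbh",
                "FkbH dephosphorylation of 1,3-bisphosphoglycerate onto the carrier",
                {M.BPG13: -1, self.carrier: -1, chain0: 1, M.PI: 2},
                provenance="FkbH",
                genes=genes,
            )

    # -- release and post-assembly steps ----------------------------------
    def build_release(self) -> None:
        assert self.chain is not None
        product = MetaboliteRef(
            f"{self.cid}_product", f"released product of {self.cid}", "c", "final_product"
        )
        terminal = (
            self.plan.modules[self.plan.terminal_index]
            if self.plan.terminal_index is not None
            else None
        )
        if terminal is not None and terminal.has(DomainKind.TD):
            self.emit(
                "release_td",
                "TD reductive release of the final product",
                {M.NADPH: -1, M.H: -1, self.chain: -1, product: 1, M.NADP: 1,
                 self.carrier: 1},
                provenance="TD",
                genes=terminal.gene_ids(),
            )
        elif terminal is not None:
            self.emit(
                "release_te",
                "TE hydrolytic release of the final product",
                {M.H2O: -1, self.chain: -1, product: 1, self.carrier: 1},
                provenance="TE",
                genes=terminal.gene_ids(),
            )
        else:
            self.warn(
                "no TE/TD domain found; product released by implicit hydrolysis"
            )
            self.emit(
                "release_implicit",
                "implicit hydrolytic release (no TE/TD annotated)",
                {M.H2O: -1, self.chain: -1, product: 1, self.carrier: 1},
                provenance="release_fallback",
            )
        self.rec.final_product = product

    def add_rare_precursors(self) -> None:
        for code in self.rare_used:
            if code == "mxmal":
                glyceryl = MetaboliteRef(
                    f"{self.cid}_glyceryl_acp", "glyceryl carrier intermediate",
                    "c", "precursor",
                )
                self.emit(
                    "mxmal_a",
                    "glyceryl transfer from 1,3-bisphosphoglycerate (methoxymalonyl-ACP route)",
                    {M.BPG13: -1, self.carrier: -1, glyceryl: 1, M.PI: 2},
                    provenance="precursor:mxmal",
                )
                self.emit(
                    "mxmal_b",
                    "oxidation and O-methylation to methoxymalonyl-ACP",
                    {glyceryl: -1, M.NAD: -2, M.SAM: -1,
                     M.MXMAL_ACP: 1, M.NADH: 2, M.SAH: 1, M.H: 2},
                    provenance="precursor:mxmal",
                )
                continue
            steps = M.RARE_PRECURSOR_PATHWAYS.get(code)
            if steps is None:
                self.warn(f"rare monomer {code!r} has no synthesis subpathway defined")
                continue
            for tag, name, stoich in steps:
                self.emit(tag, name, stoich, provenance=f"precursor:{code}")

    def add_generic_pseudoreactions(self) -> None:
        if self.generic_aa_used:
            for code, aa in M.PROTEINOGENIC_AA.items():
                self.emit(
                    f"gaa_{code}",
                    f"pseudo-conversion {aa.name} -> generic amino acid",
                    {aa: -1, M.GENERIC_AA: 1},
                    provenance="pseudo:generic_aa",
                )
        if self.generic_fa_used:
            self.emit(
                "gfa",
                "pseudo-sourcing of a generic fatty acyl-CoA from the cellular pool",
                {M.FA_POOL: -1, M.GENERIC_FA: 1},
                provenance="pseudo:generic_fa",
            )
        if self.generic_starter_used:
            self.emit(
                "gstarter",
                "pseudo-sourcing of a generic starter unit from acetyl-CoA",
                {M.ACCOA: -1, M.H2O: -1, M.GENERIC_STARTER: 1, M.COA: 1},
                provenance="pseudo:generic_starter",
            )

    def add_tailoring(self) -> None:
        assert self.rec.final_product is not None
        current = self.rec.final_product
        k = 0
        for gene in self.cluster.genes:  # gene genomic order fixes the sequence
            code = gene.smcog_id
            if code not in M.TAILORING_SMCOGS:
                continue
            k += 1
            nxt = MetaboliteRef(
                f"{self.cid}_product_t{k}", f"tailored product (step {k})",
                "c", "final_product",
            )
            if code in M.GLYCOSYLATION_SMCOGS:
                self.emit(
                    f"tailor{k}_glyc",
                    f"glycosylation by {gene.gene_id} (smCOG {code})",
                    {M.NDP_HEXOSE: -1, current: -1, nxt: 1, M.NDP: 1},
                    provenance=f"smCOG:{code}",
                    genes=[gene.gene_id],
                )
            elif code == M.C5N_SMCOG:
                self.emit(
                    f"tailor{k}_c5n",
                    f"2-amino-3-hydroxycyclopent-2-enone incorporation by {gene.gene_id}",
                    {M.ACCOA: -1, M.PROTEINOGENIC_AA["gly"]: -1, M.ATP: -1,
                     current: -1, nxt: 1, M.COA: 1, M.AMP: 1, M.PPI: 1, M.H2O: 1},
                    provenance=f"smCOG:{code}",
                    genes=[gene.gene_id],
                )
            else:  # ATP-dependent ligase
                self.emit(
                    f"tailor{k}_lig",
                    f"ATP-dependent ligation by {gene.gene_id} (smCOG {code})",
                    {M.ATP: -1, current: -1, nxt: 1, M.AMP: 1, M.PPI: 1},
                    provenance=f"smCOG:{code}",
                    genes=[gene.gene_id],
                )
            current = nxt
        if k:
            self.rec.final_product = current

    # -- orchestration -----------------------------------------------------
    def build(self) -> PathwayReconstruction:
        self.build_load()
        last = (
            self.plan.terminal_index
            if self.plan.terminal_index is not None
            else len(self.plan.modules) - 1
        )
        for idx, module in enumerate(self.plan.modules[: last + 1]):
            if not module.is_extending:
                continue
            loaded = self.load_monomer(module, idx)
            if self.chain is None:
                # no load module: the first extender's loaded monomer starts
                # the chain; no condensation is possible yet
                self.chain = loaded
                self.chain_index = 0
                self.warn(
                    "no load module found; chain initialized from the first "
                    "extender's monomer"
                )
                self.tailor_in_module(module, idx)
                continue
            self.condense(module, loaded, idx)
            self.tailor_in_module(module, idx)
        if self.chain is None:
            raise ValueError(
                f"cluster {self.cid}: no chain could be initialized "
                "(no load module and no active extender)"
            )
        self.build_release()
        self.add_rare_precursors()
        self.add_generic_pseudoreactions()
        self.add_tailoring()
        # cluster-specific species are necessarily new to any reference model
        for met in self.rec.all_metabolites().values():
            if met.met_id.startswith(self.cid):
                self.rec.new_metabolites.add(met)
        return self.rec


def build_pathway(plan: AssemblyPlan, cluster: ClusterRecord) -> PathwayReconstruction:
    """Build the full stoichiometric reconstruction for one cluster."""
    rec = _Builder(plan, cluster).build()
    validate_reconstruction(rec)
    return rec


def reconstruct(genbank_text: str) -> PathwayReconstruction:
    """Parse, classify, assemble and build in one call."""
    from .assembly import assemble_modules
    from .ingest import classify_cluster, parse_region

    cluster = parse_region(genbank_text)
    classify_cluster(cluster)
    plan = assemble_modules(cluster)
    return build_pathway(plan, cluster)


# ---------------------------------------------------------------------------
# validation and audit helpers
# ---------------------------------------------------------------------------

def validate_reconstruction(rec: PathwayReconstruction) -> None:
    """Assert chain connectivity and carrier balance.

    Every backbone intermediate must be produced by exactly one reaction and
    consumed by exactly one (the next step or the release); the final product
    of the reconstruction is produced once and never consumed.  Net carrier
    production over the pathway must be zero.
    """
    produced: dict[str, int] = {}
    consumed: dict[str, int] = {}
    carrier_net = 0.0
    for rxn in rec.reactions:
        for met, coeff in rxn.stoich.items():
            if met.role == "chain_intermediate" or met.role == "final_product":
                if coeff > 0:
                    produced[met.met_id] = produced.get(met.met_id, 0) + 1
                elif coeff < 0:
                    consumed[met.met_id] = consumed.get(met.met_id, 0) + 1
            if met.met_id == f"{rec.cluster_id}_carrier":
                carrier_net += coeff
    assert rec.final_product is not None, "reconstruction lacks a final product"
    fp = rec.final_product.met_id
    for met_id, n in produced.items():
        if n != 1:
            raise AssertionError(f"{met_id} produced by {n} reactions (expected 1)")
    for met_id, n in consumed.items():
        if met_id == fp:
            raise AssertionError("final product must not be consumed")
        if n != 1:
            raise AssertionError(f"{met_id} consumed by {n} reactions (expected 1)")
    for met_id in produced:
        if met_id != fp and met_id not in consumed:
            raise AssertionError(f"dead-end intermediate {met_id}")
    if abs(carrier_net) > 1e-9:
        raise AssertionError(f"net carrier balance {carrier_net} != 0")


def cofactor_audit(rec: PathwayReconstruction) -> dict[str, float]:
    """Sum cofactor usage per domain-provenance class over the backbone.

    Only reactions whose provenance is a Table-style domain kind are counted,
    so the canonical identities hold exactly: ATP consumed equals the number
    of A-domain loadings, SAM equals SAH equals active methyltransferase
    steps, NADPH equals active KR + ER (+1 for a TD release), and CO2 from
    condensations equals the number of active KS steps.  Precursor
    subpathways, pseudo-reactions, GNAT loads and tailoring move these
    species too and are reported separately.
    """
    domain_provs_mt = {"cMT", "nMT", "oMT"}
    audit = {
        "n_A": 0, "atp_A": 0.0,
        "n_MT": 0, "sam_MT": 0.0, "sah_MT": 0.0,
        "n_KR": 0, "n_ER": 0, "n_TD": 0, "nadph_red": 0.0,
        "n_KS": 0, "co2_KS": 0.0,
        "carrier_net": 0.0,
        "co2_other": 0.0, "atp_other": 0.0,
    }
    for rxn in rec.reactions:
        prov = rxn.provenance
        atp = -min(rxn.coefficient("atp"), 0.0)
        co2 = max(rxn.coefficient("co2"), 0.0)
        audit["carrier_net"] += rxn.coefficient(f"{rec.cluster_id}_carrier")
        if prov == "A":
            audit["n_A"] += 1
            audit["atp_A"] += atp
        elif prov in domain_provs_mt:
            audit["n_MT"] += 1
            audit["sam_MT"] += -min(rxn.coefficient("amet"), 0.0)
            audit["sah_MT"] += max(rxn.coefficient("ahcys"), 0.0)
        elif prov in ("KR", "ER", "TD"):
            audit[f"n_{prov}"] += 1
            audit["nadph_red"] += -min(rxn.coefficient("nadph"), 0.0)
        elif prov == "KS":
            audit["n_KS"] += 1
            audit["co2_KS"] += co2
        else:
            audit["co2_other"] += co2
            audit["atp_other"] += atp
    return audit


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def pathway_to_json(rec: PathwayReconstruction) -> str:
    """Serialize a reconstruction to the versioned pathway-JSON schema."""
    mets = rec.all_metabolites()
    payload = {
        "schema_version": SCHEMA_VERSION,
        "cluster_id": rec.cluster_id,
        "final_product": rec.final_product.met_id if rec.final_product else None,
        "metabolites": {
            mid: {"name": m.name, "compartment": m.compartment, "role": m.role}
            for mid, m in sorted(mets.items())
        },
        "reactions": [
            {
                "id": r.rxn_id,
                "name": r.name,
                "stoichiometry": {m.met_id: c for m, c in sorted(
                    r.stoich.items(), key=lambda kv: kv[0].met_id)},
                "lower_bound": r.bounds[0],
                "upper_bound": r.bounds[1],
                "genes": r.genes,
                "provenance": r.provenance,
            }
            for r in rec.reactions
        ],
        "warnings": rec.warnings,
    }
    return json.dumps(payload, indent=2, sort_keys=False)


def pathway_from_json(text: str) -> PathwayReconstruction:
    payload = json.loads(text)
    mets = {
        mid: MetaboliteRef(mid, info["name"], info["compartment"], info["role"])
        for mid, info in payload["metabolites"].items()
    }
    rec = PathwayReconstruction(cluster_id=payload["cluster_id"])
    for entry in payload["reactions"]:
        rec.reactions.append(
            ReactionSpec(
                rxn_id=entry["id"],
                name=entry["name"],
                stoich={mets[mid]: c for mid, c in entry["stoichiometry"].items()},
                bounds=(entry["lower_bound"], entry["upper_bound"]),
                genes=list(entry["genes"]),
                provenance=entry["provenance"],
            )
        )
    fp = payload.get("final_product")
    rec.final_product = mets[fp] if fp else None
    rec.warnings = list(payload.get("warnings", []))
    return rec
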