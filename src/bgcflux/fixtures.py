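"""Synthetic test inputs: antiSMASH-dialect region files and a toy model.

The region writer emits exactly the qualifier vocabulary the parser consumes
(one shared table in :mod:`bgcflux.dialect`), so writer and parser cannot
drift apart.  The toy reference model is a 34-reaction single-compartment
network with small rational coefficients whose optima are exactly
representable, including a gene-annotated by-product route whose knockout is
the unique production-improving target.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

import cobra
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import dialect
from .analysis import MediumSpec
from .records import DomainKind

DOMAIN_WIDTH = 300
GENE_GAP = 100


@dataclass
class DomainSpec:
    kind: DomainKind
    substrate: str | None = None
    activity: str | None = None  # "active" | "inactive" | None
    raw_name: str | None = None  # override the emitted aSDomain name

    def specificity_entries(self) -> list[str]:
        out: list[str] = []
        if self.substrate is not None:
            out.append(f"{dialect.CONSENSUS_PREFIX} {self.substrate}")
        if self.activity is not None:
            prefix = (
                dialect.KR_ACTIVITY_PREFIX
                if self.kind == DomainKind.KR
                else "activity:"
            )
            out.append(f"{prefix} {self.activity}")
        return out


@dataclass
class GeneSpec:
    gene_id: str
    strand: int = 1
    is_core: bool = True
    smcog_id: str | None = None
    # groups of domains; grouping is authoring convenience only unless
    # emit_module_features is set on the cluster spec
    modules: list[list[DomainSpec]] = field(default_factory=list)

    def domains(self) -> list[DomainSpec]:
        return [d for group in self.modules for d in group]


@dataclass
class SyntheticBGCSpec:
    cluster_id: str
    classes: list[str]
    genes: list[GeneSpec]
    seed: int = 0
    emit_module_features: bool = False


def write_synthetic_region(spec: SyntheticBGCSpec) -> str:
    """Render a spec as an antiSMASH-style region GenBank document."""
    if not spec.genes:
        raise ValueError("spec contains no genes")

    features: list[SeqFeature] = []
    cursor = GENE_GAP
    gene_layouts: list[tuple[GeneSpec, int, int]] = []
    for gene in spec.genes:
        n = len(gene.domains())
        start, end = cursor, cursor + max(n, 1) * DOMAIN_WIDTH
        gene_layouts.append((gene, start, end))
        cursor = end + GENE_GAP
    total = cursor

    region = SeqFeature(
        FeatureLocation(0, total, strand=1),
        type=dialect.REGION_FEATURE,
        qualifiers={
            dialect.PRODUCT_QUALIFIER: list(spec.classes),
            "region_number": ["1"],
        },
    )
    features.append(region)

    for gene, start, end in gene_layouts:
        quals = {dialect.LOCUS_TAG_QUALIFIER: [gene.gene_id]}
        if gene.is_core:
            quals[dialect.GENE_KIND_QUALIFIER] = [dialect.CORE_GENE_KIND]
        if gene.smcog_id is not None:
            quals[dialect.GENE_FUNCTIONS_QUALIFIER] = [
                f"biosynthetic-additional (smcogs) SMCOG{gene.smcog_id}:"
                f"synthetic annotation (Score: 100.0; E-value: 1e-10)"
            ]
        features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=gene.strand),
                type=dialect.CDS_FEATURE,
                qualifiers=quals,
            )
        )
        doms = gene.domains()
        group_ids: list[list[str]] = []
        for gi, group in enumerate(gene.modules):
            group_ids.append([])
        flat_index = 0
        for gi, group in enumerate(gene.modules):
            for dom in group:
                # translation slot -> genomic slot (reversed on minus strand)
                slot = (
                    flat_index
                    if gene.strand != -1
                    else len(doms) - 1 - flat_index
                )
                d_start = start + slot * DOMAIN_WIDTH
                d_end = d_start + DOMAIN_WIDTH
                name = dom.raw_name or dialect.KIND_TO_ASDOMAIN.get(
                    dom.kind, "Unknown_domain"
                )
                domain_id = f"nrpspksdomains_{gene.gene_id}_{flat_index}_{dom.kind.value}"
                group_ids[gi].append(domain_id)
                dom_quals = {
                    dialect.ASDOMAIN_NAME_QUALIFIER: [name],
                    dialect.LOCUS_TAG_QUALIFIER: [gene.gene_id],
                    dialect.DOMAIN_ID_QUALIFIER: [domain_id],
                }
                entries = dom.specificity_entries()
                if entries:
                    dom_quals[dialect.SPECIFICITY_QUALIFIER] = entries
                features.append(
                    SeqFeature(
                        FeatureLocation(d_start, d_end, strand=gene.strand),
                        type=dialect.DOMAIN_FEATURE,
                        qualifiers=dom_quals,
                    )
                )
                flat_index += 1
        if spec.emit_module_features:
            for gi, ids in enumerate(group_ids):
                if not ids:
                    continue
                features.append(
                    SeqFeature(
                        FeatureLocation(start, end, strand=gene.strand),
                        type=dialect.MODULE_FEATURE,
                        qualifiers={
                            dialect.MODULE_DOMAINS_QUALIFIER: ids,
                            dialect.LOCUS_TAG_QUALIFIER: [gene.gene_id],
                            dialect.MODULE_TYPE_QUALIFIER: ["synthetic"],
                        },
                    )
                )

    record = SeqRecord(
        Seq("a" * total),
        id=spec.cluster_id,
        name=spec.cluster_id[:16],
        description=f"synthetic region {spec.cluster_id}",
        features=features,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["date"] = "01-JAN-2000"  # fixed for byte determinism
    record.annotations["data_file_division"] = "BCT"
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# randomized specs with known expected module structure
# ---------------------------------------------------------------------------

TOY_NRPS_SUBSTRATES = ["gly", "ala", "ser", "thr", "lys", "tyr"]
TOY_PKS_SUBSTRATES = ["mal", "mmal"]


def random_spec(seed: int) -> tuple[SyntheticBGCSpec, dict]:
    """Generate a random but structurally legal cluster spec.

    Returns the spec plus the expected assembly outcome (load descriptor,
    per-module extension/bridging flags, terminator kind), derived from the
    generative grammar itself so round-trip tests have an oracle.
    """
    rng = random.Random(seed)
    classes = rng.choice(
        [["NRPS"], ["T1PKS"], ["transAT-PKS"], ["NRPS", "T1PKS"]]
    )
    is_transat = "transAT-PKS" in classes
    is_hybrid = len(classes) > 1

    modules: list[list[DomainSpec]] = []  # groups in final cluster order
    expected_extending: list[bool] = []
    expected_bridging: list[bool] = []
    split_after_ks: set[int] = set()  # module indices to split across genes

    def nrps_substrate():
        return rng.choice(TOY_NRPS_SUBSTRATES + ["X"])

    def pks_substrate():
        return rng.choice(TOY_PKS_SUBSTRATES + [""])

    # --- load module ---
    if "NRPS" in classes and (not is_hybrid or rng.random() < 0.5):
        # pure-NRPS clusters always get a load module: an initiating module
        # with a C domain is by definition the acylated load variant
        kind = rng.choice(["standard_NRPS", "C_acylated_NRPS"])
        if kind == "standard_NRPS":
            modules.append([
                DomainSpec(DomainKind.A, substrate=nrps_substrate()),
                DomainSpec(DomainKind.PCP),
            ])
        elif kind == "C_acylated_NRPS":
            modules.append([
                DomainSpec(DomainKind.C),
                DomainSpec(DomainKind.A, substrate=nrps_substrate()),
                DomainSpec(DomainKind.PCP),
            ])
        load_descriptor = kind
    else:
        kind = rng.choice(["standard_PKS", "GNAT", "FkbH", "none"])
        if kind == "standard_PKS":
            modules.append([
                DomainSpec(DomainKind.AT, substrate=pks_substrate()),
                DomainSpec(DomainKind.ACP),
            ])
        elif kind == "GNAT":
            modules.append([DomainSpec(DomainKind.GNAT), DomainSpec(DomainKind.ACP)])
        elif kind == "FkbH":
            modules.append([DomainSpec(DomainKind.FKBH), DomainSpec(DomainKind.ACP)])
        load_descriptor = kind
    if load_descriptor != "none":
        expected_extending.append(False)
        expected_bridging.append(False)

    # --- extender modules ---
    n_ext = rng.randint(1, 4)
    for ext_i in range(n_ext):
        # with no load module the first module must carry PKS chemistry,
        # otherwise its C domain would reclassify it as an acylated load
        force_pks = load_descriptor == "none" and ext_i == 0
        if (
            "NRPS" in classes
            and not force_pks
            and (not is_hybrid or rng.random() < 0.5)
        ):
            group = [
                DomainSpec(rng.choice([DomainKind.C, DomainKind.CY])),
                DomainSpec(DomainKind.A, substrate=nrps_substrate()),
            ]
            if rng.random() < 0.3:
                group.append(DomainSpec(rng.choice([DomainKind.NMT, DomainKind.CMT])))
            if rng.random() < 0.2:
                group.append(DomainSpec(DomainKind.E))
            group.append(DomainSpec(DomainKind.PCP))
            modules.append(group)
            expected_extending.append(True)
            expected_bridging.append(False)
        else:
            variant = rng.random()
            if force_pks and variant < 0.15:
                variant = 0.5  # the chain-starting module must stay active
            group = [DomainSpec(DomainKind.KS)]
            if not is_transat:
                group.append(DomainSpec(DomainKind.AT, substrate=pks_substrate()))
            active = True
            bridging = False
            if variant < 0.15:
                group.append(DomainSpec(DomainKind.OMT))  # deactivates the module
                active = False
            else:
                kr_activity = rng.choice(["active", "inactive", None])
                if rng.random() < 0.7:
                    group.append(DomainSpec(DomainKind.KR, activity=kr_activity))
                    if rng.random() < 0.5:
                        group.append(DomainSpec(DomainKind.DH))
                        if rng.random() < 0.5:
                            group.append(DomainSpec(DomainKind.ER))
                if rng.random() < 0.2:
                    group.append(DomainSpec(DomainKind.CMT))
            group.append(DomainSpec(DomainKind.ACP))
            if is_transat and variant >= 0.15 and not force_pks and rng.random() < 0.35:
                # split across a gene boundary after the KS domain
                head = [d for d in group[1:]]
                if rng.random() < 0.5:
                    # DHD arrangement: DH immediately followed by ACP -> inactive
                    head = [DomainSpec(DomainKind.DH), DomainSpec(DomainKind.ACP)]
                    group = [DomainSpec(DomainKind.KS)] + head
                    active = False
                else:
                    head = [DomainSpec(DomainKind.KR, activity="active"),
                            DomainSpec(DomainKind.ACP)]
                    group = [DomainSpec(DomainKind.KS)] + head
                    active = True
                bridging = True
                split_after_ks.add(len(modules))
            modules.append(group)
            expected_extending.append(active)
            expected_bridging.append(bridging)

    # --- terminator on the last module ---
    terminator = rng.choice([DomainKind.TE, DomainKind.TD])
    modules[-1].append(DomainSpec(terminator))

    # --- distribute groups over genes ---
    genes: list[GeneSpec] = []
    current: list[list[DomainSpec]] = []
    gene_count = 0

    def flush():
        nonlocal gene_count, current
        if current:
            gene_count += 1
            strand = -1 if rng.random() < 0.2 else 1
            genes.append(
                GeneSpec(gene_id=f"g{gene_count}", strand=strand, modules=current)
            )
            current = []

    for i, group in enumerate(modules):
        if i in split_after_ks:
            # tail of previous gene carries the KS; head opens the next gene
            current.append([group[0]])
            flush()
            genes[-1].strand = 1  # bridging halves stay on plus strand
            current = [group[1:]]
        else:
            current.append(group)
        if i not in split_after_ks and rng.random() < 0.3:
            flush()
    flush()

    # occasionally a trailing free-standing epimerase gene (non-modular)
    n_free = 1 if rng.random() < 0.3 else 0
    if n_free:
        genes.append(
            GeneSpec(gene_id=f"g{len(genes) + 1}",
                     modules=[[DomainSpec(DomainKind.E)]])
        )

    spec = SyntheticBGCSpec(
        cluster_id=f"bgc{seed}",
        classes=classes,
        genes=genes,
        seed=seed,
    )
    expected_extending = [e for e in expected_extending if e is not None]
    expected_bridging = [b for b in expected_bridging if b is not None]
    all_subs = [
        d.substrate for g in genes for grp in g.modules for d in grp
        if d.substrate not in (None,)
    ]
    producible_codes = set(TOY_NRPS_SUBSTRATES + TOY_PKS_SUBSTRATES + ["X", ""])
    expectation = {
        "classes": sorted(classes),
        "load_descriptor": load_descriptor,
        "n_modules": len(expected_extending),
        "extending": expected_extending,
        "bridging": expected_bridging,
        "n_active_extenders": sum(expected_extending),
        "terminator": terminator.value,
        "n_free_domains": n_free,
        "toy_producible": all(s in producible_codes for s in all_subs),
        "domain_kinds": [
            [d.kind for grp in g.modules for d in grp] for g in genes
        ],
    }
    return spec, expectation


def fig_style_bridging_spec() -> SyntheticBGCSpec:
    """Three-gene trans-AT toy: a cross-gene active bridging module plus a
    terminal module deactivated by its oMT domain."""
    return SyntheticBGCSpec(
        cluster_id="bridgetoy",
        classes=["transAT-PKS"],
        genes=[
            GeneSpec("geneA", modules=[
                [DomainSpec(DomainKind.GNAT), DomainSpec(DomainKind.ACP)],
                [DomainSpec(DomainKind.KS), DomainSpec(DomainKind.ACP)],
                [DomainSpec(DomainKind.KS)],  # bridge tail
            ]),
            GeneSpec("geneB", modules=[
                [DomainSpec(DomainKind.KR, activity="active"),
                 DomainSpec(DomainKind.ACP)],  # bridge head
                [DomainSpec(DomainKind.KS), DomainSpec(DomainKind.DH),
                 DomainSpec(DomainKind.KR, activity="active"),
                 DomainSpec(DomainKind.ACP)],
            ]),
            GeneSpec("geneC", modules=[
                [DomainSpec(DomainKind.KS), DomainSpec(DomainKind.OMT),
                 DomainSpec(DomainKind.ACP), DomainSpec(DomainKind.TE)],
            ]),
        ],
    )


# ---------------------------------------------------------------------------
# toy reference model
# ---------------------------------------------------------------------------

def build_toy_reference_model() -> cobra.Model:
    """Desk-scale reference model with hand-computable rational optima.

    Single cytosolic compartment; lumped glycolysis, pyruvate oxidation, TCA
    and oxidative phosphorylation with small-rational stoichiometry; six
    amino acids; malonyl- and methylmalonyl-CoA; a SAM/SAH cycle; a fatty
    acyl-CoA pool; and an NDP-hexose glycosyl donor.

    Biomass assembly co-produces one unit of a by-product (``byp``) that
    must be detoxified before secretion.  Two routes exist:

    * ``BYPT`` (no gene): condensation with a glycolytic side-product
      (``glx``, spilled at 1/4 per glucose), effectively free but capacity-
      coupled to glycolytic flux;
    * ``BYPD`` (gene ``g_byp``): an acetyl-CoA-consuming drain that handles
      the excess and therefore competes with precursor supply.

    At the wild-type optimum the free route saturates and ``BYPD`` carries
    the excess; knocking out ``g_byp`` caps growth at the ``glx``-coupled
    capacity, leaving a large glucose surplus for product synthesis — the
    engineered, hand-computable knockout target.  Because the coupling is
    stoichiometric (not a fixed flux bound), the model stays homogeneous:
    doubling the glucose limit doubles maximum growth, and the all-zero
    flux vector remains feasible on empty media.
    """
    model = cobra.Model("toy_reference")

    mets = {}
    for mid, name in [
        ("glc__D", "D-glucose"), ("nh4", "ammonium"), ("pi", "phosphate"),
        ("so4", "sulphate"), ("o2", "oxygen"), ("co2", "carbon dioxide"),
        ("h2o", "water"), ("h", "proton"), ("atp", "ATP"), ("adp", "ADP"),
        ("amp", "AMP"), ("ppi", "diphosphate"), ("nad", "NAD+"),
        ("nadh", "NADH"), ("nadp", "NADP+"), ("nadph", "NADPH"),
        ("pyr", "pyruvate"), ("accoa", "acetyl-CoA"), ("coa", "coenzyme A"),
        ("malcoa", "malonyl-CoA"), ("mmcoa__R", "(R)-methylmalonyl-CoA"),
        ("amet", "S-adenosyl-L-methionine"), ("ahcys", "S-adenosyl-L-homocysteine"),
        ("ala__L", "L-alanine"), ("gly", "glycine"), ("ser__L", "L-serine"),
        ("thr__L", "L-threonine"), ("lys__L", "L-lysine"), ("tyr__L", "L-tyrosine"),
        ("fa_coa", "fatty acyl-CoA pool"), ("ndphex", "NDP-hexose"),
        ("ndp", "nucleoside diphosphate"), ("byp", "by-product"),
        ("glx", "glycolytic side-product (lumped)"),
        ("dbyp", "detoxified by-product"),
        ("13dpg", "1,3-bisphosphoglycerate"),
    ]:
        mets[mid] = cobra.Metabolite(f"{mid}_c", name=name, compartment="c")
    model.add_metabolites(list(mets.values()))

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, gene=None):
        r = cobra.Reaction(rid, name=name)
        r.lower_bound, r.upper_bound = lb, ub
        model.add_reactions([r])
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        if gene:
            r.gene_reaction_rule = gene
        return r

    # exchanges (uptake = negative flux; bounds set by the medium)
    for mid in ["glc__D", "nh4", "pi", "so4", "o2", "h2o", "h"]:
        rxn(f"EX_{mid}_c", f"{mid} exchange", {mid: -1}, lb=-1000.0)
    rxn("EX_co2_c", "co2 exchange", {"co2": -1}, lb=0.0)
    rxn("EX_dbyp_c", "detoxified by-product exchange", {"dbyp": -1}, lb=0.0)
    rxn("EX_glx_c", "glycolytic side-product exchange", {"glx": -1}, lb=0.0)
    rxn("SK_ndp_c", "spent-NDP sink", {"ndp": -1}, lb=0.0)

    rxn("GLYC", "glycolysis (lumped)",
        {"glc__D": -1, "adp": -2, "pi": -2, "nad": -2,
         "pyr": 2, "atp": 2, "nadh": 2, "h2o": 2, "glx": 0.25}, gene="g_glyc")
    rxn("PDH", "pyruvate dehydrogenase",
        {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1})
    rxn("TCA", "TCA cycle (lumped)",
        {"accoa": -1, "nad": -3, "adp": -1, "pi": -1,
         "co2": 2, "coa": 1, "nadh": 3, "atp": 1})
    rxn("OXPHOS", "oxidative phosphorylation (lumped, P/O=2)",
        {"nadh": -2, "o2": -1, "adp": -4, "pi": -4,
         "nad": 2, "atp": 4, "h2o": 2})
    rxn("THD", "transhydrogenase", {"nadh": -1, "nadp": -1, "nad": 1, "nadph": 1},
        lb=-1000.0)
    rxn("ACCOAC", "acetyl-CoA carboxylase",
        {"accoa": -1, "co2": -1, "atp": -1, "malcoa": 1, "adp": 1, "pi": 1},
        gene="g_accC")
    rxn("MMSYN", "methylmalonyl-CoA synthesis (lumped)",
        {"accoa": -1, "co2": -1, "atp": -1, "nadph": -1,
         "mmcoa__R": 1, "adp": 1, "pi": 1, "nadp": 1}, gene="g_mm")
    rxn("ALAS", "alanine synthesis (lumped)",
        {"pyr": -1, "nh4": -1, "nadph": -1, "ala__L": 1, "nadp": 1, "h2o": 1},
        gene="g_ala")
    rxn("GLYS", "glycine synthesis (lumped)",
        {"pyr": -1, "nh4": -1, "nad": -1, "gly": 1, "co2": 1, "nadh": 1, "h2o": 1},
        gene="g_gly")
    rxn("SERS", "serine synthesis (lumped)",
        {"pyr": -1, "nh4": -1, "h2o": -1, "ser__L": 1}, gene="g_ser")
    rxn("THRS", "threonine synthesis (lumped)",
        {"pyr": -1, "co2": -1, "nh4": -1, "nadph": -2, "atp": -1,
         "thr__L": 1, "nadp": 2, "adp": 1, "pi": 1}, gene="g_thr")
    rxn("LYSS", "lysine synthesis (lumped)",
        {"pyr": -2, "nh4": -2, "nadph": -2,
         "lys__L": 1, "co2": 1, "nadp": 2, "h2o": 2}, gene="g_lys")
    rxn("TYRS", "tyrosine synthesis (lumped)",
        {"pyr": -3, "nh4": -1, "nadph": -1,
         "tyr__L": 1, "co2": 2, "nadp": 1, "h2o": 2}, gene="g_tyr")
    rxn("SAMR", "SAM regeneration from SAH (lumped)",
        {"ahcys": -1, "atp": -1, "nadph": -1,
         "amet": 1, "adp": 1, "pi": 1, "nadp": 1}, gene="g_sam")
    rxn("FAS", "fatty acyl-CoA synthesis (lumped)",
        {"accoa": -1, "malcoa": -3, "nadph": -6,
         "fa_coa": 1, "coa": 3, "co2": 3, "nadp": 6, "h2o": 2}, gene="g_fas")
    rxn("NDPHEXS", "NDP-hexose synthesis (lumped)",
        {"glc__D": -1, "atp": -2, "ndphex": 1, "adp": 2, "pi": 1}, gene="g_ndp")
    rxn("ADK", "adenylate kinase", {"amp": -1, "atp": -1, "adp": 2}, lb=-1000.0)
    rxn("PPA", "inorganic pyrophosphatase", {"ppi": -1, "h2o": -1, "pi": 2})
    rxn("BPGS", "1,3-bisphosphoglycerate supply (lumped)",
        {"pyr": -1, "atp": -2, "13dpg": 1, "adp": 2}, gene="g_bpg")
    rxn("ATPM", "ATP dissipation (non-forced maintenance)",
        {"atp": -1, "h2o": -1, "adp": 1, "pi": 1})
    rxn("BYPT", "by-product detoxification (side-product condensation)",
        {"byp": -1, "glx": -1, "dbyp": 1})
    rxn("BYPD", "by-product drain (acetyl-CoA detoxification)",
        {"byp": -1, "accoa": -1, "dbyp": 1, "coa": 1}, gene="g_byp")
    biomass = rxn(
        "BIOMASS_TOY", "biomass (toy)",
        {"ala__L": -1, "gly": -1, "ser__L": -1, "thr__L": -1, "so4": -1,
         "atp": -40, "h2o": -40, "adp": 40, "pi": 40, "byp": 1},
    )
    model.objective = biomass
    return model


def toy_medium() -> MediumSpec:
    """Glucose/ammonium minimal medium for the toy model (glucose 0.8)."""
    return MediumSpec(
        uptake_limits={"EX_glc__D_c": 0.8},
        unconstrained={
            "EX_nh4_c", "EX_pi_c", "EX_so4_c", "EX_o2_c", "EX_h2o_c", "EX_h_c"
        },
    )


def write_toy_model_sbml(path: str) -> None:
    model = build_toy_reference_model()
    from .analysis import set_medium

    set_medium(model, toy_medium())
    cobra.io.write_sbml_model(model, str(path))
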