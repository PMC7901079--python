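"""Canonical metabolite vocabulary, extender-unit tables and rare-monomer
subpathways.

Metabolite ids follow BiGG-style base ids (compartment suffix added when a
reconstruction is inserted into a model).  The reference model acts purely as
a library: ids are resolved against it by exact match or the synonym table,
and anything unresolved becomes a new metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MetaboliteRef:
    met_id: str
    name: str
    compartment: str = "c"
    role: str = "cofactor"  # extender|cofactor|chain_intermediate|starter|final_product|precursor


def ref(met_id: str, name: str | None = None, role: str = "cofactor") -> MetaboliteRef:
    return MetaboliteRef(met_id=met_id, name=name or met_id, role=role)


# --- cofactors and common currency metabolites --------------------------------
ATP = ref("atp", "ATP")
ADP = ref("adp", "ADP")
AMP = ref("amp", "AMP")
PPI = ref("ppi", "diphosphate")
PI = ref("pi", "phosphate")
H2O = ref("h2o", "water")
H = ref("h", "proton")
CO2 = ref("co2", "carbon dioxide")
NH4 = ref("nh4", "ammonium")
O2 = ref("o2", "oxygen")
NAD = ref("nad", "NAD+")
NADH = ref("nadh", "NADH")
NADP = ref("nadp", "NADP+")
NADPH = ref("nadph", "NADPH")
COA = ref("coa", "coenzyme A")
SAM = ref("amet", "S-adenosyl-L-methionine")
SAH = ref("ahcys", "S-adenosyl-L-homocysteine")
ACCOA = ref("accoa", "acetyl-CoA")
BPG13 = ref("13dpg", "1,3-bisphosphoglycerate")
NDP_HEXOSE = ref("ndphex", "NDP-hexose (glycosyl donor)")
NDP = ref("ndp", "nucleoside diphosphate")
GLC = ref("glc__D", "D-glucose")
PYR = ref("pyr", "pyruvate")

# --- generic pseudo-monomers ---------------------------------------------------
GENERIC_AA = ref("generic_aa", "generic amino acid", role="extender")
GENERIC_FA = ref("generic_fa", "generic fatty acid (CoA-activated)", role="starter")
GENERIC_STARTER = ref("generic_starter", "generic starter unit", role="starter")
FA_POOL = ref("fa_coa", "fatty acyl-CoA pool", role="precursor")

# --- PKS extender units (acyl-CoA thioesters; mxmal is carrier-bound) ---------
MALCOA = ref("malcoa", "malonyl-CoA", role="extender")
MMCOA = ref("mmcoa__R", "(R)-methylmalonyl-CoA", role="extender")
EMCOA = ref("emcoa__S", "ethylmalonyl-CoA", role="extender")
MXMAL_ACP = ref("mxmal_acp", "methoxymalonyl-ACP", role="extender")

PKS_EXTENDER_CODES: dict[str, MetaboliteRef] = {
    "mal": MALCOA,
    "mmal": MMCOA,
    "emal": EMCOA,
    "mxmal": MXMAL_ACP,
}

# --- NRPS monomers -------------------------------------------------------------
PROTEINOGENIC_AA: dict[str, MetaboliteRef] = {
    code: ref(met, name, role="extender")
    for code, met, name in [
        ("ala", "ala__L", "L-alanine"),
        ("arg", "arg__L", "L-arginine"),
        ("asn", "asn__L", "L-asparagine"),
        ("asp", "asp__L", "L-aspartate"),
        ("cys", "cys__L", "L-cysteine"),
        ("gln", "gln__L", "L-glutamine"),
        ("glu", "glu__L", "L-glutamate"),
        ("gly", "gly", "glycine"),
        ("his", "his__L", "L-histidine"),
        ("ile", "ile__L", "L-isoleucine"),
        ("leu", "leu__L", "L-leucine"),
        ("lys", "lys__L", "L-lysine"),
        ("met", "met__L", "L-methionine"),
        ("phe", "phe__L", "L-phenylalanine"),
        ("pro", "pro__L", "L-proline"),
        ("ser", "ser__L", "L-serine"),
        ("thr", "thr__L", "L-threonine"),
        ("trp", "trp__L", "L-tryptophan"),
        ("tyr", "tyr__L", "L-tyrosine"),
        ("val", "val__L", "L-valine"),
    ]
}

RARE_AA: dict[str, MetaboliteRef] = {
    "hpg": ref("hpg", "4-hydroxyphenylglycine", role="extender"),
    "bht": ref("bht", "beta-hydroxytyrosine", role="extender"),
    "abu": ref("2abu", "2-aminobutyric acid", role="extender"),
    "pip": ref("pipecol", "pipecolic acid", role="extender"),
    "dhpg": ref("dhpg", "3,5-dihydroxyphenylglycine", role="extender"),
    "ahba": ref("ahba", "3-amino-5-hydroxybenzoate", role="extender"),
}

NRPS_MONOMER_CODES: dict[str, MetaboliteRef] = {**PROTEINOGENIC_AA, **RARE_AA}

#: non-specific placeholder codes emitted by the annotation tool
NONSPECIFIC_CODES = frozenset({"x", "nrp", "pk", "n/a", "none", "unknown", ""})

# --- lumped synthesis subpathways for rare monomers ---------------------------
# Stoichiometries are documented lumped forms from common precursors; the
# exact enzymology varies per cluster and is not resolved here.
RARE_PRECURSOR_PATHWAYS: dict[str, list[tuple[str, str, dict[MetaboliteRef, float]]]] = {
    "hpg": [(
        "hpg_synth",
        "4-hydroxyphenylglycine synthesis (lumped from L-tyrosine)",
        {PROTEINOGENIC_AA["tyr"]: -1, NAD: -2, H2O: -1,
         RARE_AA["hpg"]: 1, NADH: 2, CO2: 1, H: 2},
    )],
    "bht": [(
        "bht_synth",
        "beta-hydroxytyrosine synthesis (lumped hydroxylation of L-tyrosine)",
        {PROTEINOGENIC_AA["tyr"]: -1, O2: -1, NADPH: -1, H: -1,
         RARE_AA["bht"]: 1, H2O: 1, NADP: 1},
    )],
    "abu": [(
        "abu_synth",
        "2-aminobutyrate synthesis (lumped from L-threonine)",
        {PROTEINOGENIC_AA["thr"]: -1, NADPH: -1, H: -1,
         RARE_AA["abu"]: 1, H2O: 1, NADP: 1},
    )],
    "pip": [(
        "pip_synth",
        "pipecolate synthesis (lumped lysine cyclodeamination)",
        {PROTEINOGENIC_AA["lys"]: -1, RARE_AA["pip"]: 1, NH4: 1},
    )],
    "dhpg": [(
        "dhpg_synth",
        "3,5-dihydroxyphenylglycine synthesis (lumped from L-tyrosine)",
        {PROTEINOGENIC_AA["tyr"]: -1, O2: -1,
         RARE_AA["dhpg"]: 1, CO2: 1, H2O: 1},
    )],
    "ahba": [(
        "ahba_synth",
        "3-amino-5-hydroxybenzoate synthesis (lumped aminoshikimate route)",
        {GLC: -1, PYR: -1, NH4: -1, ATP: -1,
         RARE_AA["ahba"]: 1, CO2: 2, ADP: 1, PI: 1, H2O: 2},
    )],
}

#: smCOG code whose presence in the cluster gates the methoxymalonyl-ACP route
MXMAL_GATING_SMCOG = "1256"

#: smCOG codes that trigger post-release tailoring reactions
TAILORING_SMCOGS = frozenset({"1256", "1084", "1002", "1109", "1062"})
GLYCOSYLATION_SMCOGS = frozenset({"1062", "1256", "1084"})
C5N_SMCOG = "1109"
LIGASE_SMCOG = "1002"

# --- synonym table for resolving canonical ids against a reference model ------
# canonical base id -> alternative base ids seen in published models
SYNONYMS: dict[str, list[str]] = {
    "mmcoa__R": ["mmcoa_R", "mmcoa"],
    "emcoa__S": ["emcoa_S", "emcoa"],
    "amet": ["sam", "SAM"],
    "ahcys": ["sah", "SAH"],
    "glc__D": ["glc_D", "glc"],
    "13dpg": ["_13dpg", "bpg13"],
    "gly": ["gly__L"],
}
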