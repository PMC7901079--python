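"""Shared antiSMASH-5 region-GenBank feature vocabulary.

Both the parser (:mod:`bgcflux.ingest`) and the synthetic-region writer
(:mod:`bgcflux.fixtures`) consume this single table so the two cannot drift
apart.  Only the features the pipeline actually reads are described; full
antiSMASH records carry many more.
"""

from __future__ import annotations

from .records import ClusterClass, DomainKind

REGION_FEATURE = "region"
CDS_FEATURE = "CDS"
DOMAIN_FEATURE = "aSDomain"
MODULE_FEATURE = "aSModule"

#: qualifier on the region feature naming the predicted product classes
PRODUCT_QUALIFIER = "product"
#: qualifier marking core biosynthetic genes
GENE_KIND_QUALIFIER = "gene_kind"
CORE_GENE_KIND = "biosynthetic"
#: free-text qualifier carrying smCOG assignments
GENE_FUNCTIONS_QUALIFIER = "gene_functions"
LOCUS_TAG_QUALIFIER = "locus_tag"
DOMAIN_ID_QUALIFIER = "domain_id"
SPECIFICITY_QUALIFIER = "specificity"
ASDOMAIN_NAME_QUALIFIER = "aSDomain"
MODULE_DOMAINS_QUALIFIER = "domains"
MODULE_TYPE_QUALIFIER = "type"

#: canonical aSDomain name emitted by the fixture writer for each kind
KIND_TO_ASDOMAIN: dict[DomainKind, str] = {
    DomainKind.A: "AMP-binding",
    DomainKind.ACP: "ACP",
    DomainKind.AT: "PKS_AT",
    DomainKind.C: "Condensation",
    DomainKind.CAL: "CAL_domain",
    DomainKind.CMT: "cMT",
    DomainKind.CY: "Heterocyclization",
    DomainKind.DH: "PKS_DH",
    DomainKind.E: "Epimerization",
    DomainKind.ECH: "ECH",
    DomainKind.ER: "PKS_ER",
    DomainKind.FKBH: "FkbH",
    DomainKind.GNAT: "GNAT",
    DomainKind.KR: "PKS_KR",
    DomainKind.KS: "PKS_KS",
    DomainKind.NMT: "nMT",
    DomainKind.OMT: "oMT",
    DomainKind.PCP: "PCP",
    DomainKind.TD: "Thioester-redct",
    DomainKind.TE: "Thioesterase",
}

#: parser-side aliases: every name antiSMASH 5.x dialects may use
ASDOMAIN_TO_KIND: dict[str, DomainKind] = {
    **{v: k for k, v in KIND_TO_ASDOMAIN.items()},
    "A-OX": DomainKind.A,
    "PP-binding": DomainKind.ACP,
    "ACP_beta": DomainKind.ACP,
    "Condensation_LCL": DomainKind.C,
    "Condensation_DCL": DomainKind.C,
    "Condensation_Starter": DomainKind.C,
    "Condensation_Dual": DomainKind.C,
    "Cglyc": DomainKind.C,
    "MT": DomainKind.CMT,
    "PKS_DH2": DomainKind.DH,
    "PKS_DHt": DomainKind.DH,
    "TD": DomainKind.TD,
}

#: region product labels handled by the pipeline
PRODUCT_TO_CLASS: dict[str, ClusterClass] = {
    "NRPS": ClusterClass.NRPS,
    "T1PKS": ClusterClass.T1PKS,
    "transAT-PKS": ClusterClass.TRANSAT_PKS,
}

#: prefix of the specificity entry carrying KR activity calls
KR_ACTIVITY_PREFIX = "KR activity:"
#: prefix of the specificity entry carrying the substrate consensus code
CONSENSUS_PREFIX = "consensus:"
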