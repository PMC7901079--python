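"""Parse antiSMASH region GenBank files into :class:`ClusterRecord` objects."""

from __future__ import annotations

import io
import json
from dataclasses import asdict

from Bio import SeqIO
from Bio.SeqFeature import SeqFeature

from . import dialect
from .records import (
    Activity,
    ClusterClass,
    ClusterRecord,
    DomainKind,
    DomainRecord,
    GeneRecord,
    ModuleRecord,
    SUPPORTED_CLASSES,
    parse_smcog,
)


class ParseError(ValueError):
    """The GenBank document could not be interpreted."""


class EmptyClusterError(ParseError):
    """The region contains no CDS features."""


class UnsupportedClusterClassError(ValueError):
    """The region's product classes are all outside NRPS/T1PKS/trans-AT PKS."""

    def __init__(self, classes: set[ClusterClass]):
        self.classes = classes
        super().__init__(
            "cluster class(es) not handled by the pipeline: "
            + ", ".join(sorted(c.value for c in classes))
        )


def _qualifier(feature: SeqFeature, key: str) -> list[str]:
    return list(feature.qualifiers.get(key, []))


def _first_qualifier(feature: SeqFeature, key: str) -> str | None:
    vals = _qualifier(feature, key)
    return vals[0] if vals else None


def _activity_from_specificity(spec_entries: list[str]) -> Activity:
    for entry in spec_entries:
        entry = entry.strip()
        for prefix in (dialect.KR_ACTIVITY_PREFIX, "activity:"):
            if entry.startswith(prefix):
                value = entry[len(prefix):].strip().lower()
                if value == "active":
                    return Activity.ACTIVE
                if value == "inactive":
                    return Activity.INACTIVE
    return Activity.UNKNOWN


def parse_region(genbank_text: str, strict: bool = False) -> ClusterRecord:
    """Parse one antiSMASH region document into a cluster record.

    Biopython performs the GenBank parse proper (its locations are already
    0-based half-open).  Unknown domain names become ``UNKNOWN`` kinds and are
    reported, never dropped; in ``strict`` mode they raise instead.
    """
    try:
        seqrec = SeqIO.read(io.StringIO(genbank_text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError
        raise ParseError(f"malformed GenBank document: {exc}") from exc

    report: list[str] = []
    classes: set[ClusterClass] = set()
    for feat in seqrec.features:
        if feat.type == dialect.REGION_FEATURE:
            for product in _qualifier(feat, dialect.PRODUCT_QUALIFIER):
                cls = dialect.PRODUCT_TO_CLASS.get(product)
                if cls is None:
                    classes.add(ClusterClass.OTHER)
                    report.append(f"unsupported region product label: {product}")
                else:
                    classes.add(cls)
    if not classes:
        classes = {ClusterClass.OTHER}
        report.append("no region feature with product labels; class unknown")

    genes: list[GeneRecord] = []
    for feat in seqrec.features:
        if feat.type != dialect.CDS_FEATURE:
            continue
        gene_id = (
            _first_qualifier(feat, dialect.LOCUS_TAG_QUALIFIER)
            or _first_qualifier(feat, "gene")
            or f"cds_{int(feat.location.start)}"
        )
        smcog = None
        for text in _qualifier(feat, dialect.GENE_FUNCTIONS_QUALIFIER):
            smcog = smcog or parse_smcog(text)
        is_core = (
            _first_qualifier(feat, dialect.GENE_KIND_QUALIFIER)
            == dialect.CORE_GENE_KIND
        )
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                span=(int(feat.location.start), int(feat.location.end)),
                strand=feat.location.strand or 1,
                is_core=is_core,
                smcog_id=smcog,
            )
        )
    if not genes:
        raise EmptyClusterError("region contains no CDS features")
    genes.sort(key=lambda g: g.span[0])
    by_id = {g.gene_id: g for g in genes}

    domains_by_id: dict[str, DomainRecord] = {}
    for feat in seqrec.features:
        if feat.type != dialect.DOMAIN_FEATURE:
            continue
        name = _first_qualifier(feat, dialect.ASDOMAIN_NAME_QUALIFIER) or ""
        kind = dialect.ASDOMAIN_TO_KIND.get(name)
        if kind is None:
            if strict:
                raise ParseError(f"unknown domain name {name!r}")
            kind = DomainKind.UNKNOWN
            report.append(f"unknown domain name {name!r} kept as UNKNOWN")
        start, end = int(feat.location.start), int(feat.location.end)
        gene_id = _first_qualifier(feat, dialect.LOCUS_TAG_QUALIFIER)
        gene = by_id.get(gene_id) if gene_id else None
        if gene is None:  # fall back to coordinate containment
            for g in genes:
                if g.span[0] <= start and end <= g.span[1]:
                    gene = g
                    break
        if gene is None:
            report.append(f"domain {name!r} at {start}..{end} matches no CDS; dropped into report")
            continue
        spec_entries = _qualifier(feat, dialect.SPECIFICITY_QUALIFIER)
        dom = DomainRecord(
            kind=kind,
            gene_id=gene.gene_id,
            span=(start, end),
            strand=feat.location.strand or gene.strand,
            order_index=0,  # assigned after sorting
            specificity=spec_entries,
            activity=_activity_from_specificity(spec_entries),
            domain_id=_first_qualifier(feat, dialect.DOMAIN_ID_QUALIFIER) or "",
            raw_qualifiers={k: list(v) for k, v in feat.qualifiers.items()},
        )
        gene.domains.append(dom)
        if dom.domain_id:
            domains_by_id[dom.domain_id] = dom

    # translation order: genomic order on +, reversed genomic order on -
    for gene in genes:
        gene.domains.sort(key=lambda d: d.span[0], reverse=(gene.strand == -1))
        for i, dom in enumerate(gene.domains):
            dom.order_index = i

    annotated_modules: list[ModuleRecord] = []
    for feat in seqrec.features:
        if feat.type != dialect.MODULE_FEATURE:
            continue
        ids = _qualifier(feat, dialect.MODULE_DOMAINS_QUALIFIER)
        mod_domains = [domains_by_id[i] for i in ids if i in domains_by_id]
        missing = [i for i in ids if i not in domains_by_id]
        if missing:
            report.append(f"module references unknown domain ids: {missing}")
        if mod_domains:
            annotated_modules.append(
                ModuleRecord(domains=mod_domains, provenance="annotated")
            )

    cluster = ClusterRecord(
        cluster_id=seqrec.id or seqrec.name or "region",
        classes=classes,
        genes=genes,
        annotated_modules=annotated_modules,
        parse_report=report,
    )
    return cluster


def classify_cluster(cluster: ClusterRecord) -> set[ClusterClass]:
    """Return the supported class labels of a cluster.

    Raises :class:`UnsupportedClusterClassError` when none of the region's
    labels are handled, so callers can decide to skip or abort.
    """
    supported = cluster.classes & SUPPORTED_CLASSES
    if not supported:
        raise UnsupportedClusterClassError(cluster.classes)
    return supported


def cluster_to_json(cluster: ClusterRecord) -> str:
    """Serialize a cluster record to JSON for inspection."""

    def default(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(v.value if hasattr(v, "value") else v for v in obj)
        if hasattr(obj, "value"):
            return obj.value
        raise TypeError(type(obj))

    payload = {
        "cluster_id": cluster.cluster_id,
        "classes": sorted(c.value for c in cluster.classes),
        "genes": [asdict(g) for g in cluster.genes],
        "parse_report": cluster.parse_report,
    }
    return json.dumps(payload, indent=2, default=default)
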