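"""Core in-memory records for annotated biosynthetic gene clusters.

A cluster record holds genes, their functional domains and (optionally) the
module grouping reported by the annotation tool.  Coordinates are 0-based
half-open in cluster (region) coordinates; GenBank's 1-based inclusive
convention is converted at the I/O boundary.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


class DomainKind(str, enum.Enum):
    """Functional domain categories of NRPS / PKS assembly lines."""

    A = "A"            # adenylation: selects and activates an amino acid
    ACP = "ACP"        # acyl carrier protein
    AT = "AT"          # acyltransferase: loads the acyl extender unit
    C = "C"            # condensation: peptide-bond formation
    CAL = "CAL"        # CoA ligase: alternative starter incorporation
    CMT = "cMT"        # C-methyltransferase
    CY = "Cy"          # heterocyclization (condensation + cyclization)
    DH = "DH"          # dehydratase
    E = "E"            # epimerase
    ECH = "ECH"        # enoyl-CoA hydratase / isomerase
    ER = "ER"          # enoylreductase
    FKBH = "FkbH"      # FkbH-like glyceryl transferase (alt. load)
    GNAT = "GNAT"      # GCN5-related N-acetyltransferase (alt. load)
    KR = "KR"          # ketoreductase
    KS = "KS"          # ketosynthase: Claisen condensation
    NMT = "nMT"        # N-methyltransferase
    OMT = "oMT"        # O-methyltransferase
    PCP = "PCP"        # peptidyl carrier protein
    TD = "TD"          # thioester reductase (reductive release)
    TE = "TE"          # thioesterase (hydrolytic release)
    UNKNOWN = "UNKNOWN"


#: domains that carry the growing chain
CARRIER_KINDS = frozenset({DomainKind.ACP, DomainKind.PCP})
#: domains that catalyse chain elongation (condensation chemistry)
CONDENSATION_KINDS = frozenset({DomainKind.C, DomainKind.CY, DomainKind.KS})
#: domains that release the finished chain
RELEASE_KINDS = frozenset({DomainKind.TE, DomainKind.TD})
#: methyltransferase variants
MT_KINDS = frozenset({DomainKind.CMT, DomainKind.NMT, DomainKind.OMT})


class Activity(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNKNOWN = "unknown"


class ClusterClass(str, enum.Enum):
    NRPS = "NRPS"
    T1PKS = "T1PKS"
    TRANSAT_PKS = "transAT-PKS"
    OTHER = "other"


SUPPORTED_CLASSES = frozenset(
    {ClusterClass.NRPS, ClusterClass.T1PKS, ClusterClass.TRANSAT_PKS}
)

_SMCOG_RE = re.compile(r"SMCOG(\d{4})")


@dataclass
class DomainRecord:
    """One annotated functional domain on a gene."""

    kind: DomainKind
    gene_id: str
    span: tuple[int, int]
    strand: int
    order_index: int
    specificity: list[str] = field(default_factory=list)
    activity: Activity = Activity.UNKNOWN
    domain_id: str = ""
    raw_qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError(f"empty span {self.span} for domain {self.kind}")

    @property
    def substrate(self) -> str | None:
        """First substrate code from the specificity annotation, if any."""
        for s in self.specificity:
            s = s.strip()
            if s.lower().startswith("consensus:"):
                return s.split(":", 1)[1].strip()
        return None


@dataclass
class GeneRecord:
    """A CDS feature with its translation-ordered domains."""

    gene_id: str
    span: tuple[int, int]
    strand: int
    is_core: bool = False
    smcog_id: str | None = None
    domains: list[DomainRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.smcog_id is not None and not re.fullmatch(r"\d{4}", self.smcog_id):
            raise ValueError(f"smCOG id {self.smcog_id!r} is not a 4-digit code")


@dataclass
class ModuleRecord:
    """An ordered group of domains acting as one assembly-line step."""

    domains: list[DomainRecord]
    module_kind: str = "unknown"  # PKS | NRPS | hybrid | unknown
    provenance: str = "assembled"  # annotated | assembled
    is_load: bool = False
    is_extending: bool = False
    is_terminating: bool = False
    is_bridging: bool = False

    def has(self, *kinds: DomainKind) -> bool:
        present = {d.kind for d in self.domains}
        return any(k in present for k in kinds)

    def get(self, kind: DomainKind) -> DomainRecord | None:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None

    def gene_ids(self) -> list[str]:
        out: list[str] = []
        for d in self.domains:
            if d.gene_id not in out:
                out.append(d.gene_id)
        return out

    @property
    def spans_gene_boundary(self) -> bool:
        return len(self.gene_ids()) > 1


@dataclass
class ClusterRecord:
    """Parsed representation of one annotated BGC region."""

    cluster_id: str
    classes: set[ClusterClass]
    genes: list[GeneRecord]
    annotated_modules: list[ModuleRecord] = field(default_factory=list)
    parse_report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("cluster must carry at least one class label")

    def all_domains(self) -> list[DomainRecord]:
        """Domains in gene genomic order, translation order within genes."""
        out: list[DomainRecord] = []
        for g in self.genes:
            out.extend(g.domains)
        return out

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def parse_smcog(text: str) -> str | None:
    """Extract a 4-digit smCOG code from a free-text gene_functions entry."""
    m = _SMCOG_RE.search(text)
    return m.group(1) if m else None
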