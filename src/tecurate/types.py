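"""Shared domain types for the TE-model curation pipeline.

All coordinates held in memory are 0-based half-open; conversions from the
1-based inclusive file dialects happen inside the parsers only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_MODEL_CHARS = frozenset("ACGTN")

#: stages of the filtering cascade, in canonical order
CASCADE_STAGES = ("clustering", "copy_number", "exon_overlap", "tandem", "trna")

FAMILY_LABELS = (
    "LTR_Gypsy_like",
    "LINE_like",
    "LTR_unclassified",
    "nonLTR_unclassified",
    "SINE_candidate",
    "unclassified",
)

EVIDENCE_SOURCES = ("dfam", "interpro", "sprot", "known_te", "trna")


class StatusError(ValueError):
    """Raised on an illegal ConsensusModel status transition."""


@dataclass
class ConsensusModel:
    """A candidate interspersed-repeat consensus sequence.

    Status starts at ``candidate`` and may move exactly once, to either
    ``discarded`` (with a stage and reason) or ``accepted``.
    """

    model_id: str
    sequence: str
    source_genome: str = "unknown"
    status: str = "candidate"
    discard_stage: Optional[str] = None
    discard_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"model {self.model_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_MODEL_CHARS
        if bad:
            raise ValueError(
                f"model {self.model_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mark_discarded(self, stage: str, reason: str) -> None:
        if self.status != "candidate":
            raise StatusError(
                f"model {self.model_id!r}: cannot discard from status {self.status!r}"
            )
        self.status = "discarded"
        self.discard_stage = stage
        self.discard_reason = reason

    def mark_accepted(self) -> None:
        if self.status != "candidate":
            raise StatusError(
                f"model {self.model_id!r}: cannot accept from status {self.status!r}"
            )
        self.status = "accepted"


@dataclass
class AlignmentHit:
    """One pairwise local alignment record (model-model or model-genome).

    ``pct_identity`` is a fraction in [0, 1].  Subject coordinates are stored
    ascending; a minus-strand match is indicated by ``strand`` only.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    evalue: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: q_end <= q_start")
        if self.s_end <= self.s_start:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: s_end <= s_start")
        if not 0.0 <= self.pct_identity <= 1.0:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: identity {self.pct_identity} outside [0,1]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("negative evalue")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start


@dataclass
class ExonRecord:
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    exon_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon on {self.contig_id}: end <= start")


@dataclass
class DomainEvidence:
    """One protein/profile/tRNA evidence row attached to a model."""

    model_id: str
    source: str
    accession: str
    description: str
    m_start: int
    m_end: int
    evalue: float = 0.0
    te_related: bool = False
    family_label: Optional[str] = None
    frame: Optional[int] = None
    pseudo: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(
                f"evidence for {self.model_id!r}: unknown source {self.source!r}"
            )
        if self.m_end <= self.m_start:
            raise ValueError(f"evidence {self.accession!r}: m_end <= m_start")
        if self.frame is not None and self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"evidence {self.accession!r}: bad frame {self.frame}")

    @property
    def span(self) -> int:
        return self.m_end - self.m_start


@dataclass
class TandemRecord:
    model_id: str
    start: int
    end: int
    period: int
    copies: float

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period < 1")
        if self.copies < 2:
            raise ValueError("copies < 2")
        if self.end - self.start < 2 * self.period:
            raise ValueError(
                f"tandem on {self.model_id!r}: span {self.end - self.start} < 2 x period {self.period}"
            )


@dataclass
class CurationDecision:
    model_id: str
    verdict: str  # accepted | discarded
    stage: str
    reason: str = ""
    supporting_evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict not in ("accepted", "discarded"):
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.verdict == "accepted" and not self.supporting_evidence:
            raise ValueError(f"{self.model_id!r}: accepted without supporting evidence")
        if self.verdict == "discarded" and not self.reason:
            raise ValueError(f"{self.model_id!r}: discarded without a reason")


@dataclass
class TEClassification:
    model_id: str
    family: str
    basis: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LABELS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "unclassified" and not self.basis:
            raise ValueError(f"{self.model_id!r}: classified without basis")


@dataclass
class GenomeSummary:
    """Per-genome mobilome statistics (assembly length, merged TE coverage)."""

    genome_id: str
    assembly_length: int
    te_covered: int
    te_percent: float
    copy_count: int = 0
    main_family: str = "unclassified"

    def __post_init__(self) -> None:
        if not 0 <= self.te_covered <= self.assembly_length:
            raise ValueError(
                f"{self.genome_id}: covered {self.te_covered} outside "
                f"[0, {self.assembly_length}]"
            )
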