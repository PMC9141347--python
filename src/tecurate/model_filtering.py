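"""The interspersed-repeat filtering cascade.

Five stages applied in canonical order — redundancy clustering, copy-number
filter, exon-overlap filter, tandem-repeat filter, tRNA screening — with
full stage accounting.  Each discarded model carries exactly one
(stage, reason) pair, and the stage report satisfies flow conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .alignment_core import tandem_fraction
from .config import DEFAULT_CONFIG, PipelineConfig
from .evidence_curation import is_te_description
from .intervals import clip, total_length
from .types import (
    AlignmentHit,
    CASCADE_STAGES,
    ConsensusModel,
    DomainEvidence,
    TandemRecord,
)


@dataclass
class Cluster:
    representative_id: str
    member_ids: set[str]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative not among members")


@dataclass
class StageRow:
    stage: str
    n_in: int
    n_discarded: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_discarded


@dataclass
class StageReport:
    rows: list[StageRow] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_discarded: int) -> None:
        if self.rows and self.rows[-1].n_out != n_in:
            raise ValueError(
                f"stage {stage}: n_in {n_in} != previous n_out {self.rows[-1].n_out}"
            )
        if n_discarded > n_in:
            raise ValueError(f"stage {stage}: discarded {n_discarded} > in {n_in}")
        self.rows.append(StageRow(stage, n_in, n_discarded))

    @property
    def counts(self) -> list[int]:
        """The flow as [initial, after stage 1, after stage 2, ...]."""
        if not self.rows:
            return []
        return [self.rows[0].n_in] + [r.n_out for r in self.rows]

    def to_tsv(self) -> str:
        lines = ["stage\tn_in\tn_discarded\tn_out"]
        for r in self.rows:
            lines.append(f"{r.stage}\t{r.n_in}\t{r.n_discarded}\t{r.n_out}")
        return "\n".join(lines) + "\n"


@dataclass
class CascadeInputs:
    """Evidence bundle consumed by :func:`run_cascade`.

    genome_hits maps genome_id -> model-vs-genome hits; exon_products maps
    exon subject ids to their product descriptions (for the hypothetical/TE
    exclusions of the exon filter).
    """

    model_hits: list[AlignmentHit] = field(default_factory=list)
    genome_hits: Mapping[str, list[AlignmentHit]] = field(default_factory=dict)
    exon_hits: list[AlignmentHit] = field(default_factory=list)
    exon_products: Mapping[str, str] = field(default_factory=dict)
    #: None means "no TRF run available" -> fall back to the internal detector
    tandem_records: Optional[list[TandemRecord]] = None
    trna_rows: list[DomainEvidence] = field(default_factory=list)


def cluster_models(
    models: Sequence[ConsensusModel],
    hits: Sequence[AlignmentHit],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[Cluster], set[str]]:
    """Single-linkage redundancy clustering of all-vs-all model hits.

    Two models link iff some hit between them has identity strictly above
    ``cluster_id_thresh`` and alignment length over the shorter model's
    length strictly above ``cluster_cov_thresh``.  One representative (the
    longest member; ties to the lexicographically smallest id) is kept per
    connected component; all other members are discarded as redundant.
    """
    lengths = {m.model_id: m.length for m in models}
    parent = {m.model_id: m.model_id for m in models}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for h in hits:
        if h.query_id not in lengths or h.subject_id not in lengths:
            unknown = h.query_id if h.query_id not in lengths else h.subject_id
            raise ValueError(f"hit references unknown model id {unknown!r}")
        if h.query_id == h.subject_id:
            continue
        if h.evalue > config.evalue_cluster:
            continue
        shorter = min(lengths[h.query_id], lengths[h.subject_id])
        if (
            h.pct_identity > config.cluster_id_thresh
            and h.aln_len / shorter > config.cluster_cov_thresh
        ):
            union(h.query_id, h.subject_id)

    groups: dict[str, set[str]] = {}
    for mid in lengths:
        groups.setdefault(find(mid), set()).add(mid)

    clusters: list[Cluster] = []
    discarded: set[str] = set()
    for members in groups.values():
        rep = max(members, key=lambda mid: (lengths[mid], _rev_lex(mid)))
        clusters.append(Cluster(representative_id=rep, member_ids=members))
        discarded |= members - {rep}
    clusters.sort(key=lambda c: c.representative_id)
    return clusters, discarded


def _rev_lex(s: str) -> tuple[int, ...]:
    # invert ordinals so that max() prefers the lexicographically smallest id
    return tuple(-ord(c) for c in s) + (1,)


def copy_number_filter(
    model: ConsensusModel,
    genome_hits: Mapping[str, Sequence[AlignmentHit]],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[bool, str]:
    """Keep iff at least one genome holds >= ``min_copies`` full-length hits.

    A hit is full-length iff it covers at least ``full_length_frac`` of the
    model.  Returns (keep, reason).
    """
    for hits in genome_hits.values():
        full = sum(
            1
            for h in hits
            if h.query_id == model.model_id
            and h.q_span / model.length >= config.full_length_frac
        )
        if full >= config.min_copies:
            return True, ""
    return False, "low_copy_or_partial"


def exon_overlap_filter(
    model: ConsensusModel,
    exon_hits: Sequence[AlignmentHit],
    config: PipelineConfig = DEFAULT_CONFIG,
    products: Optional[Mapping[str, str]] = None,
) -> tuple[bool, float]:
    """Discard iff qualifying exon hits cover strictly more than the
    threshold fraction of the model.

    Hits to exons whose product mentions "hypothetical" or a TE keyword are
    excluded before the union is computed.
    """
    products = products or {}
    qualifying = []
    for h in exon_hits:
        if h.query_id != model.model_id:
            continue
        product = products.get(h.subject_id, "")
        if "hypothetical" in product.lower() or is_te_description(product):
            continue
        qualifying.append((h.q_start, h.q_end))
    fraction = (
        total_length(clip(qualifying, 0, model.length)) / model.length
        if qualifying
        else 0.0
    )
    return fraction <= config.exon_frac_thresh, fraction


def tandem_filter(
    model: ConsensusModel,
    records: Optional[Sequence[TandemRecord]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[bool, float]:
    """Discard iff tandem repeats cover strictly more than the threshold
    fraction of the model.

    Uses supplied TRF-style records when given; otherwise falls back to the
    internal periodicity detector.
    """
    if records is None:
        fraction, _ = tandem_fraction(model.sequence, model_id=model.model_id)
    else:
        own = [
            (r.start, r.end) for r in records if r.model_id == model.model_id
        ]
        fraction = (
            total_length(clip(own, 0, model.length)) / model.length if own else 0.0
        )
    return fraction <= config.tandem_frac_thresh, fraction


def trna_filter(
    model: ConsensusModel, trna_rows: Sequence[DomainEvidence]
) -> tuple[bool, str]:
    """tRNA screening: intact predictions discard, pseudogene-only flags.

    Returns (keep, flag_or_reason): ("", no rows), ("trna_gene", intact) or
    ("SINE_candidate", only pseudogenes).
    """
    own = [r for r in trna_rows if r.model_id == model.model_id and r.source == "trna"]
    if not own:
        return True, ""
    if any(r.pseudo is False or r.pseudo is None for r in own):
        return False, "trna_gene"
    return True, "SINE_candidate"


def run_cascade(
    models: Sequence[ConsensusModel],
    inputs: CascadeInputs,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[ConsensusModel], StageReport, dict[str, str]]:
    """Apply the five filter stages in canonical order.

    Returns (survivors, stage report, flags) where flags maps model ids to
    screening flags such as "SINE_candidate".  Discarded models are marked
    in place with their stage and reason.
    """
    report = StageReport()
    flags: dict[str, str] = {}
    active = [m for m in models if m.status == "candidate"]

    # stage 1: redundancy clustering (hits to already-settled models are
    # ignored so that re-running the cascade on survivors is a no-op)
    n_in = len(active)
    active_ids = {m.model_id for m in active}
    stage_hits = [
        h
        for h in inputs.model_hits
        if h.query_id in active_ids and h.subject_id in active_ids
    ]
    _, redundant = cluster_models(active, stage_hits, config)
    for m in active:
        if m.model_id in redundant:
            m.mark_discarded("clustering", "redundant")
    active = [m for m in active if m.status == "candidate"]
    report.add("clustering", n_in, len(redundant))

    # stage 2: copy number / full length
    n_in = len(active)
    survivors = []
    for m in active:
        keep, reason = copy_number_filter(m, inputs.genome_hits, config)
        if keep:
            survivors.append(m)
        else:
            m.mark_discarded("copy_number", reason)
    report.add("copy_number", n_in, n_in - len(survivors))
    active = survivors

    # stage 3: exon overlap
    n_in = len(active)
    survivors = []
    for m in active:
        keep, fraction = exon_overlap_filter(
            m, inputs.exon_hits, config, inputs.exon_products
        )
        if keep:
            survivors.append(m)
        else:
            m.mark_discarded("exon_overlap", f"exon_fraction={fraction:.3f}")
    report.add("exon_overlap", n_in, n_in - len(survivors))
    active = survivors

    # stage 4: tandem repeats
    n_in = len(active)
    survivors = []
    for m in active:
        keep, fraction = tandem_filter(m, inputs.tandem_records, config)
        if keep:
            survivors.append(m)
        else:
            m.mark_discarded("tandem", f"tandem_fraction={fraction:.3f}")
    report.add("tandem", n_in, n_in - len(survivors))
    active = survivors

    # stage 5: tRNA screening
    n_in = len(active)
    survivors = []
    for m in active:
        keep, flag = trna_filter(m, inputs.trna_rows)
        if keep:
            if flag:
                flags[m.model_id] = flag
            survivors.append(m)
        else:
            m.mark_discarded("trna", flag)
    report.add("trna", n_in, n_in - len(survivors))

    assert [r.stage for r in report.rows] == list(CASCADE_STAGES)
    return survivors, report, flags
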