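"""Evidence integration: TE-relatedness tagging, low-complexity vetting,
accept/discard verdicts and family classification.

The accept rule requires support from at least one TE-related evidence row
(any source), with one veto: a profile-database (dfam) hit is invalidated
when protein-domain (interpro) rows exist and every one of them is unrelated
to TEs — such models are discarded as conflicts.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

from .alignment_core import MaskTrack
from .config import DEFAULT_CONFIG, PipelineConfig
from .intervals import overlap_length
from .types import ConsensusModel, CurationDecision, DomainEvidence, TEClassification

#: family_label values counted as evidence for each classification bucket
_LTR_LABELS = frozenset({"gypsy", "ty3"})
_LINE_LABELS = frozenset({"r2", "line", "ape+rt", "ape"})


@lru_cache(maxsize=1)
def load_te_keywords() -> tuple[str, ...]:
    """Load the TE keyword vocabulary shipped with the package."""
    text = (
        resources.files("tecurate").joinpath("data/te_keywords.txt").read_text()
    )
    keywords = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            keywords.append(line)
    return tuple(keywords)


@lru_cache(maxsize=1)
def _keyword_pattern() -> re.Pattern:
    alts = sorted(load_te_keywords(), key=len, reverse=True)
    body = "|".join(re.escape(k) for k in alts)
    return re.compile(rf"\b(?:{body})\b", re.IGNORECASE)


def is_te_description(description: str) -> bool:
    return bool(_keyword_pattern().search(description))


def tag_te_relatedness(evidence: list[DomainEvidence]) -> list[DomainEvidence]:
    """Set ``te_related`` on each row from the keyword vocabulary (in place)."""
    for row in evidence:
        row.te_related = is_te_description(row.description)
    return evidence


def screen_evidence(
    model: ConsensusModel,
    evidence: list[DomainEvidence],
    mask: MaskTrack,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[DomainEvidence]:
    """Drop evidence rows that sit in low-complexity regions or are too short.

    A row is dropped iff its overlap with the mask exceeds
    ``config.lowcomp_overlap_thresh`` of its own length (strictly), or its
    interval is shorter than ``config.min_evidence_len`` nt.
    """
    kept = []
    for row in evidence:
        if row.span < config.min_evidence_len:
            continue
        if mask.intervals:
            frac = overlap_length((row.m_start, row.m_end), mask.intervals) / row.span
            if frac > config.lowcomp_overlap_thresh:
                continue
        kept.append(row)
    return kept


def curate_model(
    model: ConsensusModel, vetted: list[DomainEvidence]
) -> CurationDecision:
    """Accept/discard verdict from vetted, te_related-tagged evidence."""
    te_rows = [r for r in vetted if r.te_related and r.source != "trna"]
    interpro_rows = [r for r in vetted if r.source == "interpro"]
    dfam_rows = [r for r in vetted if r.source == "dfam"]

    conflict = (
        bool(dfam_rows)
        and bool(interpro_rows)
        and not any(r.te_related for r in interpro_rows)
    )
    if te_rows and not conflict:
        return CurationDecision(
            model_id=model.model_id,
            verdict="accepted",
            stage="evidence_curation",
            supporting_evidence=sorted({r.accession for r in te_rows}),
        )
    reason = "dfam_interpro_conflict" if (conflict and te_rows) else "no_te_evidence"
    return CurationDecision(
        model_id=model.model_id,
        verdict="discarded",
        stage="evidence_curation",
        reason=reason,
    )


def classify_model(
    model: ConsensusModel,
    vetted: list[DomainEvidence],
    ltr_structure_flag: bool = False,
    sine_flag: bool = False,
) -> TEClassification:
    """Family classification by majority vote over evidence family labels.

    Gypsy/Ty3 labels vote for LTR Gypsy-like, R2/LINE/APE labels for
    LINE-like; with TE evidence but no label majority the LTR structure flag
    decides between LTR- and non-LTR-unclassified.  A SINE flag (from tRNA
    pseudogene screening) overrides everything.  Ties are broken by the
    lowest-evalue labeled row.
    """
    if model.status != "accepted":
        raise ValueError(
            f"model {model.model_id!r}: cannot classify status {model.status!r}"
        )
    te_rows = [r for r in vetted if r.te_related]
    if sine_flag:
        basis = sorted({r.accession for r in vetted}) or ["trna_pseudogene_screen"]
        return TEClassification(model.model_id, "SINE_candidate", basis)

    ltr_votes = [
        r for r in te_rows if r.family_label and r.family_label.lower() in _LTR_LABELS
    ]
    line_votes = [
        r for r in te_rows if r.family_label and r.family_label.lower() in _LINE_LABELS
    ]
    if ltr_votes or line_votes:
        if len(ltr_votes) != len(line_votes):
            winner = ltr_votes if len(ltr_votes) > len(line_votes) else line_votes
        else:  # tie: side of the lowest-evalue labeled row
            best = min(ltr_votes + line_votes, key=lambda r: (r.evalue, r.accession))
            winner = ltr_votes if best in ltr_votes else line_votes
        family = "LTR_Gypsy_like" if winner is ltr_votes else "LINE_like"
        return TEClassification(
            model.model_id, family, sorted({r.accession for r in winner})
        )
    if te_rows:
        family = "LTR_unclassified" if ltr_structure_flag else "nonLTR_unclassified"
        return TEClassification(
            model.model_id, family, sorted({r.accession for r in te_rows})
        )
    return TEClassification(model.model_id, "unclassified", [])
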