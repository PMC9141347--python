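"""Readers and writers for the external file dialects.

Every parser converts to 0-based half-open coordinates on entry; every
serializer converts back on exit.  Parsing is order-preserving, and each
parser/serializer pair round-trips field-by-field on its own output.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evidence_curation import tag_te_relatedness
from .tree import RootedTree, TreeNode
from .types import (
    AlignmentHit,
    ConsensusModel,
    DomainEvidence,
    EVIDENCE_SOURCES,
    ExonRecord,
    TandemRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

EVIDENCE_COLUMNS = (
    "model_id",
    "source",
    "accession",
    "description",
    "family_label",
    "m_start",
    "m_end",
    "frame",
    "evalue",
    "pseudo",
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike, allow_n: bool = True) -> list[ConsensusModel]:
    """Read a multi-FASTA file into ConsensusModels (order preserved).

    Duplicate ids and empty sequences are hard errors.  With
    ``allow_n=False`` (consensus-model loading) any N character is rejected.
    """
    models: list[ConsensusModel] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if not allow_n and "N" in seq:
            raise ValueError(
                f"{path}: model {rec.id!r} contains N characters; consensus "
                "models must be fully resolved"
            )
        models.append(ConsensusModel(model_id=rec.id, sequence=seq))
    return models


def write_fasta(models: Iterable[ConsensusModel], path: PathLike,
                descriptions: Optional[dict[str, str]] = None) -> None:
    """Write models as FASTA wrapped at 60 columns."""
    descriptions = descriptions or {}
    records = [
        SeqRecord(
            Seq(m.sequence), id=m.model_id,
            description=descriptions.get(m.model_id, ""),
        )
        for m in models
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6, 12 columns)
# ---------------------------------------------------------------------------

def read_tabular_hits(path: PathLike) -> list[AlignmentHit]:
    """Parse 12-column tab-separated alignment hits.

    File coordinates are 1-based inclusive; sstart > send marks a
    minus-strand match and is stored ascending with strand "-".  Percent
    identity is converted to a fraction.  Extra columns are ignored.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                aln_len = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=pident / 100.0,
                    aln_len=aln_len,
                    q_start=qstart - 1,
                    q_end=qend,
                    s_start=sstart - 1,
                    s_end=send,
                    strand=strand,
                    evalue=evalue,
                    score=bitscore,
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            s1, s2 = h.s_start + 1, h.s_end
            if h.strand == "-":
                s1, s2 = s2, s1
            mismatches = round(h.aln_len * (1 - h.pct_identity))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity * 100:.2f}",
                        str(h.aln_len),
                        str(mismatches),
                        "0",
                        str(h.q_start + 1),
                        str(h.q_end),
                        str(s1),
                        str(s2),
                        f"{h.evalue:.2g}",
                        f"{h.score:g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: PathLike) -> list[AlignmentHit]:
    """Parse a RepeatMasker .out annotation table into model-vs-genome hits.

    The file's query is the genome contig and the matching repeat is the
    model; hits are returned with the model as query (q interval on the
    model) and the contig as subject, so downstream arithmetic matches the
    other hit tables.  "C" marks a minus-strand match.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("SW", "score", "bit")):
            continue
        parts = stripped.split()
        if len(parts) < 14:
            raise ValueError(f"{path}:{lineno}: truncated row ({len(parts)} fields)")
        try:
            score = float(parts[0])
            div = float(parts[1])
            contig = parts[4]
            g_begin, g_end = int(parts[5]), int(parts[6])
            strand_field = parts[8]
            model = parts[9]
            if strand_field == "C":
                # minus strand: repeat position printed as (left) end begin
                r_end, r_begin = int(parts[12]), int(parts[13])
                strand = "-"
            else:
                r_begin, r_end = int(parts[11]), int(parts[12])
                strand = "+"
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad field ({exc})") from None
        hits.append(
            AlignmentHit(
                query_id=model,
                subject_id=contig,
                pct_identity=max(0.0, 1.0 - div / 100.0),
                aln_len=g_end - g_begin + 1,
                q_start=r_begin - 1,
                q_end=r_end,
                s_start=g_begin - 1,
                s_end=g_end,
                strand=strand,
                score=score,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# TRF .dat
# ---------------------------------------------------------------------------

def read_trf_dat(path: PathLike) -> list[TandemRecord]:
    """Parse Tandem Repeat Finder .dat output ("Sequence:" block dialect)."""
    records: list[TandemRecord] = []
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                current = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Tandem", "Program", "Version", "Parameters:", "Gary")):
                continue
            parts = line.split()
            if len(parts) < 4 or not parts[0].isdigit():
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: data row before any 'Sequence:' header")
            start, end = int(parts[0]), int(parts[1])
            period = int(parts[2])
            copies = float(parts[3])
            try:
                records.append(
                    TandemRecord(
                        model_id=current,
                        start=start - 1,
                        end=end,
                        period=period,
                        copies=copies,
                    )
                )
            except ValueError as exc:
                warnings.warn(f"{path}:{lineno}: skipping tandem row ({exc})")
    return records


def write_trf_dat(records: Iterable[TandemRecord], path: PathLike) -> None:
    by_model: dict[str, list[TandemRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.model_id not in by_model:
            by_model[r.model_id] = []
            order.append(r.model_id)
        by_model[r.model_id].append(r)
    with open(path, "w") as fh:
        for model_id in order:
            fh.write(f"Sequence: {model_id}\n")
            fh.write("Parameters: 2 7 7 80 10 50 500\n")
            for r in by_model[model_id]:
                fh.write(f"{r.start + 1} {r.end} {r.period} {r.copies:.1f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3 exons
# ---------------------------------------------------------------------------

def read_gff_exons(path: PathLike, genome_id: Optional[str] = None) -> list[ExonRecord]:
    """Extract exon features (with product attribute) from a GFF3 file."""
    if genome_id is None:
        genome_id = Path(path).stem
    exons: list[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                logger.warning("%s:%d: malformed GFF row skipped", path, lineno)
                continue
            if parts[2] != "exon":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                logger.warning("%s:%d: exon without coordinates skipped", path, lineno)
                continue
            attrs = _parse_gff_attributes(parts[8])
            exons.append(
                ExonRecord(
                    genome_id=genome_id,
                    contig_id=parts[0],
                    start=start - 1,
                    end=end,
                    strand=parts[6] if parts[6] in "+-" else "+",
                    product=attrs.get("product", ""),
                    exon_id=attrs.get("ID", ""),
                )
            )
    return exons


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.split(";"):
        item = item.strip()
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key] = value
    return attrs


def write_gff_exons(exons: Iterable[ExonRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for x in exons:
            attrs = []
            if x.exon_id:
                attrs.append(f"ID={x.exon_id}")
            if x.product:
                attrs.append(f"product={x.product}")
            fh.write(
                "\t".join(
                    [
                        x.contig_id,
                        "tecurate",
                        "exon",
                        str(x.start + 1),
                        str(x.end),
                        ".",
                        x.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Evidence TSV
# ---------------------------------------------------------------------------

def read_evidence_tsv(path: PathLike) -> list[DomainEvidence]:
    """Read a domain/profile/tRNA evidence table and tag TE-relatedness.

    Columns (header required): model_id, source, accession, description,
    family_label, m_start, m_end, frame, evalue, pseudo.  Missing optional
    values are ".".  te_related is derived from the keyword vocabulary, not
    read from the file.
    """
    rows: list[DomainEvidence] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in EVIDENCE_COLUMNS if c not in idx]
        if missing:
            raise ValueError(f"{path}: missing evidence columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")

            def get(col: str) -> str:
                return parts[idx[col]]

            source = get("source")
            if source not in EVIDENCE_SOURCES:
                raise ValueError(f"{path}:{lineno}: unknown source {source!r}")
            frame_raw = get("frame")
            pseudo_raw = get("pseudo")
            rows.append(
                DomainEvidence(
                    model_id=get("model_id"),
                    source=source,
                    accession=get("accession"),
                    description=get("description"),
                    family_label=get("family_label") if get("family_label") != "." else None,
                    m_start=int(get("m_start")),
                    m_end=int(get("m_end")),
                    frame=int(frame_raw) if frame_raw != "." else None,
                    evalue=float(get("evalue")),
                    pseudo=(pseudo_raw == "true") if pseudo_raw != "." else None,
                )
            )
    return tag_te_relatedness(rows)


def write_evidence_tsv(rows: Iterable[DomainEvidence], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.model_id,
                        r.source,
                        r.accession,
                        r.description,
                        r.family_label if r.family_label is not None else ".",
                        str(r.m_start),
                        str(r.m_end),
                        str(r.frame) if r.frame is not None else ".",
                        f"{r.evalue:.3g}",
                        "." if r.pseudo is None else ("true" if r.pseudo else "false"),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: PathLike) -> RootedTree:
    """Parse a single rooted Newick tree; branch lengths are ignored.

    Unnamed internal nodes are auto-named by post-order index.  Unbalanced
    parentheses and duplicate leaf labels are errors.
    """
    text = str(source)
    if "(" not in text:  # a path, not an inline newick string
        text = Path(source).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"invalid newick: {exc}") from None

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            if not label:
                raise ValueError("leaf without a label")
            return TreeNode(name=label)
        node = TreeNode(name=dnode.label or "")
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    labels = [n.name for n in _leaves(root)]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return RootedTree(root)


def _leaves(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves(c))
    return out


def write_newick(tree: RootedTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
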