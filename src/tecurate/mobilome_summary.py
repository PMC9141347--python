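"""Per-genome mobilome statistics: merged TE coverage, percent of genome
covered, presence/absence matrices, and the GC-median split summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import merge
from .types import AlignmentHit, FAMILY_LABELS, GenomeSummary


def merge_intervals(
    hits: Iterable[AlignmentHit],
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[dict[str, list[tuple[int, int]]], int]:
    """Union of subject (genome) intervals per contig.

    Returns (intervals by contig, total covered bases); overlapping hits are
    counted once.  When contig lengths are known, intervals beyond a
    contig's end are errors.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if contig_lengths is not None:
            length = contig_lengths.get(h.subject_id)
            if length is not None and h.s_end > length:
                raise ValueError(
                    f"hit on {h.subject_id} ends at {h.s_end} beyond contig "
                    f"length {length}"
                )
        by_contig.setdefault(h.subject_id, []).append((h.s_start, h.s_end))
    merged = {contig: merge(ivs) for contig, ivs in sorted(by_contig.items())}
    covered = sum(e - s for ivs in merged.values() for s, e in ivs)
    return merged, covered


def coverage_percent(covered: int, assembly_length: int) -> float:
    """100 x covered / length, rounded half-even to two decimals."""
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    if covered > assembly_length:
        raise ValueError(f"covered {covered} exceeds assembly length {assembly_length}")
    pct = Decimal(100 * covered) / Decimal(assembly_length)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def genome_te_coverage(
    genome_id: str,
    covered: int,
    assembly_length: int,
    copy_count: int = 0,
    main_family: str = "unclassified",
) -> GenomeSummary:
    """Assemble a GenomeSummary with the canonical percent rounding."""
    return GenomeSummary(
        genome_id=genome_id,
        assembly_length=assembly_length,
        te_covered=covered,
        te_percent=coverage_percent(covered, assembly_length),
        copy_count=copy_count,
        main_family=main_family,
    )


@dataclass
class PresenceMatrix:
    species: list[str]
    families: list[str]
    matrix: list[list[bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family labels")
        if len(self.matrix) != len(self.species) or any(
            len(row) != len(self.families) for row in self.matrix
        ):
            raise ValueError("matrix dimensions do not match labels")

    def present(self, species: str, family: str) -> bool:
        return self.matrix[self.species.index(species)][self.families.index(family)]

    def species_with(self, family: str) -> list[str]:
        j = self.families.index(family)
        return [sp for i, sp in enumerate(self.species) if self.matrix[i][j]]

    def to_tsv(self) -> str:
        lines = ["species\t" + "\t".join(self.families)]
        for sp, row in zip(self.species, self.matrix):
            lines.append(sp + "\t" + "\t".join("1" if x else "0" for x in row))
        return "\n".join(lines) + "\n"


def build_presence_matrix(
    summaries: Sequence[GenomeSummary],
    families: Optional[Sequence[str]] = None,
) -> PresenceMatrix:
    """Presence/absence by genome and family (presence = copy_count > 0).

    Genomes with zero hits appear as all-false rows.
    """
    seen = set()
    for s in summaries:
        if s.genome_id in seen:
            raise ValueError(f"duplicate genome id {s.genome_id!r}")
        seen.add(s.genome_id)
    if families is None:
        families = [f for f in FAMILY_LABELS if f != "unclassified"]
    matrix = [
        [s.copy_count > 0 and s.main_family == fam for fam in families]
        for s in summaries
    ]
    return PresenceMatrix(
        species=[s.genome_id for s in summaries],
        families=list(families),
        matrix=matrix,
    )


def gc_split_summary(
    rows: Sequence[tuple[float, bool]],
) -> tuple[float, int, int]:
    """Split genomes at the median GC and count TE-bearing ones per side.

    ``rows`` are (gc_percent, has_te) pairs.  The median is the lower median
    for even n.  Returns (median_gc, TE count strictly below the median,
    TE count at or above it).
    """
    if len(rows) < 2:
        raise ValueError("need at least two genomes")
    for gc, _ in rows:
        if not 0.0 < gc < 100.0:
            raise ValueError(f"gc_percent {gc} outside (0, 100)")
    ordered = sorted(gc for gc, _ in rows)
    median = ordered[(len(ordered) - 1) // 2]
    below = sum(1 for gc, has_te in rows if has_te and gc < median)
    at_or_above = sum(1 for gc, has_te in rows if has_te and gc >= median)
    return median, below, at_or_above
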