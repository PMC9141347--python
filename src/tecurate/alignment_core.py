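"""Bespoke sequence computations used by the curation pipeline.

Local alignment with identity/coverage, DUST-style low-complexity masking,
tandem-periodicity detection, and six-frame ORF finding.  These are internal
stand-ins for the identity/coverage arithmetic of the external search tools;
they favour exactness and determinism over speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.Seq import Seq

from .intervals import merge, total_length
from .types import TandemRecord

DNA_ALPHABET = frozenset("ACGT")


@dataclass
class LocalAlignment:
    score: int
    identity: float
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    aligned_columns: int
    matches: int

    def __post_init__(self) -> None:
        if self.matches > self.aligned_columns:
            raise ValueError("matches > aligned_columns")
        if self.aligned_columns > 0:
            expected = self.matches / self.aligned_columns
            if abs(self.identity - expected) > 1e-12:
                raise ValueError("identity inconsistent with matches/aligned_columns")


@dataclass
class MaskTrack:
    """Disjoint sorted masked intervals over a sequence."""

    seq_len: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.intervals:
            if s < prev_end or e <= s or e > self.seq_len:
                raise ValueError(f"bad mask intervals {self.intervals}")
            prev_end = e

    @property
    def masked_bases(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def masked_fraction(self) -> float:
        return self.masked_bases / self.seq_len if self.seq_len else 0.0


def _check_dna(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name}: characters outside ACGT: {sorted(bad)}")
    return seq


def local_align(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -1,
    gap: int = -2,
) -> LocalAlignment:
    """Maximal-scoring local alignment under a linear gap penalty.

    Ties between equally scoring alignments are broken by earliest query
    start, then earliest subject start, then fewest gaps; the traceback
    prefers substitutions over gaps, which makes the result deterministic.
    """
    a = _check_dna(a, "query")
    b = _check_dna(b, "subject")
    n, m = len(a), len(b)

    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            score = sub
            up = prev[j] + gap
            if up > score:
                score = up
            left = row[j - 1] + gap
            if left > score:
                score = left
            if score < 0:
                score = 0
            row[j] = score
            if score > best:
                best = score

    if best == 0:
        return LocalAlignment(0, 0.0, (0, 0), (0, 0), 0, 0)

    end_cells = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(1, m + 1)
        if H[i][j] == best
    ]

    def traceback(i: int, j: int) -> tuple[int, int, int, int, int]:
        matches = columns = gaps = 0
        while H[i][j] > 0:
            here = H[i][j]
            is_match = a[i - 1] == b[j - 1]
            sub = H[i - 1][j - 1] + (match if is_match else mismatch)
            if sub == here:
                matches += is_match
                columns += 1
                i, j = i - 1, j - 1
            elif H[i - 1][j] + gap == here:
                gaps += 1
                columns += 1
                i -= 1
            else:
                gaps += 1
                columns += 1
                j -= 1
        return i, j, gaps, matches, columns

    chosen = None
    for i_end, j_end in end_cells:
        q0, s0, gaps, matches, columns = traceback(i_end, j_end)
        key = (q0, s0, gaps, i_end, j_end)
        if chosen is None or key < chosen[0]:
            chosen = (key, (q0, s0, gaps, matches, columns, i_end, j_end))

    _, (q0, s0, _, matches, columns, i_end, j_end) = chosen
    return LocalAlignment(
        score=best,
        identity=matches / columns,
        q_interval=(q0, i_end),
        s_interval=(s0, j_end),
        aligned_columns=columns,
        matches=matches,
    )


def dust_mask(seq: str, window: int = 64, score_thresh: float = 2.0) -> MaskTrack:
    """DUST-style low-complexity masking.

    For every window w of up to ``window`` positions the score is
    sum_t c_t(c_t - 1)/2 over triplet counts, normalised by (|w| - 3);
    positions in windows whose score exceeds ``score_thresh`` are masked
    and overlapping masked windows merged.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 4:
        return MaskTrack(seq_len=n)

    w = min(window, n)
    triplets = [seq[i : i + 3] for i in range(n - 2)]
    counts: dict[str, int] = {}
    pairsum = 0  # sum of c*(c-1)/2 over the current window's triplets
    denom = max(1, w - 3)
    masked: list[tuple[int, int]] = []

    # window [i, i+w) covers triplets i .. i+w-3
    for t in triplets[: w - 2]:
        pairsum += counts.get(t, 0)
        counts[t] = counts.get(t, 0) + 1
    for i in range(n - w + 1):
        if pairsum / denom > score_thresh:
            masked.append((i, i + w))
        if i + w <= n - 1:
            out_t = triplets[i]
            counts[out_t] -= 1
            pairsum -= counts[out_t]
            if i + w - 2 < len(triplets):
                in_t = triplets[i + w - 2]
                pairsum += counts.get(in_t, 0)
                counts[in_t] = counts.get(in_t, 0) + 1
    return MaskTrack(seq_len=n, intervals=merge(masked) if masked else [])


def tandem_fraction(
    seq: str,
    max_period: int = 100,
    min_copies: float = 2.0,
    min_identity: float = 0.85,
    min_length: int = 24,
    model_id: str = "seq",
) -> tuple[float, list[TandemRecord]]:
    """Detect tandem periodicity via self-comparison at lag p.

    For each period p <= ``max_period``, positions where seq[i] == seq[i+p]
    are scanned for maximal runs with match rate >= ``min_identity`` and run
    length >= ``min_copies`` x p.  Runs shorter than ``min_length`` nt
    (including the trailing period) are ignored as noise.  Records fully
    covered by smaller-period records are suppressed.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2:
        return 0.0, []

    records: list[TandemRecord] = []
    covered: list[tuple[int, int]] = []
    for p in range(1, min(max_period, n - 1) + 1):
        m = [seq[i] == seq[i + p] for i in range(n - p)]
        runs = _qualifying_runs(m, min_identity)
        for s, e in runs:
            run_len = e - s
            span = (s, e + p)
            if run_len < min_copies * p:
                continue
            if span[1] - span[0] < min_length:
                continue
            if covered and _contained(span, covered):
                continue
            records.append(
                TandemRecord(
                    model_id=model_id,
                    start=span[0],
                    end=span[1],
                    period=p,
                    copies=round((span[1] - span[0]) / p, 2),
                )
            )
            covered = merge(covered + [span])
    fraction = total_length(covered) / n if covered else 0.0
    return fraction, records


def _qualifying_runs(m: list[bool], min_identity: float) -> list[tuple[int, int]]:
    """Maximal runs of the match array with overall match rate >= min_identity."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(m)
    while i < n:
        if not m[i]:
            i += 1
            continue
        s = i
        matches = 0
        best_end = i
        j = i
        while j < n:
            matches += m[j]
            if matches / (j - s + 1) >= min_identity:
                best_end = j + 1
            elif not m[j] and (j - s + 1) * min_identity > matches + 1:
                break  # rate cannot recover soon; close the run
            j += 1
        runs.append((s, best_end))
        i = max(best_end, s + 1)
    return runs


def _contained(span: tuple[int, int], covered: list[tuple[int, int]]) -> bool:
    return any(cs <= span[0] and span[1] <= ce for cs, ce in covered)


class OrfHit(NamedTuple):
    frame: int
    m_start: int
    m_end: int
    peptide: str


def six_frame_orfs(seq: str, min_aa: int = 50) -> list[OrfHit]:
    """Maximal stop-free stretches of >= ``min_aa`` residues in all six frames.

    A start codon is not required (stop-to-stop ORFs); coordinates are
    half-open on the forward strand of the input sequence.
    """
    seq = seq.upper()
    n = len(seq)
    hits: list[OrfHit] = []
    rc = str(Seq(seq).reverse_complement())
    for frame_sign, template in ((1, seq), (-1, rc)):
        for off in range(3):
            frame = frame_sign * (off + 1)
            usable = (n - off) // 3
            if usable < min_aa:
                continue
            protein = str(Seq(template[off : off + 3 * usable]).translate())
            aa = 0
            for stretch in protein.split("*"):
                if len(stretch) >= min_aa:
                    nt_start = off + 3 * aa
                    nt_end = off + 3 * (aa + len(stretch))
                    if frame_sign == 1:
                        coords = (nt_start, nt_end)
                    else:
                        coords = (n - nt_end, n - nt_start)
                    hits.append(OrfHit(frame, coords[0], coords[1], stretch))
                aa += len(stretch) + 1
    hits.sort(key=lambda h: (h.frame < 0, abs(h.frame), h.m_start))
    return hits
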