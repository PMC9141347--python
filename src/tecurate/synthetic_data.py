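"""Synthetic genomes with planted mobile elements and decoys.

Generates toy genomes (background composition at a target GC), plants
LTR-like and LINE-like elements plus multigene-family, tandem-repeat,
low-copy and tRNA decoys, and emits every evidence table the curation
pipeline consumes — together with a ground-truth ledger of intended fates.

All randomness flows from a single ``random.Random(seed)`` stream using
integer draws only, so datasets are byte-identical across platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .types import AlignmentHit, ConsensusModel, DomainEvidence, ExonRecord, TandemRecord

#: intended fates; everything except true_te is an expected discard
FATES = ("true_te", "redundant", "low_copy", "gene_decoy", "tandem_decoy", "trna_decoy")

_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

_GENE_PRODUCTS = (
    "60S ribosomal protein L7a",
    "elongation factor 1-alpha",
    "heat shock protein 70",
    "serine/threonine protein kinase",
)


@dataclass
class SimulationRecipe:
    rng_seed: int = 0
    n_genomes: int = 3
    contig_lengths: tuple[int, ...] = (15000, 15000, 12000, 10000)
    gc_target: float = 0.35
    #: (family, length, ltr_flag) triples
    te_templates: tuple[tuple[str, int, bool], ...] = (
        ("LTR_Gypsy_like", 1200, True),
        ("LINE_like", 1500, False),
    )
    copies_per_te: int = 4
    divergence: float = 0.05
    n_gene_decoys: int = 2
    n_tandem_decoys: int = 2
    n_trna_decoys: int = 1
    n_redundant: int = 2
    n_low_copy: int = 1

    #: length of the terminal repeat on LTR-like templates
    ltr_len: int = 200

    def __post_init__(self) -> None:
        if not 0.15 <= self.gc_target <= 0.60:
            raise ValueError(f"gc_target {self.gc_target} outside [0.15, 0.60]")
        if not 0.0 <= self.divergence < 0.3:
            raise ValueError(f"divergence {self.divergence} outside [0, 0.3)")
        for n in (
            self.n_genomes,
            self.copies_per_te,
            self.n_gene_decoys,
            self.n_tandem_decoys,
            self.n_trna_decoys,
            self.n_redundant,
            self.n_low_copy,
        ):
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.te_templates:
            largest = max(length for _, length, _ in self.te_templates)
            if min(self.contig_lengths) < largest:
                raise ValueError("every contig must fit the largest planted element")
        if self.n_redundant > len(self.te_templates):
            raise ValueError("cannot make more redundant variants than templates")


@dataclass
class PlantedElement:
    genome_id: str
    contig_id: str
    start: int
    end: int
    family: str
    template_id: str
    n_substitutions: int = 0


@dataclass
class GroundTruth:
    planted: list[PlantedElement] = field(default_factory=list)
    #: model_id -> intended fate (one of FATES)
    fates: dict[str, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    ltr_flags: dict[str, bool] = field(default_factory=dict)
    #: model_id -> template sequence (candidates emitted from templates)
    candidate_seqs: dict[str, str] = field(default_factory=dict)

    def expected_survivors(self) -> set[str]:
        return {mid for mid, fate in self.fates.items() if fate == "true_te"}

    def expected_discards(self) -> set[str]:
        return {mid for mid, fate in self.fates.items() if fate != "true_te"}


@dataclass
class SyntheticDataset:
    recipe: SimulationRecipe
    genomes: dict[str, dict[str, str]]
    truth: GroundTruth
    models: list[ConsensusModel]
    self_hits: list[AlignmentHit]
    genome_hits: dict[str, list[AlignmentHit]]
    exon_records: list[ExonRecord]
    exon_hits: list[AlignmentHit]
    exon_products: dict[str, str]
    tandem_records: list[TandemRecord]
    evidence: list[DomainEvidence]
    trna_rows: list[DomainEvidence]
    genome_table: list[tuple[str, int, float]]  # genome_id, length, gc_percent


# ---------------------------------------------------------------------------
# sequence primitives (integer RNG draws only)
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, n: int, gc: float) -> str:
    gc_thr = round(gc * 2_000_000)
    out = []
    for _ in range(n):
        r = rng.randrange(2_000_000)
        if r < gc_thr:
            out.append("G" if r & 1 else "C")
        else:
            out.append("A" if r & 1 else "T")
    return "".join(out)


def _coding_seq(rng: random.Random, n: int) -> str:
    """Stop-free (frame +1) sequence of length n."""
    codons = [_NON_STOP_CODONS[rng.randrange(61)] for _ in range(n // 3 + 1)]
    return "".join(codons)[:n]


def _mutate(rng: random.Random, seq: str, rate: float) -> tuple[str, int]:
    """Substitution-only mutation at the given per-site rate."""
    thr = round(rate * 1_000_000)
    out = list(seq)
    n_subs = 0
    for i, base in enumerate(out):
        if rng.randrange(1_000_000) < thr:
            others = [b for b in "ACGT" if b != base]
            out[i] = others[rng.randrange(3)]
            n_subs += 1
    return "".join(out), n_subs


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _build_templates(
    rng: random.Random, recipe: SimulationRecipe
) -> tuple[dict[str, str], dict[str, str], dict[str, bool]]:
    """Returns (sequences, families, ltr_flags) keyed by template id."""
    seqs: dict[str, str] = {}
    families: dict[str, str] = {}
    flags: dict[str, bool] = {}
    for i, (family, length, ltr_flag) in enumerate(recipe.te_templates):
        tid = f"TE{i:02d}_{'LTR' if ltr_flag else 'LINE'}"
        if ltr_flag:
            if length <= 2 * recipe.ltr_len:
                raise ValueError(f"template {tid}: too short for terminal repeats")
            ltr = _random_seq(rng, recipe.ltr_len, 0.45)
            internal = _coding_seq(rng, length - 2 * recipe.ltr_len)
            seqs[tid] = ltr + internal + ltr
        else:
            # UTR length is a codon multiple so the ORF sits in frame +1
            utr = _coding_seq(rng, 48)
            orf = _coding_seq(rng, ((length - 96) // 3) * 3)
            seqs[tid] = utr + orf + _random_seq(rng, length - len(utr) - len(orf), 0.40)
        families[tid] = family
        flags[tid] = ltr_flag
    return seqs, families, flags


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

class _Planter:
    """Places elements at non-overlapping uniform positions in the contigs
    of one genome."""

    MAX_TRIES = 500

    def __init__(self, rng: random.Random, genome_id: str, contig_lengths: tuple[int, ...]):
        self.rng = rng
        self.genome_id = genome_id
        self.contigs = [f"{genome_id}_c{k}" for k in range(len(contig_lengths))]
        self.lengths = dict(zip(self.contigs, contig_lengths))
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.contigs}

    def place(self, el_len: int) -> tuple[str, int]:
        eligible = [c for c in self.contigs if self.lengths[c] >= el_len]
        if not eligible:
            raise ValueError(
                f"{self.genome_id}: no contig can hold an element of {el_len} nt"
            )
        for _ in range(self.MAX_TRIES):
            contig = eligible[self.rng.randrange(len(eligible))]
            start = self.rng.randrange(self.lengths[contig] - el_len + 1)
            end = start + el_len
            if all(e <= start or s >= end for s, e in self.occupied[contig]):
                self.occupied[contig].append((start, end))
                return contig, start
        raise ValueError(
            f"{self.genome_id}: could not place an element of {el_len} nt after "
            f"{self.MAX_TRIES} tries; contigs too crowded"
        )


def simulate_genomes(
    recipe: SimulationRecipe,
) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Generate background genomes and plant all elements.

    Returns (genomes, truth): genomes maps genome_id -> contig_id -> sequence;
    the truth ledger records every planted interval and, after
    :func:`emit_candidates`, the intended fate of each candidate model.
    """
    rng = random.Random(recipe.rng_seed)
    truth = GroundTruth()

    te_seqs, te_families, te_flags = _build_templates(rng, recipe)

    # decoy templates
    gene_seqs = {
        f"GENE{i:02d}": _coding_seq(rng, 900) for i in range(recipe.n_gene_decoys)
    }
    tandem_seqs = {}
    for i in range(recipe.n_tandem_decoys):
        unit = _random_seq(rng, 10, 0.5)
        n_units = 36  # 360 nt of tandem, 60% of the 600 nt model
        tandem_seqs[f"TAND{i:02d}"] = (unit * n_units) + _random_seq(rng, 240, 0.35)
    trna_seqs = {
        f"TRNA{i:02d}": _random_seq(rng, 300, 0.40) for i in range(recipe.n_trna_decoys)
    }
    low_copy_seqs = {
        f"LOWC{i:02d}": _coding_seq(rng, 800) for i in range(recipe.n_low_copy)
    }

    truth.candidate_seqs.update(te_seqs)
    truth.candidate_seqs.update(low_copy_seqs)
    truth.candidate_seqs.update(gene_seqs)
    truth.candidate_seqs.update(tandem_seqs)
    truth.candidate_seqs.update(trna_seqs)
    for tid in te_seqs:
        truth.fates[tid] = "true_te"
        truth.families[tid] = te_families[tid]
        truth.ltr_flags[tid] = te_flags[tid]
    for tid in low_copy_seqs:
        truth.fates[tid] = "low_copy"
    for tid in gene_seqs:
        truth.fates[tid] = "gene_decoy"
    for tid in tandem_seqs:
        truth.fates[tid] = "tandem_decoy"
    for tid in trna_seqs:
        truth.fates[tid] = "trna_decoy"

    # redundant variants of the first n_redundant TE templates: 97% identity,
    # truncated so the original template stays the longest cluster member
    for i, tid in enumerate(sorted(te_seqs)[: recipe.n_redundant]):
        vid = f"{tid}_v"
        variant, _ = _mutate(rng, te_seqs[tid][:-30], 0.03)
        truth.candidate_seqs[vid] = variant
        truth.fates[vid] = "redundant"

    genomes: dict[str, dict[str, str]] = {}
    for g in range(recipe.n_genomes):
        genome_id = f"g{g}"
        planter = _Planter(rng, genome_id, recipe.contig_lengths)
        plan: list[tuple[str, str]] = []  # (template_id, fate)

        # true TEs: full copy number in the first two genomes
        if g < 2:
            for tid in sorted(te_seqs):
                plan.extend((tid, "true_te") for _ in range(recipe.copies_per_te))
        # low-copy templates: below min_copies everywhere
        for tid in sorted(low_copy_seqs):
            plan.extend((tid, "low_copy") for _ in range(2))
        # gene decoys: multigene family in genome 0, conserved single copy elsewhere
        for tid in sorted(gene_seqs):
            plan.extend((tid, "gene_decoy") for _ in range(3 if g == 0 else 1))
        # tandem and tRNA decoys: multi-copy in genome 0 only
        if g == 0:
            for tid in sorted(tandem_seqs):
                plan.extend((tid, "tandem_decoy") for _ in range(3))
            for tid in sorted(trna_seqs):
                plan.extend((tid, "trna_decoy") for _ in range(3))

        placements = []
        for tid, fate in plan:
            template = truth.candidate_seqs[tid]
            contig, start = planter.place(len(template))
            copy_seq, n_subs = _mutate(rng, template, recipe.divergence)
            placements.append((contig, start, copy_seq))
            truth.planted.append(
                PlantedElement(
                    genome_id=genome_id,
                    contig_id=contig,
                    start=start,
                    end=start + len(template),
                    family=truth.families.get(tid, fate),
                    template_id=tid,
                    n_substitutions=n_subs,
                )
            )

        contigs = {
            c: list(_random_seq(rng, recipe.contig_lengths[k], recipe.gc_target))
            for k, c in enumerate(planter.contigs)
        }
        for contig, start, copy_seq in placements:
            contigs[contig][start : start + len(copy_seq)] = copy_seq
        genomes[genome_id] = {c: "".join(s) for c, s in contigs.items()}

    return genomes, truth


# ---------------------------------------------------------------------------
# evidence emission
# ---------------------------------------------------------------------------

def emit_candidates(
    genomes: dict[str, dict[str, str]],
    truth: GroundTruth,
    recipe: SimulationRecipe,
) -> SyntheticDataset:
    """Emit candidate models and every evidence table, consistent with the
    planted genomes."""
    models = [
        ConsensusModel(model_id=mid, sequence=seq, source_genome="merged")
        for mid, seq in sorted(truth.candidate_seqs.items())
    ]
    model_len = {m.model_id: m.length for m in models}

    # all-vs-all hits: one row per redundant pair (identity from the actual
    # substitution count is recomputed by direct comparison)
    self_hits: list[AlignmentHit] = []
    for mid, fate in sorted(truth.fates.items()):
        if fate != "redundant":
            continue
        parent = mid[: -len("_v")]
        a, b = truth.candidate_seqs[parent], truth.candidate_seqs[mid]
        matches = sum(1 for x, y in zip(a, b) if x == y)
        self_hits.append(
            AlignmentHit(
                query_id=parent,
                subject_id=mid,
                pct_identity=matches / len(b),
                aln_len=len(b),
                q_start=0,
                q_end=len(b),
                s_start=0,
                s_end=len(b),
                evalue=1e-180,
                score=2.0 * matches,
            )
        )

    # model-vs-genome hits: one full-length hit per planted copy
    genome_hits: dict[str, list[AlignmentHit]] = {g: [] for g in genomes}
    for el in truth.planted:
        length = el.end - el.start
        identity = 1.0 - el.n_substitutions / length
        genome_hits[el.genome_id].append(
            AlignmentHit(
                query_id=el.template_id,
                subject_id=el.contig_id,
                pct_identity=identity,
                aln_len=length,
                q_start=0,
                q_end=length,
                s_start=el.start,
                s_end=el.end,
                evalue=1e-150,
                score=2.0 * round(identity * length),
            )
        )

    # exon annotations + model-vs-exon hits for gene decoys (80% of length)
    exon_records: list[ExonRecord] = []
    exon_hits: list[AlignmentHit] = []
    exon_products: dict[str, str] = {}
    k = 0
    for el in truth.planted:
        if truth.fates.get(el.template_id) != "gene_decoy":
            continue
        length = el.end - el.start
        lo, hi = length // 10, length - length // 10
        exon_id = f"exon_{k}"
        k += 1
        idx = int(el.template_id[len("GENE"):]) % len(_GENE_PRODUCTS)
        product = _GENE_PRODUCTS[idx]
        exon_records.append(
            ExonRecord(
                genome_id=el.genome_id,
                contig_id=el.contig_id,
                start=el.start + lo,
                end=el.start + hi,
                strand="+",
                product=product,
                exon_id=exon_id,
            )
        )
        exon_products[exon_id] = product
        exon_hits.append(
            AlignmentHit(
                query_id=el.template_id,
                subject_id=exon_id,
                pct_identity=1.0 - el.n_substitutions / length,
                aln_len=hi - lo,
                q_start=lo,
                q_end=hi,
                s_start=0,
                s_end=hi - lo,
                evalue=1e-120,
                score=2.0 * (hi - lo),
            )
        )

    # TRF-style tandem records for the tandem decoys (60% of the model)
    tandem_records = [
        TandemRecord(
            model_id=mid,
            start=0,
            end=360,
            period=10,
            copies=36.0,
        )
        for mid, fate in sorted(truth.fates.items())
        if fate == "tandem_decoy"
    ]

    # domain evidence for the true TEs; intact tRNA rows for tRNA decoys
    evidence: list[DomainEvidence] = []
    for mid, fate in sorted(truth.fates.items()):
        if fate != "true_te":
            continue
        length = model_len[mid]
        if truth.ltr_flags.get(mid):
            evidence.extend(
                [
                    DomainEvidence(
                        model_id=mid, source="dfam", accession="DF0001001",
                        description="Gypsy LTR retrotransposon",
                        family_label="Gypsy",
                        m_start=recipe.ltr_len + 50, m_end=length - recipe.ltr_len - 50,
                        evalue=1e-30,
                    ),
                    DomainEvidence(
                        model_id=mid, source="interpro", accession="IPR000477",
                        description="reverse transcriptase (RNA-dependent DNA polymerase)",
                        m_start=recipe.ltr_len + 80, m_end=recipe.ltr_len + 500,
                        evalue=1e-25, frame=1,
                    ),
                    DomainEvidence(
                        model_id=mid, source="sprot", accession="P10401",
                        description="gag-pol polyprotein",
                        family_label="Ty3",
                        m_start=recipe.ltr_len + 60, m_end=recipe.ltr_len + 450,
                        evalue=1e-18, frame=1,
                    ),
                ]
            )
        else:
            evidence.extend(
                [
                    DomainEvidence(
                        model_id=mid, source="dfam", accession="DF0002002",
                        description="R2 non-LTR retrotransposon",
                        family_label="R2",
                        m_start=100, m_end=length - 100,
                        evalue=1e-28,
                    ),
                    DomainEvidence(
                        model_id=mid, source="interpro", accession="IPR004244",
                        description="reverse transcriptase",
                        m_start=200, m_end=min(length - 100, 900),
                        evalue=1e-22, frame=1,
                    ),
                    DomainEvidence(
                        model_id=mid, source="interpro", accession="IPR027847",
                        description="apurinic endonuclease",
                        m_start=80, m_end=300,
                        evalue=1e-15, frame=1,
                    ),
                    DomainEvidence(
                        model_id=mid, source="sprot", accession="P16425",
                        description="LINE R2 retrotransposon protein",
                        family_label="R2",
                        m_start=150, m_end=min(length - 120, 850),
                        evalue=1e-12, frame=1,
                    ),
                ]
            )

    from .evidence_curation import tag_te_relatedness

    tag_te_relatedness(evidence)

    trna_rows = [
        DomainEvidence(
            model_id=mid, source="trna", accession="tRNA-Ala-AGC",
            description="tRNA-Ala (AGC) prediction",
            m_start=100, m_end=175, evalue=1e-5, pseudo=False,
        )
        for mid, fate in sorted(truth.fates.items())
        if fate == "trna_decoy"
    ]

    genome_table = [
        (
            gid,
            sum(len(s) for s in contigs.values()),
            round(100 * gc_fraction("".join(contigs.values())), 2),
        )
        for gid, contigs in sorted(genomes.items())
    ]

    return SyntheticDataset(
        recipe=recipe,
        genomes=genomes,
        truth=truth,
        models=models,
        self_hits=self_hits,
        genome_hits=genome_hits,
        exon_records=exon_records,
        exon_hits=exon_hits,
        exon_products=exon_products,
        tandem_records=tandem_records,
        evidence=evidence,
        trna_rows=trna_rows,
        genome_table=genome_table,
    )


def generate_dataset(recipe: Optional[SimulationRecipe] = None) -> SyntheticDataset:
    """Convenience wrapper: simulate genomes and emit all tables."""
    recipe = recipe or SimulationRecipe()
    genomes, truth = simulate_genomes(recipe)
    return emit_candidates(genomes, truth, recipe)


# ---------------------------------------------------------------------------
# on-disk dataset layout (used by the CLI)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    from . import io_formats as io

    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    for gid, contigs in sorted(dataset.genomes.items()):
        io.write_fasta(
            [ConsensusModel(model_id=c, sequence=s) for c, s in sorted(contigs.items())],
            out / "genomes" / f"{gid}.fasta",
        )
    io.write_fasta(dataset.models, out / "models.fasta")
    io.write_tabular_hits(dataset.self_hits, out / "self_hits.tsv")
    all_genome_hits = [h for g in sorted(dataset.genome_hits) for h in dataset.genome_hits[g]]
    io.write_tabular_hits(all_genome_hits, out / "genome_hits.tsv")
    io.write_tabular_hits(dataset.exon_hits, out / "exon_hits.tsv")
    io.write_gff_exons(dataset.exon_records, out / "exons.gff3")
    io.write_trf_dat(dataset.tandem_records, out / "tandem.dat")
    io.write_evidence_tsv(dataset.evidence, out / "evidence.tsv")
    io.write_evidence_tsv(dataset.trna_rows, out / "trna.tsv")

    with open(out / "contigs.tsv", "w") as fh:
        fh.write("contig_id\tgenome_id\tlength\n")
        for gid, contigs in sorted(dataset.genomes.items()):
            for cid, seq in sorted(contigs.items()):
                fh.write(f"{cid}\t{gid}\t{len(seq)}\n")
    with open(out / "genome_table.tsv", "w") as fh:
        fh.write("genome_id\tassembly_length\tgc_percent\n")
        for gid, length, gc in dataset.genome_table:
            fh.write(f"{gid}\t{length}\t{gc:.2f}\n")
    with open(out / "ltr_flags.tsv", "w") as fh:
        fh.write("model_id\tltr_structure_flag\n")
        for mid in sorted(m.model_id for m in dataset.models):
            flag = dataset.truth.ltr_flags.get(mid, False)
            fh.write(f"{mid}\t{'1' if flag else '0'}\n")
    with open(out / "truth_fates.tsv", "w") as fh:
        fh.write("model_id\tfate\tfamily\n")
        for mid, fate in sorted(dataset.truth.fates.items()):
            fam = dataset.truth.families.get(mid, ".")
            fh.write(f"{mid}\t{fate}\t{fam}\n")
    with open(out / "truth_planted.tsv", "w") as fh:
        fh.write("genome_id\tcontig_id\tstart\tend\tfamily\ttemplate_id\tn_substitutions\n")
        for el in dataset.truth.planted:
            fh.write(
                f"{el.genome_id}\t{el.contig_id}\t{el.start}\t{el.end}\t"
                f"{el.family}\t{el.template_id}\t{el.n_substitutions}\n"
            )
    with open(out / "recipe.txt", "w") as fh:
        for key, value in vars(dataset.recipe).items():
            fh.write(f"{key}={value}\n")
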