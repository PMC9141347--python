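# tecurate

Curation toolkit for de-novo transposable-element (TE) consensus models.

Starting from candidate interspersed-repeat consensus sequences and their
supporting search evidence, `tecurate` applies a five-stage filtering
cascade, integrates protein/profile evidence into accept/discard verdicts
and family classifications, summarizes per-genome mobilome statistics, and
reconstructs minimum gain/loss scenarios for TE presence/absence on a
species tree. A synthetic-data module generates toy genomes with planted
elements and full ground truth, so the whole pipeline is testable offline.

## Components

| module | what it does |
| --- | --- |
| `io_formats` | FASTA, 12-column BLAST tabular, RepeatMasker `.out`, TRF `.dat`, GFF3 exons, evidence TSV, Newick. All in-memory coordinates are 0-based half-open; conversions live only in the parsers/serializers. |
| `alignment_core` | Local alignment (linear gaps) with identity/coverage, DUST-style low-complexity masking, tandem-periodicity detection, six-frame stop-to-stop ORF finding. |
| `model_filtering` | The cascade: redundancy clustering (>90% identity over >90% of the shorter model, single linkage, longest member kept) → copy-number filter (≥3 full-length copies in ≥1 genome) → exon-overlap filter (>40% discards) → tandem filter (>40% discards) → tRNA screen (intact genes discard, pseudogenes flag SINE candidates). Produces a stage report with flow accounting. |
| `evidence_curation` | TE-relatedness tagging from an editable keyword vocabulary (`data/te_keywords.txt`), low-complexity vetting of evidence rows, the accept/discard rule (any TE-related support, with a dfam-vs-interpro conflict veto), and family classification (LTR Gypsy-like, LINE-like, LTR/non-LTR unclassified, SINE candidate). |
| `mobilome_summary` | Merged (union) TE coverage per genome, percent of genome covered (half-even, 2 decimals), presence/absence matrices, GC-median split summary. |
| `gainloss_parsimony` | Sankoff minimum gain/loss cost with a stem-absent convention, complete enumeration of optimal scenarios, and a single-origin (Dollo) variant. Packaged fixtures cover the piroplasmid and coccidian instances. |
| `synthetic_data` | Deterministic generator for genomes (target GC), planted LTR-like/LINE-like elements, redundant variants, low-copy/gene/tandem/tRNA decoys, and all matching evidence tables plus a ground-truth ledger. |

Every numeric threshold lives in `tecurate.config.PipelineConfig`.

## CLI

```sh
# generate a synthetic dataset with ground truth
tecurate simulate --seed 42 --out-dir ds

# five-stage filtering cascade with stage accounting
tecurate filter --dataset ds --out-dir flt

# evidence integration and classification of the survivors
tecurate curate --models flt/survivors.fasta --evidence ds/evidence.tsv \
    --ltr-flags ds/ltr_flags.tsv --filter-decisions flt/decisions.tsv \
    --out-dir cur

# per-genome mobilome summary and presence matrix
tecurate summarize --hits ds/genome_hits.tsv --contigs ds/contigs.tsv \
    --genome-table ds/genome_table.tsv --accepted cur/accepted.fasta \
    --families cur/decisions.tsv --out-dir summ

# gain/loss scenarios on a rooted tree
tecurate parsimony \
    --tree src/tecurate/data/piroplasmids.nwk \
    --presence src/tecurate/data/piroplasmids_presence.tsv
```

`summarize` also accepts RepeatMasker `.out` files for `--hits`.

## Notes and non-goals

- Consensus-model *construction* (RepeatModeler's job), profile-HMM and
  domain search engines, and database contents are out of scope: the
  pipeline consumes their outputs as tables.
- Screening assemblies for bacterial transposase contamination is noted but
  not implemented.
- The internal tandem detector is a stand-in; supplying TRF `.dat` records
  is the faithful path.
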