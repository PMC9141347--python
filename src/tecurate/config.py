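"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here; operations
take a :class:`PipelineConfig` rather than ad-hoc keyword thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass(frozen=True)
class PipelineConfig:
    #: redundancy clustering: link two models iff identity > this ...
    cluster_id_thresh: float = 0.90
    #: ... and alignment length / min(model lengths) > this
    cluster_cov_thresh: float = 0.90
    #: keep a model iff >= this many full-length copies in at least one genome
    min_copies: int = 3
    #: a genome hit is "full length" iff it covers >= this fraction of the model
    full_length_frac: float = 0.80
    #: discard iff exon-hit union covers strictly more than this fraction
    exon_frac_thresh: float = 0.40
    #: discard iff tandem-repeat union covers strictly more than this fraction
    tandem_frac_thresh: float = 0.40
    evalue_cluster: float = 1e-10
    evalue_known_te: float = 1e-20
    evalue_protein: float = 1e-10
    #: evidence rows overlapping low-complexity masks by more than this fraction
    #: are dropped during curation
    lowcomp_overlap_thresh: float = 0.50
    #: evidence intervals shorter than this many nt are dropped as "too short"
    min_evidence_len: int = 30
    #: DUST window score above which a window is masked; calibrated so that
    #: uniform random DNA masks < 5 percent of positions (see tests)
    dust_score_thresh: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cluster_id_thresh",
            "cluster_cov_thresh",
            "full_length_frac",
            "exon_frac_thresh",
            "tandem_frac_thresh",
            "lowcomp_overlap_thresh",
        ):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name}={value} outside (0, 1]")
        if self.min_copies < 1:
            raise ValueError("min_copies < 1")
        for name in ("evalue_cluster", "evalue_known_te", "evalue_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


DEFAULT_CONFIG = PipelineConfig()
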