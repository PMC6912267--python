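"""Core domain containers shared across the pipeline.

The objects here mirror the experimental designs the package analyses: a
reference bundle for the hierarchical small-RNA annotation cascade, planted
molecules with a 3'-terminal 2'-O-methylation fraction, the four synthetic
spike-in oligos used to calibrate periodate/beta-elimination treatment, and a
single configuration object holding every knob of the synthetic-data
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

# Fixed order of the annotation cascade: a read keeps the first database it
# hits, so earlier categories shadow later ones (miRNA shadows piRNA).
CASCADE_ORDER: tuple[str, ...] = (
    "miRNA",
    "rRNA",
    "tRNA",
    "ensembl",
    "rfam",
    "piRNA",
)

CATEGORIES: tuple[str, ...] = CASCADE_ORDER + ("unannotated",)

_RNA_TO_DNA = str.maketrans("ACGU", "ACGT")


def rna_to_dna(seq: str) -> str:
    """Convert an RNA oligo (possibly carrying ``m`` 2'-O-methyl marks) to the
    DNA-alphabet string a sequencer reports."""
    return seq.replace("m", "").translate(_RNA_TO_DNA)


@dataclass(frozen=True)
class SpikeIn:
    """One synthetic single-stranded calibration oligo."""

    name: str
    rna_sequence: str  # as synthesized; "mG" marks a 2'-O-methylated base
    methylated: bool

    @property
    def sequence(self) -> str:
        """DNA-alphabet read sequence of the oligo."""
        return rna_to_dna(self.rna_sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpikeInSet:
    """The pool of calibration oligos added at fixed molarity before
    periodate treatment: two 3'-OH (cleavable) and two 3'-2'-O-methyl
    (resistant) molecules of 22 and 28 nt."""

    spikes: tuple[SpikeIn, ...]
    molecules_per_ug: float = 0.3e10

    def __post_init__(self) -> None:
        n_meth = sum(s.methylated for s in self.spikes)
        if len(self.spikes) != 4 or n_meth != 2:
            raise ValueError(
                "spike-in set must hold exactly two methylated and two "
                "non-methylated oligos"
            )
        if sorted(len(s) for s in self.spikes) != [22, 22, 28, 28]:
            raise ValueError("spike-in lengths must be 22 and 28 nt")
        names = [s.name for s in self.spikes]
        if len(set(names)) != 4:
            raise ValueError("spike-in names must be unique")

    @property
    def methylated(self) -> tuple[SpikeIn, ...]:
        return tuple(s for s in self.spikes if s.methylated)

    @property
    def non_methylated(self) -> tuple[SpikeIn, ...]:
        return tuple(s for s in self.spikes if not s.methylated)

    def by_name(self, name: str) -> SpikeIn:
        for s in self.spikes:
            if s.name == name:
                return s
        raise KeyError(name)


def default_spikes() -> SpikeInSet:
    """The four oligos used in the assay, as synthesized (5'->3')."""
    return SpikeInSet(
        spikes=(
            SpikeIn("SS-22", "UAUCAGUGCUACGUGUCUCAGU", methylated=False),
            SpikeIn("SS-28", "CGUAUCGCUGCUCUGAGUCACUAUCUAC", methylated=False),
            SpikeIn("mSS-22", "AUGCUGAUGAUAGACGCUACUmG", methylated=True),
            SpikeIn("mSS-28", "AGAUAGUACUGAUCUGCUGCGACGAGUmG", methylated=True),
        )
    )


@dataclass
class PlantedMolecule:
    """A ground-truth small RNA emitted by the generator.

    ``methylation_fraction`` is the fraction of cellular copies carrying the
    3'-terminal 2'-O-methyl group; it drives both cloning efficiency in the
    untreated library and survival of periodate treatment.
    """

    name: str
    sequence: str
    category: str
    methylation_fraction: float
    base_abundance: float
    bound_by_piwil1: bool = False
    sticky: bool = False  # bead-background molecule, pulled down in every IP

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "piRNA" and not (20 <= len(self.sequence) <= 35):
            raise ValueError("piRNA length must be within 20-35 nt")
        if not 0.0 <= self.methylation_fraction <= 1.0:
            raise ValueError("methylation_fraction must lie in [0, 1]")
        if self.category == "miRNA" and self.methylation_fraction != 0.0:
            raise ValueError("miRNAs carry no 3' 2'-O-methyl group (m = 0)")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be strictly positive")


@dataclass(frozen=True)
class TranscriptRecord:
    """A protein-coding transcript with its 5'UTR/CDS/3'UTR spans
    (0-based, half-open, tiling the sequence exactly)."""

    transcript_id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        spans = (self.utr5, self.cds, self.utr3)
        if self.utr5[0] != 0 or self.utr3[1] != n:
            raise ValueError("region spans must cover [0, len)")
        for (a, b), (c, _) in zip(spans, spans[1:]):
            if b != c:
                raise ValueError("region spans must be contiguous")
        if any(a > b for a, b in spans):
            raise ValueError("region spans must be non-decreasing")

    def region_of(self, pos: int) -> str:
        """Region label of a transcript position (the site's 5'-most base)."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"position {pos} outside transcript")
        if pos < self.utr5[1]:
            return "utr5"
        if pos < self.cds[1]:
            return "cds"
        return "utr3"


@dataclass
class ReferenceBundle:
    """References for one simulated study: a genome (every database entry is
    a genome substring), the ordered annotation databases, and the transcript
    set used for piRISC target mapping."""

    genome: dict[str, str]
    db_list: list[tuple[str, dict[str, str]]]
    transcripts: list[TranscriptRecord]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.db_list]
        if len(set(names)) != len(names):
            raise ValueError("database names must be unique")

    @property
    def cascade_order(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.db_list)

    def transcript(self, transcript_id: str) -> TranscriptRecord:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


# Default per-category design of the generator: molecule counts, base
# abundance share of the whole library, and methylation fraction ("mix"
# means the piRNA-style three-state mixture in SimulationConfig).
DEFAULT_CATEGORY_DESIGN: Mapping[str, Mapping[str, float | int | str]] = {
    "miRNA": {"n": 30, "share": 0.45, "methylation": 0.0},
    "rRNA": {"n": 10, "share": 0.05, "methylation": 0.0},
    "tRNA": {"n": 15, "share": 0.10, "methylation": 0.5},
    "ensembl": {"n": 10, "share": 0.05, "methylation": 0.5},
    "rfam": {"n": 8, "share": 0.02, "methylation": 0.0},
    "piRNA": {"n": 60, "share": 0.20, "methylation": "mix"},
    "unannotated": {"n": 25, "share": 0.13, "methylation": "mix"},
}


@dataclass
class SimulationConfig:
    """Every knob of the synthetic study, with the study conditions as
    defaults. ``seed`` is mandatory; all sampling is reproducible from it."""

    seed: int
    depth: int = 100_000
    depth_treated: int | None = None  # defaults to ``depth``
    cleavage_efficiency: float = 0.98  # e: P(cleave a non-methylated copy)
    incorporation_bias: float = 0.5  # b: cloning eff. of methylated 3' ends
    ip_enrichment_factor: float = 16.0
    replicates: int = 3
    long_read_fraction: float = 0.05  # 46-75 nt mRNA fragments in IP reads
    spike_fraction: float = 0.06  # molar share of the 4 spikes combined
    substitution_rate: float = 0.0
    biological_cv: float = 0.1  # per-replicate abundance CV in RIP designs
    n_bound_pirnas: int = 10
    n_sticky: int = 5
    sticky_factor: float = 8.0
    n_target_transcripts: int = 10
    n_decoy_transcripts: int = 5
    n_idle_transcripts: int = 5
    abundance_sigma: float = 0.7  # lognormal spread within a category
    pirna_methylation_mix: tuple[tuple[float, float], ...] = (
        (1.0, 0.30),
        (0.5, 0.30),
        (0.0, 0.40),
    )
    category_design: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORY_DESIGN.items()}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("cleavage_efficiency", "incorporation_bias",
                     "long_read_fraction", "spike_fraction",
                     "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per RIP class")
        weights = [w for _, w in self.pirna_methylation_mix]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("pirna_methylation_mix weights must sum to 1")

    @property
    def treated_depth(self) -> int:
        return self.depth if self.depth_treated is None else self.depth_treated

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_design"] = {k: dict(v) for k, v in self.category_design.items()}
        return d


@dataclass(frozen=True)
class DepletionEstimate:
    """Spike-in-calibrated periodate depletion efficiency for non-methylated
    RNA (1 means every 3'-OH molecule was destroyed)."""

    efficiency: float
    per_spike_retention: Mapping[str, float]
    n_spike_reads: Mapping[str, Mapping[str, int]]  # library -> spike -> count


@dataclass(frozen=True)
class TargetSite:
    """One antisense complementarity site of a piRNA on a transcript."""

    pirna_sequence: str
    transcript_id: str
    start: int  # 0-based, 5'-most transcript position of the duplex
    region: str  # utr5 | cds | utr3
    mismatches: int
    seed_perfect: bool
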