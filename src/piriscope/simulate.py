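"""Synthetic-data generator with planted ground truth.

Three experimental designs are emulated so every downstream stage has a
no-download test surface:

* a periodate/beta-elimination pair (treated T vs non-treated NT small-RNA
  libraries with the four calibration spike-ins),
* a PIWIL1 RIP-Seq sample set (input, two antibodies IP1/IP2, IgG and
  no-antibody bead controls, in replicates) with a planted bound set and a
  sticky bead background,
* piRISC co-capture: 46-75 nt fragments of designated target transcripts
  present only in the IP libraries, with perfect-complement piRNA sites
  planted in 3'UTRs.

Cloning model per molecule copy (abundance ``a``, methylated fraction ``m``,
cleavage efficiency ``e``, incorporation bias ``b``):

* untreated library weight  ``w_NT = a * (m*b + (1-m))``  — methylated 3'
  ends ligate at reduced efficiency ``b`` when competing with 3'-OH ends;
* treated library weight    ``w_T  = a * (m + (1-m)*(1-e))``  — periodate
  destroys each non-methylated copy with probability ``e``; survivors clone
  at full efficiency because the competing 3'-OH pool is gone.

Reads are emitted pre-trimmed with constant qualities; sequencing error is
off by default (substitution-rate knob).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import write_fasta, write_fastq, write_tsv
from .types import (
    CASCADE_ORDER,
    PlantedMolecule,
    ReferenceBundle,
    SimulationConfig,
    SpikeInSet,
    TranscriptRecord,
    default_spikes,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Independent, named random streams derived from the one user seed.
_STREAMS = {
    "references": 11,
    "abundance": 13,
    "library_nt": 17,
    "library_t": 19,
    "rip": 23,
    "fragments": 29,
    "errors": 31,
    "cpg": 37,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return b"".join(rng.choice(_BASES, size=length)).decode()


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def expected_tn_ratio(m: float, config: SimulationConfig) -> float:
    """Expected treated/untreated molecular weight ratio of one molecule
    (before whole-library renormalization)."""
    e, b = config.cleavage_efficiency, config.incorporation_bias
    return (m + (1.0 - m) * (1.0 - e)) / (m * b + (1.0 - m))


# ---------------------------------------------------------------------------
# References and planted molecules
# ---------------------------------------------------------------------------

def _unique_seq(rng, length, taken: set[str], context: list[str]) -> str:
    """Draw a random sequence that is not contained in, and does not contain,
    anything generated so far (keeps planted categories unambiguous)."""
    haystack = "#".join(context)
    for _ in range(1000):
        s = _random_seq(rng, length)
        if s in taken or s in haystack:
            continue
        if any(t in s for t in taken if len(t) <= length):
            continue
        return s
    raise RuntimeError("could not draw a unique sequence")


def generate_molecules(config: SimulationConfig) -> list[PlantedMolecule]:
    """Planted molecules for every category with the configured abundance
    shares, within-category lognormal spread, and methylation design."""
    rng = _rng(config.seed, "abundance")
    seq_rng = _rng(config.seed, "references")
    taken: set[str] = set()
    context: list[str] = [s.sequence for s in default_spikes().spikes]
    molecules: list[PlantedMolecule] = []

    for category in CASCADE_ORDER + ("unannotated",):
        design = config.category_design[category]
        n = int(design["n"])
        share = float(design["share"])
        meth = design["methylation"]
        # lognormal relative abundances, renormalized to the category share
        rel = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
        rel = rel / rel.sum() * share
        if meth == "mix":
            # deterministic counts per methylation state (largest remainder)
            levels, weights = zip(*config.pirna_methylation_mix)
            counts = [int(round(w * n)) for w in weights]
            counts[-1] = n - sum(counts[:-1])
            m_values = [lv for lv, c in zip(levels, counts) for _ in range(c)]
        else:
            m_values = [float(meth)] * n
        for i in range(n):
            length = int(seq_rng.integers(20, 36))
            seq = _unique_seq(seq_rng, length, taken, context)
            taken.add(seq)
            molecules.append(
                PlantedMolecule(
                    name=f"{category}_{i:04d}",
                    sequence=seq,
                    category=category,
                    methylation_fraction=m_values[i],
                    base_abundance=float(rel[i]),
                )
            )

    # bound set: piRNAs pulled down by PIWIL1 in the RIP design
    pirnas = [m for m in molecules if m.category == "piRNA"]
    bound_idx = rng.choice(len(pirnas), size=config.n_bound_pirnas, replace=False)
    for i in bound_idx:
        pirnas[i].bound_by_piwil1 = True

    # sticky bead background: enriched in every pull-down incl. controls
    candidates = [m for m in molecules
                  if m.category in ("rfam", "unannotated") and not m.bound_by_piwil1]
    sticky_idx = rng.choice(len(candidates), size=config.n_sticky, replace=False)
    for i in sticky_idx:
        candidates[i].sticky = True
    return molecules


def _make_transcripts(config: SimulationConfig, molecules, rng) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Target transcripts carry one perfect reverse-complement site of a
    distinct bound piRNA inside their 3'UTR; decoys are co-captured but have
    no planted site; idle transcripts are never captured."""
    bound = [m for m in molecules if m.bound_by_piwil1]
    utr5_len, cds_len, utr3_len = 60, 180, 160
    length = utr5_len + cds_len + utr3_len
    transcripts: list[TranscriptRecord] = []
    truth_rows = []
    n_total = (config.n_target_transcripts + config.n_decoy_transcripts
               + config.n_idle_transcripts)
    for i in range(n_total):
        seq = _random_seq(rng, length)
        role = ("target" if i < config.n_target_transcripts
                else "decoy" if i < config.n_target_transcripts + config.n_decoy_transcripts
                else "idle")
        tid = f"ENST_SYN{i:05d}"
        site_start = -1
        pirna_seq = ""
        if role == "target" and bound:
            pirna = bound[i % len(bound)]
            insert = reverse_complement(pirna.sequence)
            lo = utr5_len + cds_len
            site_start = int(rng.integers(lo, length - len(insert)))
            seq = seq[:site_start] + insert + seq[site_start + len(insert):]
            pirna_seq = pirna.sequence
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                sequence=seq,
                utr5=(0, utr5_len),
                cds=(utr5_len, utr5_len + cds_len),
                utr3=(utr5_len + cds_len, length),
            )
        )
        truth_rows.append(
            {"transcript_id": tid, "role": role,
             "pirna_sequence": pirna_seq, "site_start": site_start}
        )
    return transcripts, pd.DataFrame(truth_rows)


def generate_references(
    config: SimulationConfig,
    genome_length: int | None = None,
) -> tuple[ReferenceBundle, list[PlantedMolecule], pd.DataFrame]:
    """Build the reference bundle and its ground-truth tables.

    Returns ``(bundle, molecules, truth)`` where ``truth`` has one row per
    planted molecule. The transcript ground truth is attached as
    ``truth.attrs["transcripts"]``.

    Raises ``ValueError`` if ``genome_length`` cannot hold every database
    entry plus minimal spacers.
    """
    molecules = generate_molecules(config)
    rng = _rng(config.seed, "references")

    dbs: dict[str, dict[str, str]] = {name: {} for name in CASCADE_ORDER}
    genome_parts: list[str] = []
    for mol in molecules:
        if mol.category == "unannotated":
            genome_parts.append(mol.sequence)
            continue
        if mol.category in ("rRNA", "tRNA"):
            # fragments of longer parent non-coding RNAs: exercise substring
            # (not just equality) matching in the cascade
            flank5 = _random_seq(rng, 30)
            flank3 = _random_seq(rng, 30)
            entry = flank5 + mol.sequence + flank3
        else:
            entry = mol.sequence
        dbs[mol.category][f"{mol.category}-{mol.name.split('_')[1]}"] = entry
        genome_parts.append(entry)

    required = sum(len(p) for p in genome_parts) + 20 * (len(genome_parts) + 1)
    if genome_length is not None and genome_length < required:
        raise ValueError(
            f"genome_length {genome_length} cannot hold {required} nt of "
            "database entries plus spacers"
        )

    order = rng.permutation(len(genome_parts))
    spike_seqs = [s.sequence for s in default_spikes().spikes]
    chrom_parts: list[list[str]] = [[], []]
    for k, idx in enumerate(order):
        spacer = _random_seq(rng, int(rng.integers(20, 51)))
        chrom_parts[k % 2].extend([spacer, genome_parts[idx]])
    genome = {}
    for c, parts in enumerate(chrom_parts):
        parts.append(_random_seq(rng, int(rng.integers(20, 51))))
        chrom = "".join(parts)
        if any(sp in chrom for sp in spike_seqs):  # pragma: no cover
            raise RuntimeError("spike-in sequence collided with the genome; "
                               "use a different seed")
        genome[f"chr{c + 1}"] = chrom

    transcripts, transcript_truth = _make_transcripts(config, molecules, rng)
    bundle = ReferenceBundle(
        genome=genome,
        db_list=[(name, dbs[name]) for name in CASCADE_ORDER],
        transcripts=transcripts,
    )
    truth = pd.DataFrame(
        {
            "name": [m.name for m in molecules],
            "sequence": [m.sequence for m in molecules],
            "category": [m.category for m in molecules],
            "methylation_fraction": [m.methylation_fraction for m in molecules],
            "base_abundance": [m.base_abundance for m in molecules],
            "bound_by_piwil1": [m.bound_by_piwil1 for m in molecules],
            "sticky": [m.sticky for m in molecules],
        }
    )
    truth.attrs["transcripts"] = transcript_truth
    return bundle, molecules, truth


def write_reference_bundle(bundle: ReferenceBundle, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {"genome": out_dir / "genome.fasta"}
    write_fasta(paths["genome"], bundle.genome.items())
    for name, db in bundle.db_list:
        paths[name] = out_dir / f"db_{name}.fasta"
        write_fasta(paths[name], db.items())
    paths["transcripts"] = out_dir / "transcripts.fasta"
    write_fasta(paths["transcripts"], [(t.transcript_id, t.sequence) for t in bundle.transcripts])
    regions = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in bundle.transcripts],
            "utr5_end": [t.utr5[1] for t in bundle.transcripts],
            "cds_end": [t.cds[1] for t in bundle.transcripts],
            "length": [len(t.sequence) for t in bundle.transcripts],
        }
    )
    paths["regions"] = out_dir / "transcript_regions.tsv"
    write_tsv(regions, paths["regions"])
    return paths


# ---------------------------------------------------------------------------
# Beta-elimination library pair
# ---------------------------------------------------------------------------

def library_weights(
    molecules: list[PlantedMolecule],
    spikes: SpikeInSet | None,
    config: SimulationConfig,
    treated: bool,
) -> pd.Series:
    """Expected molar cloning weight per distinct sequence."""
    e, b = config.cleavage_efficiency, config.incorporation_bias
    seqs, weights = [], []
    total_abundance = sum(m.base_abundance for m in molecules)
    for mol in molecules:
        m = mol.methylation_fraction
        w = m + (1.0 - m) * (1.0 - e) if treated else m * b + (1.0 - m)
        seqs.append(mol.sequence)
        weights.append(mol.base_abundance * w)
    if spikes is not None:
        per_spike = config.spike_fraction / 4.0 * total_abundance
        for s in spikes.spikes:
            m = 1.0 if s.methylated else 0.0
            w = m + (1.0 - m) * (1.0 - e) if treated else m * b + (1.0 - m)
            seqs.append(s.sequence)
            weights.append(per_spike * w)
    return pd.Series(weights, index=pd.Index(seqs, name="sequence"), dtype=float)


def simulate_counts(
    weights: pd.Series, depth: int, rng: np.random.Generator
) -> pd.Series:
    """Multinomial read counts at exactly ``depth`` total reads."""
    p = weights.to_numpy()
    p = p / p.sum()
    return pd.Series(rng.multinomial(depth, p), index=weights.index, name="count")


def _counts_to_reads(counts: pd.Series, prefix: str, rng=None, sub_rate: float = 0.0):
    i = 0
    for seq, n in counts.items():
        for _ in range(int(n)):
            out = seq
            if sub_rate > 0.0 and rng is not None:
                arr = np.frombuffer(out.encode(), dtype="S1").copy()
                hit = rng.random(len(arr)) < sub_rate
                if hit.any():
                    arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
                    out = b"".join(arr).decode()
            yield f"{prefix}_{i}", out
            i += 1


def simulate_library(
    bundle: ReferenceBundle,
    molecules: list[PlantedMolecule],
    spikes: SpikeInSet | None,
    config: SimulationConfig,
    treated: bool,
    path: str | Path | None = None,
) -> pd.Series:
    """Simulate one small-RNA library; optionally write it as FASTQ.

    Returns the per-sequence read counts (total equals the configured depth).
    """
    depth = config.treated_depth if treated else config.depth
    if depth <= 0:
        raise ValueError("library depth must be positive")
    stream = "library_t" if treated else "library_nt"
    rng = _rng(config.seed, stream)
    weights = library_weights(molecules, spikes, config, treated)
    counts = simulate_counts(weights, depth, rng)
    if path is not None:
        err_rng = _rng(config.seed, "errors") if config.substitution_rate > 0 else None
        label = "T" if treated else "NT"
        write_fastq(
            path,
            _counts_to_reads(counts, label, err_rng, config.substitution_rate),
        )
    return counts


def simulate_methylation_pair(
    bundle: ReferenceBundle,
    molecules: list[PlantedMolecule],
    config: SimulationConfig,
    spikes: SpikeInSet | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Untreated (NT) and periodate-treated (T) libraries with spike-ins."""
    spikes = spikes or default_spikes()
    nt_path = t_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        nt_path, t_path = out_dir / "NT.fastq", out_dir / "T.fastq"
    nt = simulate_library(bundle, molecules, spikes, config, treated=False, path=nt_path)
    t = simulate_library(bundle, molecules, spikes, config, treated=True, path=t_path)
    return nt, t


# ---------------------------------------------------------------------------
# RIP-Seq sample set
# ---------------------------------------------------------------------------

RIP_CLASSES = ("input", "IP1", "IP2", "IgG", "NoAb")


def rip_sample_classes(config: SimulationConfig) -> dict[str, str]:
    """Column name -> sample class for the full RIP design."""
    return {
        f"{cls}_rep{r + 1}": cls
        for cls in RIP_CLASSES
        for r in range(config.replicates)
    }


def _fragment_reads(
    transcripts: list[TranscriptRecord],
    truth: pd.DataFrame,
    n_frag: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Draw 46-75 nt fragments of co-captured (target + decoy) transcripts."""
    captured = [t for t, role in zip(transcripts, truth["role"])
                if role in ("target", "decoy")]
    if not captured or n_frag == 0:
        return pd.Series(dtype=int)
    idx = rng.integers(0, len(captured), size=n_frag)
    lengths = rng.integers(46, 76, size=n_frag)
    frags: dict[str, int] = {}
    for i, L in zip(idx, lengths):
        t = captured[i]
        start = int(rng.integers(0, len(t.sequence) - int(L) + 1))
        s = t.sequence[start:start + int(L)]
        frags[s] = frags.get(s, 0) + 1
    return pd.Series(frags, dtype=int)


def simulate_rip_counts(
    bundle: ReferenceBundle,
    molecules: list[PlantedMolecule],
    config: SimulationConfig,
    transcript_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read-count matrix (sequences x samples) for the full RIP design.

    IP1/IP2 pull bound molecules up by ``ip_enrichment_factor``; all four
    bead pull-downs (IP1, IP2, IgG, NoAb) additionally pull the sticky
    background up by ``sticky_factor``; IP libraries devote
    ``long_read_fraction`` of their reads to 46-75 nt fragments of the
    co-captured transcripts.
    """
    if not any(m.bound_by_piwil1 for m in molecules):
        warnings.warn("no bound molecules configured; RIP design is null")
    rng = _rng(config.seed, "rip")
    frag_rng = _rng(config.seed, "fragments")
    classes = rip_sample_classes(config)

    base = np.array([m.base_abundance * (m.methylation_fraction * config.incorporation_bias
                                         + (1.0 - m.methylation_fraction))
                     for m in molecules])
    bound = np.array([m.bound_by_piwil1 for m in molecules])
    sticky = np.array([m.sticky for m in molecules])
    seq_index = pd.Index([m.sequence for m in molecules], name="sequence")

    columns: dict[str, pd.Series] = {}
    cv2 = config.biological_cv ** 2
    for sample, cls in classes.items():
        w = base.copy()
        if cls in ("IP1", "IP2"):
            w = w * np.where(bound, config.ip_enrichment_factor, 1.0)
        if cls in ("IP1", "IP2", "IgG", "NoAb"):
            w = w * np.where(sticky, config.sticky_factor, 1.0)
        if cv2 > 0:
            w = w * rng.gamma(shape=1.0 / cv2, scale=cv2, size=len(w))
        depth = config.depth
        n_frag = 0
        if cls in ("IP1", "IP2") and config.long_read_fraction > 0:
            n_frag = int(round(depth * config.long_read_fraction))
        counts = simulate_counts(pd.Series(w, index=seq_index), depth - n_frag, rng)
        if n_frag and transcript_truth is not None:
            frags = _fragment_reads(bundle.transcripts, transcript_truth, n_frag, frag_rng)
            counts = pd.concat([counts, frags])
        columns[sample] = counts

    matrix = pd.DataFrame(columns).fillna(0).astype(int)
    matrix.index.name = "sequence"
    return matrix, classes


def simulate_rip_libraries(
    bundle: ReferenceBundle,
    molecules: list[PlantedMolecule],
    config: SimulationConfig,
    out_dir: str | Path,
    transcript_truth: pd.DataFrame | None = None,
) -> tuple[dict[str, Path], pd.DataFrame, dict[str, str]]:
    """Write one FASTQ per RIP sample; returns paths, counts, classes."""
    matrix, classes = simulate_rip_counts(bundle, molecules, config, transcript_truth)
    out_dir = Path(out_dir)
    paths = {}
    for sample in matrix.columns:
        counts = matrix[sample]
        counts = counts[counts > 0]
        paths[sample] = out_dir / f"{sample}.fastq"
        write_fastq(paths[sample], _counts_to_reads(counts, sample))
    return paths, matrix, classes


# ---------------------------------------------------------------------------
# Promoter CpG methylation dataset
# ---------------------------------------------------------------------------

# CpG probes in the PIWIL1 promoter/first-exon island assayed on Infinium
# arrays; used as site labels for the default 6-site synthetic matrix.
PIWIL1_CPG_SITES = (
    "cg24838063", "cg26677194", "cg23887609",
    "cg02382037", "cg23548151", "cg13900773",
)


def simulate_cpg_dataset(
    seed: int,
    n_tumor: int = 100,
    n_normal: int = 20,
    n_sites: int = 6,
    hypo_fraction: float = 0.14,
    delta: float = 0.55,
    noise: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Synthetic beta-value matrix with a planted hypomethylated tumor
    subgroup whose expression rises as promoter methylation falls.

    Returns ``(beta, sample_class, expression, hypo_truth)``.
    """
    rng = _rng(seed, "cpg")
    sites = list(PIWIL1_CPG_SITES[:n_sites])
    sites += [f"cg_syn{i:07d}" for i in range(max(0, n_sites - len(sites)))]
    samples = [f"N{i:03d}" for i in range(n_normal)] + [f"T{i:03d}" for i in range(n_tumor)]
    klass = pd.Series(["normal"] * n_normal + ["tumor"] * n_tumor, index=samples, name="class")

    n_hypo = int(round(hypo_fraction * n_tumor))
    hypo = np.zeros(n_normal + n_tumor, dtype=bool)
    hypo_idx = n_normal + rng.choice(n_tumor, size=n_hypo, replace=False)
    hypo[hypo_idx] = True

    high = 0.85
    beta = rng.normal(high, noise, size=(len(samples), len(sites)))
    beta[hypo, :] = rng.normal(high - delta, noise * 1.5, size=(n_hypo, len(sites)))
    beta = np.clip(beta, 0.0, 1.0)
    beta_df = pd.DataFrame(beta, index=samples, columns=sites)

    # expression anti-correlates with island-mean methylation
    expr = 8.0 - 5.0 * beta_df.mean(axis=1) + rng.normal(0.0, 0.3, size=len(samples))
    expr = pd.Series(expr, index=samples, name="expression")
    return beta_df, klass, expr, pd.Series(hypo, index=samples, name="hypomethylated")
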