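"""End-to-end orchestration: simulate -> annotate -> methylation / RIP /
targets / promoter -> report, with a machine-readable run manifest.

A run is configured by one YAML (or dict): a mandatory seed, an output
directory, the stage list, and per-stage parameter blocks. Outputs are plain
TSV/JSON plus FASTA/FASTQ; the manifest records the config snapshot, seed,
per-stage output checksums and timings, so reruns with an identical config
reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import methylation as meth
from . import promoter as prom
from . import rip
from . import simulate as sim
from . import targets as tgt
from .io import read_fasta, read_tsv, sha256_of, write_tsv
from .types import CASCADE_ORDER, ReferenceBundle, SimulationConfig, TranscriptRecord, default_spikes

STAGES = ("simulate", "annotate", "methylation", "rip", "targets", "promoter")

_TOP_KEYS = {"seed", "out_dir", "stages", "simulation", "annotate",
             "methylation", "rip", "targets", "promoter", "inputs"}


class ConfigError(ValueError):
    """Run configuration violates the schema."""


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, (str, Path)):
        with Path(source).open() as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(source)
    if not isinstance(config, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ConfigError("config requires a seed")
    stages = config.get("stages", list(STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")
    config["stages"] = stages
    return config


def load_reference_bundle(ref_dir: str | Path) -> ReferenceBundle:
    """Rebuild a ReferenceBundle from a directory written by the simulate
    stage (genome.fasta, db_<name>.fasta, transcripts.fasta, regions TSV)."""
    ref_dir = Path(ref_dir)
    genome = read_fasta(ref_dir / "genome.fasta")
    db_list = []
    for name in CASCADE_ORDER:
        path = ref_dir / f"db_{name}.fasta"
        if path.exists():
            db_list.append((name, read_fasta(path)))
    seqs = read_fasta(ref_dir / "transcripts.fasta")
    regions = read_tsv(ref_dir / "transcript_regions.tsv").set_index("transcript_id")
    transcripts = []
    for tid, seq in seqs.items():
        row = regions.loc[tid]
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                sequence=seq,
                utr5=(0, int(row["utr5_end"])),
                cds=(int(row["utr5_end"]), int(row["cds_end"])),
                utr3=(int(row["cds_end"]), int(row["length"])),
            )
        )
    return ReferenceBundle(genome=genome, db_list=db_list, transcripts=transcripts)


def _checksum_dir(paths: list[Path]) -> dict[str, str]:
    return {str(p): sha256_of(p) for p in sorted(paths)}


def run_pipeline(
    config: str | Path | dict, out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written as ``manifest.json``); the main
    computed quantities are aggregated in ``summary.json``.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir or cfg.get("out_dir", "piriscope_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]

    manifest: dict = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "config": _jsonable(cfg),
        "stages": {},
    }
    summary: dict = {}
    state: dict = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        runner = _STAGE_RUNNERS[stage]
        try:
            outputs = runner(cfg, out, state, summary)
        except (ConfigError, FileNotFoundError):
            raise  # configuration and missing-input errors keep their type
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": _checksum_dir(outputs),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    with (out / "summary.json").open("w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    with (out / "manifest.json").open("w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# Stage runners: cfg, out dir, shared state, summary -> list of output paths
# ---------------------------------------------------------------------------

def _sim_config(cfg: dict) -> SimulationConfig:
    params = dict(cfg.get("simulation", {}))
    params.setdefault("seed", cfg["seed"])
    return SimulationConfig(**params)


def _run_simulate(cfg, out, state, summary):
    config = _sim_config(cfg)
    bundle, molecules, truth = sim.generate_references(config)
    ref_dir = out / "references"
    paths = list(sim.write_reference_bundle(bundle, ref_dir).values())
    truth_path = ref_dir / "molecule_truth.tsv"
    write_tsv(truth, truth_path)
    t_truth_path = ref_dir / "transcript_truth.tsv"
    write_tsv(truth.attrs["transcripts"], t_truth_path)
    paths += [truth_path, t_truth_path]

    lib_dir = out / "libraries"
    sim.simulate_methylation_pair(bundle, molecules, config, out_dir=lib_dir)
    rip_paths, _, classes = sim.simulate_rip_libraries(
        bundle, molecules, config, lib_dir, truth.attrs["transcripts"]
    )
    paths += [lib_dir / "NT.fastq", lib_dir / "T.fastq"] + list(rip_paths.values())

    prom_params = dict(cfg.get("promoter", {}))
    beta, klass, expr, hypo = sim.simulate_cpg_dataset(
        seed=config.seed,
        n_tumor=int(prom_params.get("n_tumor", 100)),
        n_normal=int(prom_params.get("n_normal", 20)),
        hypo_fraction=float(prom_params.get("hypo_fraction", 0.14)),
    )
    cpg_dir = out / "cpg"
    beta_path, expr_path = cpg_dir / "beta.tsv", cpg_dir / "expression.tsv"
    write_tsv(beta.rename_axis("sample"), beta_path, index=True)
    df = pd.DataFrame({"class": klass, "expression": expr, "hypomethylated": hypo})
    write_tsv(df.rename_axis("sample"), expr_path, index=True)
    paths += [beta_path, expr_path]

    state.update(
        bundle=bundle, molecules=molecules, truth=truth, config=config,
        lib_dir=lib_dir, ref_dir=ref_dir, classes=classes,
        beta=beta, sample_class=klass, expression=expr,
    )
    summary["simulate"] = {
        "n_molecules": len(molecules),
        "n_transcripts": len(bundle.transcripts),
        "depth": config.depth,
    }
    return paths


def _ensure_refs(cfg, state):
    if "bundle" not in state:
        inputs = cfg.get("inputs", {})
        if "references" not in inputs:
            raise ConfigError("no simulate stage and no inputs.references")
        state["bundle"] = load_reference_bundle(inputs["references"])
    if "lib_dir" not in state:
        inputs = cfg.get("inputs", {})
        if "libraries" not in inputs:
            raise ConfigError("no simulate stage and no inputs.libraries")
        lib_dir = Path(inputs["libraries"])
        if not lib_dir.exists():
            raise FileNotFoundError(f"library directory not found: {lib_dir}")
        state["lib_dir"] = lib_dir


def _run_annotate(cfg, out, state, summary):
    _ensure_refs(cfg, state)
    params = cfg.get("annotate", {})
    window = (int(params.get("len_min", 18)), int(params.get("len_max", 45)))
    mism = int(params.get("mismatches", 0))
    cpm_min = float(params.get("cpm_min", 0.1))
    lib_dir = Path(state["lib_dir"])
    fastqs = sorted(lib_dir.glob("*.fastq"))
    if not fastqs:
        raise FileNotFoundError(f"no FASTQ libraries under {lib_dir}")
    tables = {p.stem: ann.collapse_reads(p, window, sample=p.stem) for p in fastqs}
    merged = ann.compute_cpm(ann.merge_tables(tables))
    annotated = ann.cascade_annotate(merged, state["bundle"], mismatches=mism)
    expressed = ann.filter_expressed(annotated, cpm_min)
    composition = ann.category_composition(annotated)

    ann_dir = out / "annotation"
    paths = [ann_dir / "annotation.tsv", ann_dir / "expressed.tsv",
             ann_dir / "composition.tsv"]
    write_tsv(annotated, paths[0], index=True)
    write_tsv(expressed, paths[1], index=True)
    write_tsv(composition.rename_axis("category"), paths[2], index=True)

    state.update(annotated=annotated, expressed=expressed, tables=tables,
                 composition=composition)
    summary["annotate"] = {
        "n_sequences": int(len(annotated)),
        "n_expressed": int(len(expressed)),
        "category_composition": {
            s: composition[s].to_dict() for s in composition.columns
        },
    }
    return paths


def _single_sample(tables: dict, name: str) -> pd.DataFrame:
    if name not in tables:
        raise FileNotFoundError(f"library {name!r} missing from inputs")
    return ann.compute_cpm(tables[name])


def _require(state, key, needed_by, provider):
    if key not in state:
        raise ConfigError(f"stage {needed_by!r} requires stage {provider!r}")


def _run_methylation(cfg, out, state, summary):
    params = cfg.get("methylation", {})
    _require(state, "tables", "methylation", "annotate")
    spikes = default_spikes()
    nt = _single_sample(state["tables"], "NT")
    t = _single_sample(state["tables"], "T")
    depletion = meth.estimate_depletion_efficiency(nt, t, spikes)
    calls = meth.classify_methylation(
        nt, t, annotations=state.get("annotated"),
        categories=tuple(params.get("categories", ("piRNA",))),
        alpha=float(params.get("alpha", 0.01)),
        pseudocount=float(params.get("pseudocount", 0.5)),
    )
    comp = state.get("composition")
    msum = meth.summarize_methylation(
        calls,
        nt_composition=None if comp is None else comp.get("NT"),
        t_composition=None if comp is None else comp.get("T"),
    )
    meth_dir = out / "methylation"
    paths = [meth_dir / "methylation_calls.tsv"]
    write_tsv(calls.rename_axis("sequence"), paths[0], index=True)
    state["methylation_calls"] = calls
    summary["methylation"] = {
        "depletion_efficiency": depletion.efficiency,
        "per_spike_retention": dict(depletion.per_spike_retention),
        **msum,
    }
    return paths


def _rip_classes(tables: dict) -> dict[str, str]:
    return {name: name.split("_rep")[0] for name in tables if "_rep" in name}


def _run_rip(cfg, out, state, summary):
    params = cfg.get("rip", {})
    _require(state, "tables", "rip", "annotate")
    classes = _rip_classes(state["tables"])
    if not classes:
        raise ConfigError("no RIP libraries (sample_repN) found")
    counts = ann.merge_tables({n: state["tables"][n] for n in classes})
    counts.columns = [c[6:] for c in counts.columns]
    results = rip.identify_bound(
        counts, classes, annotations=state.get("annotated"),
        lfc_min=float(params.get("lfc_min", rip.DEFAULT_LFC_MIN)),
        fdr_max=float(params.get("fdr_max", rip.DEFAULT_FDR_MAX)),
        exclude_igg=bool(params.get("exclude_igg", False)),
    )
    rip_dir = out / "rip"
    paths = [rip_dir / "enrichment.tsv"]
    write_tsv(results.rename_axis("sequence"), paths[0], index=True)
    state.update(rip_results=results, rip_classes=classes)
    breakdown = (rip.bound_category_breakdown(results)
                 if "category" in results.columns else {})
    bound = results[results["bound"]]
    summary["rip"] = {
        "n_bound": int(results["bound"].sum()),
        "n_excluded_by_control": results.attrs["n_excluded_by_control"],
        "bound_by_category": breakdown,
        "enrichment_factor_range": (
            [float(bound["factor_pooled"].min()), float(bound["factor_pooled"].max())]
            if len(bound) else []
        ),
    }
    return paths


def _run_targets(cfg, out, state, summary):
    params = cfg.get("targets", {})
    _ensure_refs(cfg, state)
    lib_dir = Path(state["lib_dir"])
    classes = state.get("rip_classes") or _rip_classes(
        {p.stem: None for p in lib_dir.glob("*.fastq")}
    )
    long_tables = {
        name: tgt.extract_long_reads(lib_dir / f"{name}.fastq", sample=name)
        for name in classes
    }
    merged = ann.merge_tables(long_tables)
    matrix = tgt.map_to_transcripts(
        merged, state["bundle"].transcripts,
        mismatches=int(params.get("mismatches", 0)),
    )
    tr_results = tgt.test_transcript_enrichment(
        matrix, classes,
        lfc_min=float(params.get("lfc_min", rip.DEFAULT_LFC_MIN)),
        fdr_max=float(params.get("fdr_max", rip.DEFAULT_FDR_MAX)),
    )
    enriched = tr_results.index[tr_results["bound"]]

    rip_results = state.get("rip_results")
    if rip_results is not None and "category" in rip_results.columns:
        bound_pirnas = rip_results.index[
            rip_results["bound"] & (rip_results["category"] == "piRNA")
        ]
    elif rip_results is not None:
        bound_pirnas = rip_results.index[rip_results["bound"]]
    else:
        bound_pirnas = pd.Index([])
    bound_pirnas = [s for s in bound_pirnas if 20 <= len(s) <= 35]

    pairs, sites, region_summary = tgt.pair_pirna_targets(
        bound_pirnas, enriched, state["bundle"].transcripts,
        fold_enrichment=tr_results,
        seed_start=int(params.get("seed_start", 2)),
        seed_end=int(params.get("seed_end", 11)),
        min_complementarity=float(params.get("min_complementarity", 0.8)),
        wobble=bool(params.get("wobble", True)),
    )
    tgt_dir = out / "targets"
    paths = [tgt_dir / "transcript_enrichment.tsv", tgt_dir / "pairs.tsv",
             tgt_dir / "sites.tsv", tgt_dir / "region_summary.json"]
    write_tsv(tr_results.rename_axis("transcript_id"), paths[0], index=True)
    write_tsv(pairs, paths[1])
    write_tsv(sites, paths[2])
    paths[3].parent.mkdir(parents=True, exist_ok=True)
    with paths[3].open("w") as fh:
        json.dump(_jsonable(region_summary), fh, indent=2, sort_keys=True)
    state.update(pairs=pairs, sites=sites)
    summary["targets"] = {
        "n_enriched_transcripts": int(len(enriched)),
        "n_pairs": int(len(pairs)),
        "n_pirnas_in_pairs": int(pairs["pirna_sequence"].nunique()) if len(pairs) else 0,
        "region_site_counts": region_summary,
    }
    return paths


def _run_promoter(cfg, out, state, summary):
    params = cfg.get("promoter", {})
    if "beta" not in state:
        inputs = cfg.get("inputs", {})
        if "beta" not in inputs or "expression" not in inputs:
            raise ConfigError("no simulate stage and no inputs.beta/expression")
        beta = read_tsv(inputs["beta"], index_col=0)
        meta = read_tsv(inputs["expression"], index_col=0)
        state.update(beta=beta, sample_class=meta["class"],
                     expression=meta["expression"])
    hypo = prom.detect_hypomethylated_sites(
        state["beta"], state["sample_class"],
        delta_min=float(params.get("delta_min", 0.3)),
        frac_min=float(params.get("frac_min", 0.10)),
    )
    corr = prom.correlate_methylation_expression(
        state["beta"], state["expression"],
        r_max=float(params.get("r_max", -0.2)),
        alpha=float(params.get("alpha", 0.01)),
    )
    prom_dir = out / "promoter"
    paths = [prom_dir / "hypomethylation.tsv", prom_dir / "correlation.tsv"]
    write_tsv(hypo, paths[0], index=True)
    write_tsv(corr, paths[1], index=True)
    summary["promoter"] = {
        "n_sites_flagged": int(hypo["flagged"].sum()),
        "hypomethylated_fraction_mean": float(hypo["hypomethylated_fraction"].mean()),
        "n_sites_passing_correlation_gate": int(corr["passes"].sum()),
        "pearson_r_mean": float(corr["pearson_r"].mean()),
    }
    return paths


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "annotate": _run_annotate,
    "methylation": _run_methylation,
    "rip": _run_rip,
    "targets": _run_targets,
    "promoter": _run_promoter,
}


def demo_config(seed: int = 1, out_dir: str | Path = "piriscope_demo") -> dict:
    """A small end-to-end configuration (reduced depth for quick runs)."""
    return {
        "seed": int(seed),
        "out_dir": str(out_dir),
        "stages": list(STAGES),
        "simulation": {"depth": 20000},
    }
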