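"""Spike-in-calibrated periodate depletion efficiency and per-piRNA
3'-methylation-state classification.

The treated/non-treated (T/NT) design: periodate oxidation plus
beta-elimination destroys the 3' end of RNAs with free 2',3'-OH, so they
drop out of the treated library, while 2'-O-methylated 3' ends resist.
Each molecule's log2(T/NT) CPM ratio therefore reads out its methylation
state: strongly positive = methylated, strongly negative = non-methylated,
intermediate = partially methylated. The two methylated spike-ins act as
internal anchors for the treatment-efficiency estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DepletionEstimate, SpikeInSet

METHYLATION_CATEGORIES = ("methylated", "partially_methylated", "non_methylated")


def _counts_and_cpm(table: pd.DataFrame) -> tuple[pd.Series, pd.Series, int]:
    count_cols = [c for c in table.columns if c.startswith("count_")]
    cpm_cols = [c for c in table.columns if c.startswith("cpm_")]
    if len(count_cols) != 1:
        raise ValueError("expected a single-sample collapsed table")
    counts = table[count_cols[0]]
    total = int(counts.sum())
    if cpm_cols:
        cpm = table[cpm_cols[0]]
    else:
        cpm = counts * 1e6 / total
    return counts, cpm, total


def spike_read_counts(table: pd.DataFrame, spikes: SpikeInSet) -> dict[str, int]:
    """Exact-sequence spike-in read counts in a collapsed table."""
    counts, _, _ = _counts_and_cpm(table)
    return {
        s.name: int(counts.get(s.sequence, 0)) for s in spikes.spikes
    }


def estimate_depletion_efficiency(
    nt_table: pd.DataFrame,
    t_table: pd.DataFrame,
    spikes: SpikeInSet,
    bias_correction: bool = True,
) -> DepletionEstimate:
    """Depletion efficiency of non-methylated RNA from spike-in abundances.

    Retention of each 3'-OH spike is its treated/untreated count ratio
    normalized to the methylated spike-ins (internal anchors, chemically
    inert under periodate):

        retention = (t / t_meth_total) / (nt / nt_meth_total)

    Methylated 3' ends ligate at reduced efficiency only while competing
    with 3'-OH ends, i.e. in the untreated library; the raw double ratio is
    therefore scaled by the cloning bias. Because the spike pool is
    equimolar, that bias is itself measurable as the untreated
    methylated/non-methylated spike count ratio and is divided out
    (``bias_correction``). efficiency = 1 - mean retention, clamped to
    [0, 1].
    """
    nt_counts = spike_read_counts(nt_table, spikes)
    t_counts = spike_read_counts(t_table, spikes)

    for s in spikes.spikes:
        if nt_counts[s.name] == 0:
            raise ValueError(f"spike-in {s.name} not found in the untreated library")
    nt_anchor = sum(nt_counts[s.name] for s in spikes.methylated)
    t_anchor = sum(t_counts[s.name] for s in spikes.methylated)
    if nt_anchor == 0 or t_anchor == 0:
        raise ValueError("methylated spike-in anchors have zero reads")

    if bias_correction:
        nt_nm = np.mean([nt_counts[s.name] for s in spikes.non_methylated])
        cloning_bias = (nt_anchor / len(spikes.methylated)) / nt_nm
    else:
        cloning_bias = 1.0

    retention = {}
    for s in spikes.non_methylated:
        double_ratio = (t_counts[s.name] / t_anchor) / (
            nt_counts[s.name] / nt_anchor
        )
        retention[s.name] = double_ratio / cloning_bias
    efficiency = float(np.clip(1.0 - np.mean(list(retention.values())), 0.0, 1.0))
    return DepletionEstimate(
        efficiency=efficiency,
        per_spike_retention=retention,
        n_spike_reads={"NT": nt_counts, "T": t_counts},
    )


def classify_methylation(
    nt_table: pd.DataFrame,
    t_table: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    categories: tuple[str, ...] = ("piRNA",),
    alpha: float = 0.01,
    pseudocount: float = 0.5,
    expression_floor: float = 0.1,
    log2_threshold: float = 2.0,
    adjust: str = "fdr_bh",
    drop_nonsignificant: bool = False,
) -> pd.DataFrame:
    """Three-way 3'-methylation call per molecule from the T/NT pair.

    A molecule enters classification if it is annotated to one of
    ``categories`` (when annotations are given) and expressed above
    ``expression_floor`` CPM in the untreated library. The log2(T/NT) CPM
    ratio (with pseudocount) is thresholded at +/- ``log2_threshold`` with
    strict inequalities — boundary values fall in ``partially_methylated`` —
    and molecules whose count change is not significant (exact conditional
    binomial test on T vs NT counts, BH-adjusted, gate at ``alpha``) are
    conservatively called ``partially_methylated`` (or dropped when
    ``drop_nonsignificant``).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    nt_counts, nt_cpm, nt_total = _counts_and_cpm(nt_table)
    t_counts, t_cpm, t_total = _counts_and_cpm(t_table)

    universe = nt_cpm[nt_cpm > expression_floor].index
    if annotations is not None:
        keep = annotations.index[annotations["category"].isin(categories)]
        universe = universe.intersection(keep)
    universe = universe.sort_values()

    nt_c = nt_counts.reindex(universe).fillna(0).astype(int)
    t_c = t_counts.reindex(universe).fillna(0).astype(int)
    nt_x = nt_cpm.reindex(universe).fillna(0.0)
    t_x = t_cpm.reindex(universe).fillna(0.0)

    log2_ratio = np.log2((t_x + pseudocount) / (nt_x + pseudocount))

    # exact conditional test: given n = t + nt reads of this molecule, the
    # treated share is Binomial(n, t_total / (t_total + nt_total)) under no
    # treatment effect
    p0 = t_total / (t_total + nt_total)
    pvals = np.array([
        stats.binomtest(int(t), int(t) + int(n), p0).pvalue if (t + n) > 0 else 1.0
        for t, n in zip(t_c, nt_c)
    ])
    if adjust == "none" or len(pvals) == 0:
        qvals = pvals.copy()
    else:
        qvals = multipletests(pvals, method=adjust)[1]

    category = np.where(
        log2_ratio > log2_threshold, "methylated",
        np.where(log2_ratio < -log2_threshold, "non_methylated",
                 "partially_methylated"),
    )
    significant = qvals < alpha
    category = np.where(significant, category, "partially_methylated")

    calls = pd.DataFrame(
        {
            "nt_count": nt_c,
            "t_count": t_c,
            "nt_cpm": nt_x,
            "t_cpm": t_x,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
            "q_value": qvals,
            "significant": significant,
            "category": category,
        },
        index=universe,
    )
    if drop_nonsignificant:
        calls = calls[calls["significant"]]
    calls.attrs["alpha"] = alpha
    calls.attrs["log2_threshold"] = log2_threshold
    return calls


def summarize_methylation(
    calls: pd.DataFrame,
    detection_floor: float = 0.1,
    nt_composition: pd.Series | None = None,
    t_composition: pd.Series | None = None,
) -> dict:
    """Category counts/fractions, treated-detectability, and (optionally)
    the T-vs-NT fold change of each annotation category's library share."""
    counts = calls["category"].value_counts().reindex(
        METHYLATION_CATEGORIES
    ).fillna(0).astype(int)
    n = int(counts.sum())
    summary = {
        "n_classified": n,
        "counts": counts.to_dict(),
        "fractions": (counts / n).to_dict() if n else {k: 0.0 for k in METHYLATION_CATEGORIES},
        "detectable_in_treated_fraction": float((calls["t_cpm"] > detection_floor).mean()) if n else 0.0,
    }
    if nt_composition is not None and t_composition is not None:
        cats = nt_composition.index.union(t_composition.index)
        nt = nt_composition.reindex(cats).fillna(0.0)
        t = t_composition.reindex(cats).fillna(0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = (t / nt).replace([np.inf, -np.inf], np.nan)
        summary["category_share_fold_change"] = fc.dropna().to_dict()
    return summary
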