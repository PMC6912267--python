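"""PIWIL1 RIP-Seq enrichment analysis.

Bound molecules are those enriched over the input lysate in both
independent-antibody pull-downs (IP1 and IP2) at log2 FC > 2 and FDR < 0.01,
minus anything also enriched in the no-antibody bead control.

Counts are compared with a negative-binomial exact test: a common dispersion
is estimated across molecules by the method of moments, replicate counts are
normalized, summed per class, and the class split is tested conditionally on
the pair total (Poisson/binomial limit when the dispersion vanishes).
Normalization defaults to median-of-ratios size factors: under a fixed
sequencing depth a strong pull-down depresses every unbound molecule's share
of the IP library, and scaling on the unbound majority removes that
compositional distortion from fold changes and enrichment factors
(``normalization="total"`` gives plain CPM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_LFC_MIN = 2.0
DEFAULT_FDR_MAX = 0.01
DEFAULT_PSEUDOCOUNT = 0.5

_MAX_DISPERSION = 10.0


class DesignError(ValueError):
    """Invalid RIP statistical design (e.g. fewer than 2 replicates)."""


def _class_columns(classes: dict[str, str], cls: str) -> list[str]:
    return [c for c, k in classes.items() if k == cls]


def size_factors(counts: pd.DataFrame, method: str = "median_ratio") -> pd.Series:
    """Per-sample scaling factors.

    ``median_ratio``: DESeq-style median of per-molecule ratios to the
    geometric-mean reference sample (computed on molecules observed in every
    sample). ``total``: library totals (plain CPM scaling). Factors are
    normalized to geometric mean 1.
    """
    if method == "total":
        sf = counts.sum(axis=0).astype(float)
    elif method == "median_ratio":
        mat = counts.to_numpy(dtype=float)
        positive = (mat > 0).all(axis=1)
        if positive.sum() < 10:
            sf = counts.sum(axis=0).astype(float)  # too sparse; fall back
        else:
            logs = np.log(mat[positive])
            ref = logs.mean(axis=1, keepdims=True)
            sf = pd.Series(
                np.exp(np.median(logs - ref, axis=0)), index=counts.columns
            )
    else:
        raise ValueError(f"unknown normalization {method!r}")
    # empty libraries (e.g. a class that cannot contain the molecule type at
    # all) get a neutral factor so downstream ratios stay finite
    valid = sf > 0
    if not valid.any():
        return pd.Series(1.0, index=counts.columns)
    fill = float(np.exp(np.log(sf[valid]).mean()))
    sf = sf.where(valid, fill)
    sf = sf / np.exp(np.log(sf).mean())
    return sf


def normalized_cpm(counts: pd.DataFrame, method: str = "median_ratio") -> pd.DataFrame:
    """Counts rescaled by size factors onto a common per-million scale."""
    sf = size_factors(counts, method)
    norm = counts / sf
    mean_total = norm.sum(axis=0).mean()
    scale = 1e6 / mean_total if mean_total > 0 else 0.0
    return norm * scale


def estimate_common_dispersion(
    counts: pd.DataFrame, classes: dict[str, str], method: str = "median_ratio"
) -> float:
    """Method-of-moments common NB dispersion phi (Var = mu + phi * mu^2),
    pooled across molecules and sample classes."""
    norm = counts / size_factors(counts, method)
    num, den = [], []
    for cls in sorted(set(classes.values())):
        cols = _class_columns(classes, cls)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = mu >= 1.0
        num.append((v[ok] - mu[ok]))
        den.append(mu[ok] ** 2)
    if not num:
        return 0.0
    num_all, den_all = np.concatenate(num), np.concatenate(den)
    if den_all.sum() <= 0:
        return 0.0
    phi = float(num_all.sum() / den_all.sum())
    return float(np.clip(phi, 0.0, _MAX_DISPERSION))


def _nb_exact_pvalue(y_a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for the class split of a pair total ``t``.

    Under the null, the class-A sum of ``n_a`` NB replicates with common
    per-replicate mean splits the conditional distribution of
    (Y_A | Y_A + Y_B = t); two-sided p sums every outcome no more probable
    than the observed one.
    """
    if t == 0:
        return 1.0
    q = n_a / (n_a + n_b)
    k = np.arange(t + 1)
    if phi < 1e-9:
        logp = stats.binom.logpmf(k, t, q)
    else:
        mu_a, mu_b = t * q, t * (1 - q)
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            stats.nbinom.logpmf(k, r_a, r_a / (r_a + mu_a))
            + stats.nbinom.logpmf(t - k, r_b, r_b / (r_b + mu_b))
        )
    logp = logp - logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[y_a]
    return float(p[p <= obs * (1.0 + 1e-12)].sum())


def test_enrichment(
    counts: pd.DataFrame,
    classes: dict[str, str],
    target_class: str,
    reference_class: str = "input",
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "median_ratio",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-molecule enrichment of ``target_class`` over ``reference_class``.

    Returns a DataFrame (indexed like ``counts``) with mean normalized CPM
    per class, ``log2_fc``, exact-test ``p_value``, BH ``fdr`` and the
    ``enriched`` flag (log2_fc > lfc_min and fdr < fdr_max).
    """
    t_cols = _class_columns(classes, target_class)
    r_cols = _class_columns(classes, reference_class)
    if len(t_cols) < 2 or len(r_cols) < 2:
        raise DesignError(
            f"need >= 2 replicates in {target_class!r} and {reference_class!r}"
        )
    sub = counts[t_cols + r_cols]
    sub_classes = {c: classes[c] for c in sub.columns}
    ncpm = normalized_cpm(sub, normalization)
    mean_t = ncpm[t_cols].mean(axis=1)
    mean_r = ncpm[r_cols].mean(axis=1)
    log2_fc = np.log2((mean_t + pseudocount) / (mean_r + pseudocount))

    if dispersion is None:
        dispersion = estimate_common_dispersion(sub, sub_classes, normalization)

    sf = size_factors(sub, normalization)
    adj = (sub / sf).round().astype(int)
    y_t = adj[t_cols].sum(axis=1).to_numpy()
    y_r = adj[r_cols].sum(axis=1).to_numpy()
    pvals = np.array([
        _nb_exact_pvalue(int(a), int(a + b), len(t_cols), len(r_cols), dispersion)
        for a, b in zip(y_t, y_r)
    ])
    fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals

    out = pd.DataFrame(
        {
            f"mean_cpm_{target_class}": mean_t,
            f"mean_cpm_{reference_class}": mean_r,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "fdr": fdr,
        },
        index=counts.index,
    )
    out["enriched"] = (out["log2_fc"] > lfc_min) & (out["fdr"] < fdr_max)
    out.attrs["dispersion"] = dispersion
    out.attrs["target_class"] = target_class
    return out


def exclude_control_enriched(
    results_ip: pd.DataFrame, results_noab: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Drop molecules enriched in the no-antibody control from an IP result.

    Returns the filtered results and the number removed; the two result sets
    must cover the same molecule universe.
    """
    if not results_ip.index.equals(results_noab.index):
        raise ValueError("IP and control results cover different molecule sets")
    control_hit = results_noab["enriched"]
    removed = int((results_ip["enriched"] & control_hit).sum())
    filtered = results_ip.copy()
    filtered["enriched"] = results_ip["enriched"] & ~control_hit
    return filtered, removed


def intersect_antibodies(
    results_ip1: pd.DataFrame, results_ip2: pd.DataFrame
) -> pd.Index:
    """Molecules enriched with both independent antibodies."""
    e1 = results_ip1.index[results_ip1["enriched"]]
    e2 = results_ip2.index[results_ip2["enriched"]]
    return e1.intersection(e2).sort_values()


def enrichment_factor(
    counts: pd.DataFrame,
    classes: dict[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "median_ratio",
) -> pd.DataFrame:
    """Mean IP concentration over mean input concentration per molecule
    (per antibody and pooled), on the normalized per-million scale.

    Zero-input molecules are kept finite by the pseudocount and flagged.
    """
    ncpm = normalized_cpm(counts, normalization)
    in_cols = _class_columns(classes, "input")
    if not in_cols:
        raise DesignError("no input samples in the design")
    mean_in = ncpm[in_cols].mean(axis=1)
    out = pd.DataFrame(index=counts.index)
    ip_cols_all: list[str] = []
    for ab in ("IP1", "IP2"):
        cols = _class_columns(classes, ab)
        if not cols:
            continue
        ip_cols_all += cols
        out[f"factor_{ab}"] = (ncpm[cols].mean(axis=1) + pseudocount) / (
            mean_in + pseudocount
        )
    if ip_cols_all:
        out["factor_pooled"] = (ncpm[ip_cols_all].mean(axis=1) + pseudocount) / (
            mean_in + pseudocount
        )
    out["zero_input"] = mean_in == 0
    return out


def identify_bound(
    counts: pd.DataFrame,
    classes: dict[str, str],
    annotations: pd.DataFrame | None = None,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    exclude_igg: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "median_ratio",
) -> pd.DataFrame:
    """Full bound-set determination: per-antibody enrichment over input,
    no-antibody (optionally IgG) exclusion, dual-antibody intersection, and
    per-molecule enrichment factors.

    The ``bound`` flag is enriched_IP1 AND enriched_IP2 AND NOT
    control-enriched; exclusion commutes with intersection, so the same set
    results in either order.
    """
    kwargs = dict(
        lfc_min=lfc_min, fdr_max=fdr_max,
        pseudocount=pseudocount, normalization=normalization,
    )
    res = {
        ab: test_enrichment(counts, classes, ab, "input", **kwargs)
        for ab in ("IP1", "IP2")
    }
    controls = ["NoAb"] + (["IgG"] if exclude_igg else [])
    present_controls = [c for c in controls if _class_columns(classes, c)]
    control_res = {
        c: test_enrichment(counts, classes, c, "input", **kwargs)
        for c in present_controls
    }
    # IgG is always reported when present, even if it does not drive exclusion
    if "IgG" not in control_res and _class_columns(classes, "IgG"):
        control_res["IgG"] = test_enrichment(counts, classes, "IgG", "input", **kwargs)

    out = pd.DataFrame(index=counts.index)
    for ab, r in res.items():
        out[f"log2_fc_{ab}"] = r["log2_fc"]
        out[f"fdr_{ab}"] = r["fdr"]
        out[f"enriched_{ab}"] = r["enriched"]
    for c, r in control_res.items():
        out[f"log2_fc_{c}"] = r["log2_fc"]
        out[f"fdr_{c}"] = r["fdr"]
        out[f"enriched_{c}"] = r["enriched"]

    control_hit = pd.Series(False, index=counts.index)
    for c in present_controls:
        control_hit |= control_res[c]["enriched"]
    out["noab_enriched"] = control_hit
    out["bound"] = out["enriched_IP1"] & out["enriched_IP2"] & ~control_hit

    factors = enrichment_factor(counts, classes, pseudocount, normalization)
    out = pd.concat([out, factors], axis=1)
    if annotations is not None:
        out["category"] = annotations["category"].reindex(out.index)
    out.attrs["n_bound"] = int(out["bound"].sum())
    out.attrs["n_excluded_by_control"] = int(
        (out["enriched_IP1"] & out["enriched_IP2"] & control_hit).sum()
    )
    return out


def bound_category_breakdown(results: pd.DataFrame) -> dict[str, int]:
    """Counts of bound molecules per annotation category."""
    if "category" not in results.columns:
        raise ValueError("results carry no annotation categories")
    bound = results[results["bound"]]
    return bound["category"].value_counts().to_dict()
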