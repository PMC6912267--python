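"""Promoter CpG hypomethylation detection and methylation-expression gates.

Links PIWIL1 re-expression in colorectal tumors to loss of DNA methylation
at the CpG island in its promoter/first exon: a site is flagged when a
sufficient fraction of tumors fall clearly below the normal-tissue
methylation level, and a site passes the correlation gate when promoter
methylation anti-correlates with mRNA expression (Pearson r < -0.2,
p < 0.01).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def detect_hypomethylated_sites(
    beta: pd.DataFrame,
    sample_class: pd.Series,
    delta_min: float = 0.3,
    frac_min: float = 0.10,
    island_level: bool = False,
) -> pd.DataFrame:
    """Flag CpG sites with a hypomethylated tumor subgroup.

    A tumor sample is hypomethylated at a site when its beta value is below
    the normal-class median minus ``delta_min``; the site is flagged when at
    least ``frac_min`` of tumors qualify. ``island_level`` applies the same
    rule to the across-site mean beta (one "island" row).

    Returns per-site normal medians, hypomethylated-tumor fractions and
    flags.
    """
    if not ((beta.to_numpy() >= 0) & (beta.to_numpy() <= 1)).all():
        raise ValueError("beta values must lie in [0, 1]")
    classes = sample_class.reindex(beta.index)
    if classes.isna().any():
        raise ValueError("every sample needs a tumor/normal class label")
    for cls in ("tumor", "normal"):
        if (classes == cls).sum() < 3:
            warnings.warn(f"fewer than 3 {cls} samples; estimates unstable")

    mat = beta.mean(axis=1).to_frame("island_mean") if island_level else beta
    normals = mat[classes == "normal"]
    tumors = mat[classes == "tumor"]
    norm_median = normals.median(axis=0)
    below = tumors.lt(norm_median - delta_min, axis=1)
    fraction = below.mean(axis=0)
    return pd.DataFrame(
        {
            "normal_median": norm_median,
            "hypomethylated_fraction": fraction,
            "flagged": fraction >= frac_min,
        }
    ).rename_axis("site")


def correlate_methylation_expression(
    beta: pd.DataFrame,
    expression: pd.Series,
    r_max: float = -0.2,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation of each CpG site's beta values with expression.

    A site passes when p < ``alpha`` and r < ``r_max``. Raises on a
    zero-variance input vector (correlation undefined).
    """
    expr = expression.reindex(beta.index)
    if expr.isna().any():
        raise ValueError("expression and beta matrices cover different samples")
    if np.isclose(expr.var(ddof=0), 0.0):
        raise ValueError("expression vector has zero variance")
    rows = []
    for site in beta.columns:
        x = beta[site].to_numpy(dtype=float)
        if np.isclose(x.var(), 0.0):
            raise ValueError(f"site {site} has zero variance")
        r, p = stats.pearsonr(x, expr.to_numpy(dtype=float))
        rows.append({"site": site, "pearson_r": r, "p_value": p,
                     "passes": bool(p < alpha and r < r_max)})
    return pd.DataFrame(rows).set_index("site")


def expression_gate(
    expression: pd.Series,
    sample_class: pd.Series,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> dict:
    """Tumor-vs-normal differential-expression gate (FC and Welch test on
    log expression); a reporting utility on the same matrices."""
    classes = sample_class.reindex(expression.index)
    tum = expression[classes == "tumor"].to_numpy(dtype=float)
    nor = expression[classes == "normal"].to_numpy(dtype=float)
    if log_scale:
        fc = 2.0 ** (tum.mean() - nor.mean())
        t, p = stats.ttest_ind(tum, nor, equal_var=False)
    else:
        fc = tum.mean() / nor.mean()
        t, p = stats.ttest_ind(np.log2(tum + 1e-9), np.log2(nor + 1e-9),
                               equal_var=False)
    return {
        "fold_change": float(fc),
        "t_statistic": float(t),
        "p_value": float(p),
        "passes": bool(fc > fc_min and p < alpha),
    }
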