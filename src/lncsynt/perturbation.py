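"""Differential expression under TF perturbation, abundance-adjusted fold
changes, conserved-vs-non-conserved shift tests, response proportions, and
the top-5% binding null."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tf_enrichment import bh_adjust, two_proportion_z

logger = logging.getLogger("lncsynt")


def de_test(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    test: str = "exact_conditional",
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene differential expression between two count matrices
    (genes x samples).

    The default exact conditional test models each gene's pooled treated
    count as Binomial(total, s) with s the treated library share, and
    doubles the smaller exact tail (capped at 1).  The nb_wald option fits a
    moment-based negative binomial per gene and tests the log-ratio of means
    by a Wald z.  q-values are BH-adjusted; log2 fold changes come from mean
    CPM with a pseudocount.
    """
    if control.shape[1] < 1 or treated.shape[1] < 1:
        raise ValueError("need >= 1 sample per arm")
    genes = control.index
    if not genes.equals(treated.index):
        raise ValueError("arms must share the gene index")
    lib_c, lib_t = control.sum().sum(), treated.sum().sum()
    kc = control.sum(axis=1).to_numpy(dtype=float)
    kt = treated.sum(axis=1).to_numpy(dtype=float)
    cpm_c = (control * 1e6 / control.sum(axis=0)).mean(axis=1).to_numpy()
    cpm_t = (treated * 1e6 / treated.sum(axis=0)).mean(axis=1).to_numpy()
    log2fc = np.log2((cpm_t + pseudocount) / (cpm_c + pseudocount))

    if test == "exact_conditional":
        total = kc + kt
        s = lib_t / (lib_c + lib_t)
        with np.errstate(invalid="ignore"):
            p_lo = sps.binom.cdf(kt, total, s)
            p_hi = sps.binom.sf(kt - 1, total, s)
        p = np.minimum(1.0, 2.0 * np.minimum(p_lo, p_hi))
        p = np.where(total == 0, 1.0, p)
    elif test == "nb_wald":
        p = _nb_wald(control.to_numpy(float), treated.to_numpy(float))
    else:
        raise ValueError(f"unknown test {test!r}")
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean_cpm_control": cpm_c,
            "mean_cpm_treated": cpm_t,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "regulated": q < alpha,
        },
        index=genes,
    )


def _nb_wald(c: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Moment-matched NB Wald test on the log ratio of CPM means."""
    sc = c / c.sum(axis=0, keepdims=True) * 1e6
    st = t / t.sum(axis=0, keepdims=True) * 1e6
    mu_c, mu_t = sc.mean(axis=1), st.mean(axis=1)
    # within-arm method-of-moments dispersion (var = mu + alpha mu^2);
    # pooling across arms would absorb the treatment effect into alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        def arm_alpha(x, mu):
            if x.shape[1] < 2:
                return np.zeros(x.shape[0])
            var = x.var(axis=1, ddof=1)
            return np.clip(
                (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0, None
            )

        alpha_d = (arm_alpha(sc, mu_c) + arm_alpha(st, mu_t)) / 2
        v_log_c = (1 / np.maximum(mu_c, 1e-12) + alpha_d) / c.shape[1]
        v_log_t = (1 / np.maximum(mu_t, 1e-12) + alpha_d) / t.shape[1]
        z = (np.log(np.maximum(mu_t, 1e-12)) - np.log(np.maximum(mu_c, 1e-12))) / np.sqrt(
            v_log_c + v_log_t
        )
    p = 2 * sps.norm.sf(np.abs(z))
    return np.where((mu_c == 0) & (mu_t == 0), 1.0, p)


def adjusted_log2fc(results: pd.DataFrame, floor: float = 0.5) -> pd.Series:
    """Residual log2 fold change after an OLS regression of log2fc on
    log2(pooled mean CPM), over genes above the CPM floor in both arms."""
    keep = (results.mean_cpm_control > floor) & (results.mean_cpm_treated > floor)
    sub = results.loc[keep]
    if len(sub) < 3:
        raise ValueError("fewer than 3 genes pass the expression floor")
    x = np.log2((sub.mean_cpm_control + sub.mean_cpm_treated) / 2)
    slope, intercept = np.polyfit(x, sub.log2fc, 1)
    resid = sub.log2fc - (slope * x + intercept)
    return resid.rename("adjusted_log2fc")


def group_shift_test(
    adjusted: pd.Series, conserved: Mapping[str, bool]
) -> dict:
    """Two-sided Mann-Whitney U comparing adjusted fold changes of conserved
    vs non-conserved lncRNAs."""
    flags = np.array([bool(conserved.get(g, False)) for g in adjusted.index])
    a = adjusted.to_numpy()[flags]
    b = adjusted.to_numpy()[~flags]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 genes")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "median_conserved": float(np.median(a)),
        "median_non_conserved": float(np.median(b)),
    }


def response_proportion(
    results: pd.DataFrame, conserved: Mapping[str, bool]
) -> dict:
    """Proportion of regulated (q < alpha) genes in the conserved and
    non-conserved groups, compared by a two-proportions z-test."""
    flags = np.array([bool(conserved.get(g, False)) for g in results.index])
    reg = results.regulated.to_numpy()
    n1, n2 = int(flags.sum()), int((~flags).sum())
    x1, x2 = int(reg[flags].sum()), int(reg[~flags].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    z, p = two_proportion_z(x1, n1, x2, n2)
    return {
        "prop_conserved": x1 / n1,
        "prop_non_conserved": x2 / n2,
        "z": z,
        "p": p,
    }


def binding_null_quantile(
    proportions: Mapping[str, float],
    focal: Sequence[str],
    flag_quantile: float = 0.95,
) -> pd.DataFrame:
    """Empirical quantile of each focal TF's conserved-lncRNA binding
    proportion within the all-TF distribution; flagged at the top 5%."""
    if len(proportions) < 20:
        logger.warning("fewer than 20 TFs; quantile estimate unstable")
    vals = np.array(list(proportions.values()), dtype=float)
    rows = []
    for tf in focal:
        if tf not in proportions:
            raise KeyError(f"unknown TF {tf}")
        qt = float(np.mean(vals <= proportions[tf]))
        rows.append((tf, proportions[tf], qt, qt >= flag_quantile))
    return pd.DataFrame(
        rows, columns=["tf", "proportion", "quantile", "flagged"]
    ).set_index("tf")


def fc_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    floor: float = 0.5,
) -> float:
    """Spearman correlation of log2 fold changes between two perturbation
    experiments over shared genes above the CPM floor in both arms of both."""
    shared = results_a.index.intersection(results_b.index)
    a, b = results_a.loc[shared], results_b.loc[shared]
    keep = (
        (a.mean_cpm_control > floor)
        & (a.mean_cpm_treated > floor)
        & (b.mean_cpm_control > floor)
        & (b.mean_cpm_treated > floor)
    )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared genes pass the floor")
    return float(
        sps.spearmanr(a.log2fc[keep], b.log2fc[keep]).statistic
    )
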