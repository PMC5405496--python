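"""Negative-binomial differential coverage and compartment assignment.

Windows are classified from replicate counts of uniquely mapping reads,
the way RNA-seq counts are tested for differential expression: median-of-
ratios size factors, a per-window negative-binomial Wald test on the
log2 ratio of class means, Benjamini–Hochberg adjustment, and a two-
contrast decision rule:

* MAC significantly depleted versus MIC (adj. p < alpha and fold-change
  > ``fc_threshold`` in favour of MIC)  →  the window is MIC-limited;
* within MIC-limited windows, PGM also significantly depleted versus MIC
  →  MIC_ONLY, otherwise MIC_PGM;
* everything else (including windows untestable in the MAC contrast)
  →  MAC_DESTINED.

The dispersion is a per-window method-of-moments estimate floored at
0.01; no shrinkage toward a fitted trend is performed.  Fold-changes are
raw (unshrunken) and capped at ±10 log2 units when a class mean is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAC_DESTINED = "MAC_DESTINED"
MIC_PGM = "MIC_PGM"
MIC_ONLY = "MIC_ONLY"

LFC_CAP = 10.0
DISPERSION_FLOOR = 0.01


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios normalization factors (one per sample/column).

    factor_j = median over windows w (with all samples non-zero) of
    counts[w, j] / geometric_mean_w.  Factors are reported unscaled, as the
    raw medians.  If no window has all samples non-zero, falls back to
    total-count ratios with a warning.
    """
    k = np.asarray(counts, dtype=float)
    if k.ndim != 2:
        raise ValueError("counts must be windows x samples")
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn("no window with non-zero counts in all samples; "
                      "falling back to total-count ratios")
        totals = k.sum(axis=0)
        geo = np.exp(np.mean(np.log(totals)))
        return totals / geo
    logk = np.log(k[all_pos])
    loggeo = logk.mean(axis=1, keepdims=True)
    return np.exp(np.median(logk - loggeo, axis=0))


@dataclass
class NbTestResult:
    log2fc: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray
    untestable: np.ndarray
    base_mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseMean": self.base_mean,
                "log2FoldChange": self.log2fc,
                "lfcSE": self.se,
                "pvalue": self.pvalue,
                "padj": self.padj,
                "untestable": self.untestable,
            }
        )


def nb_wald_test(
    counts: np.ndarray,
    factors: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    dispersion_floor: float = DISPERSION_FLOOR,
    lfc_cap: float = LFC_CAP,
    adjust: bool = True,
) -> NbTestResult:
    """Per-window NB Wald test of class B versus class A.

    ``log2fc = log2(mean_B / mean_A)`` on size-factor-normalized counts.
    The Wald statistic uses the delta-method standard error of the log
    ratio under Var(K_ij) = mu_j + alpha * mu_j^2 (alpha per window,
    method-of-moments, floored), and a two-sided normal reference.
    Windows with all-zero counts get p = 1, log2fc = 0 and are flagged
    untestable (and excluded from the BH denominator).
    """
    k = np.asarray(counts, dtype=float)
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need >=2 replicates per class")
    s = np.asarray(factors, dtype=float)
    q = k / s  # normalized counts
    qa, qb = q[:, idx_a], q[:, idx_b]
    na, nb = qa.shape[1], qb.shape[1]
    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    base_mean = q.mean(axis=1)
    untestable = k[:, np.concatenate([idx_a, idx_b])].sum(axis=1) == 0

    # method-of-moments dispersion from pooled within-class variance:
    # Var(q_ij) = mu / s_j + alpha * mu^2
    var_pool = (qa.var(axis=1, ddof=1) * (na - 1) + qb.var(axis=1, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    inv_s = np.concatenate([1.0 / s[idx_a], 1.0 / s[idx_b]]).mean()
    mu_pool = (mu_a * na + mu_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pool - mu_pool * inv_s) / np.square(mu_pool)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, dispersion_floor)

    # delta-method SE of ln(mu_b/mu_a); zero class means get half a
    # normalized count for the variance term only
    eps = 0.5 / s.mean()
    ma = np.maximum(mu_a, eps)
    mb = np.maximum(mu_b, eps)
    var_ln_a = (ma * (1.0 / s[idx_a]).sum() / na**2 + alpha * ma**2 / na) / ma**2
    var_ln_b = (mb * (1.0 / s[idx_b]).sum() / nb**2 + alpha * mb**2 / nb) / mb**2
    se_ln = np.sqrt(var_ln_a + var_ln_b)

    with np.errstate(divide="ignore"):
        log2fc = np.log2(mb / ma)
    log2fc = np.clip(log2fc, -lfc_cap, lfc_cap)
    # a class with zero counts pegs the fold-change at the cap
    log2fc[(mu_b == 0) & (mu_a > 0)] = -lfc_cap
    log2fc[(mu_a == 0) & (mu_b > 0)] = lfc_cap
    log2fc[untestable] = 0.0

    z = np.log(mb / ma) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue[untestable] = 1.0
    padj = bh_adjust(pvalue, testable=~untestable) if adjust else np.full_like(pvalue, np.nan)
    se_log2 = se_ln / np.log(2.0)
    return NbTestResult(log2fc, se_log2, pvalue, padj, untestable, base_mean)


def bh_adjust(pvals: np.ndarray, testable: np.ndarray | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity enforcement.

    Untestable entries are excluded from the multiplicity count m and get
    padj = 1.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.ones_like(p)
    mask = np.ones(len(p), dtype=bool) if testable is None else np.asarray(testable, bool)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class CompartmentCalls:
    windows: pd.DataFrame  # contig/start/end
    mac_vs_mic: NbTestResult
    pgm_vs_mic: NbTestResult
    label: np.ndarray  # per window

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.copy()
        df["log2fc_mac_vs_mic"] = self.mac_vs_mic.log2fc
        df["padj_mac_vs_mic"] = self.mac_vs_mic.padj
        df["log2fc_pgm_vs_mic"] = self.pgm_vs_mic.log2fc
        df["padj_pgm_vs_mic"] = self.pgm_vs_mic.padj
        df["label"] = self.label
        return df


def assign_compartments(
    windows: pd.DataFrame,
    res_mac_vs_mic: NbTestResult,
    res_pgm_vs_mic: NbTestResult,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> CompartmentCalls:
    """Three-way compartment labels from the two contrasts.

    ``res_*`` hold log2fc of the named class versus MIC (negative =
    depleted relative to MIC).  Significant depletion means
    padj < alpha and fold-change > fc_threshold in favour of MIC.
    """
    n = len(windows)
    for res in (res_mac_vs_mic, res_pgm_vs_mic):
        if len(res.log2fc) != n:
            raise ValueError("result sets must cover the identical window list")
    thr = np.log2(fc_threshold)
    mac_dep = (res_mac_vs_mic.padj < alpha) & (res_mac_vs_mic.log2fc < -thr) & (
        ~res_mac_vs_mic.untestable
    )
    pgm_dep = (res_pgm_vs_mic.padj < alpha) & (res_pgm_vs_mic.log2fc < -thr) & (
        ~res_pgm_vs_mic.untestable
    )
    label = np.full(n, MAC_DESTINED, dtype=object)
    label[mac_dep & ~pgm_dep] = MIC_PGM
    label[mac_dep & pgm_dep] = MIC_ONLY
    return CompartmentCalls(windows.reset_index(drop=True), res_mac_vs_mic, res_pgm_vs_mic, label)


def compartment_pipeline(
    windows: pd.DataFrame,
    count_matrix: np.ndarray,
    classes: list[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> CompartmentCalls:
    """Counts → size factors → both contrasts → labels.

    ``classes`` gives the class of each count column: "MIC", "MAC" or "PGM";
    at least two replicates of each are required.
    """
    classes = list(classes)
    idx = {c: np.flatnonzero([x == c for x in classes]) for c in ("MIC", "MAC", "PGM")}
    for c, ix in idx.items():
        if len(ix) < 2:
            raise ValueError(f"need >=2 replicates of class {c}")
    sf = size_factors(count_matrix)
    res_mac = nb_wald_test(count_matrix, sf, idx["MIC"], idx["MAC"])
    res_pgm = nb_wald_test(count_matrix, sf, idx["MIC"], idx["PGM"])
    return assign_compartments(windows, res_mac, res_pgm, fc_threshold, alpha)
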