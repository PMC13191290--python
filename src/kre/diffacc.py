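"""M-A normalization and condition-contrast accessibility calling.

Two-condition accessibility signals are put on a common scale by the M-A
rescaling used for ATAC/ChIP signal comparison: over a set of common
(unchanged) elements, an ordinary least-squares line M = alpha + beta*A is
fitted and condition-b signals are rescaled until the refitted line is flat
at zero. Elements are then classified as stimulus-activated / repressed /
insensitive from the replicate-mean fold change (cutoff 1.5) with a
two-sided rate test on pseudocounted normalized totals, BH-adjusted. The
upstream tooling delegates per-peak significance to a read-level Bayesian
model that is out of scope here; the rate test is a documented stand-in that
preserves the contract (an element-level p with FDR control).

EGR1 sensitivity of a responsive element is the attenuation of its stimulus
response when EGR1 induction is blocked: Delta = |log2FC_ctrl - log2FC_pert|
>= log2(1.5) with a significant genotype-by-stimulus association (Fisher
test on the 2x2 of normalized totals, BH-adjusted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2_FC_DEFAULT = 1.5


class NormalizationError(ValueError):
    """Too few usable common elements to fit the M-A line."""


def ma_transform(x_a, x_b):
    """M = log2(x_a/x_b), A = 0.5*log2(x_a*x_b); inputs must be positive."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if np.any(x_a <= 0) or np.any(x_b <= 0):
        raise ValueError("ma_transform requires positive signals (after pseudocount)")
    return np.log2(x_a / x_b), 0.5 * np.log2(x_a * x_b)


def _check_ids(signals: pd.DataFrame, cols: list[str]) -> None:
    if "element_id" not in signals.columns:
        raise ValueError("signal table must carry an element_id column")
    missing = [c for c in cols if c not in signals.columns]
    if missing:
        raise ValueError(f"signal table lacks sample columns: {missing}")


def ma_normalize(
    signals: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    common_ids: list[str],
    pseudocount: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Rescale condition-b sample columns onto condition a's scale.

    The per-element rescaling factor 2**(alpha + beta*A) is re-estimated over
    the common elements until the refitted line has |alpha| and |beta| below
    tol. Condition-a columns are returned unchanged.
    """
    _check_ids(signals, cols_a + cols_b)
    if len(common_ids) == 0:
        raise NormalizationError("no common elements supplied")
    out = signals.copy()
    idx = out["element_id"].isin(set(common_ids)).to_numpy()
    if idx.sum() < 2:
        raise NormalizationError(
            f"need >=2 common elements present in the table, got {int(idx.sum())}"
        )
    for _ in range(max_iter):
        mean_a = out[cols_a].to_numpy().mean(axis=1) + pseudocount
        mean_b = out[cols_b].to_numpy().mean(axis=1) + pseudocount
        m, a = ma_transform(mean_a, mean_b)
        a_common = a[idx]
        if np.ptp(a_common) == 0:
            # degenerate A spread: only a constant offset is identifiable
            alpha, beta = float(np.mean(m[idx])), 0.0
        else:
            beta, alpha = np.polyfit(a_common, m[idx], deg=1)
        if abs(alpha) < tol and abs(beta) < tol:
            break
        scale = 2.0 ** (alpha + beta * a)  # raise b so that M loses alpha+beta*A
        for c in cols_b:
            out[c] = out[c].to_numpy() * scale
    else:
        raise NormalizationError("M-A rescaling did not converge")
    return out


def first_pass_common(
    signals: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    max_abs_log2fc: float = np.log2(1.2),
    pseudocount: float = 1.0,
) -> list[str]:
    """Common-element set for normalization: raw |log2FC| < log2(1.2)."""
    _check_ids(signals, cols_a + cols_b)
    mean_a = signals[cols_a].to_numpy().mean(axis=1) + pseudocount
    mean_b = signals[cols_b].to_numpy().mean(axis=1) + pseudocount
    m = np.log2(mean_a / mean_b)
    return list(signals["element_id"].to_numpy()[np.abs(m) < max_abs_log2fc])


def _rate_test_pvalues(tot_a: np.ndarray, tot_b: np.ndarray) -> np.ndarray:
    """Two-sided exact test that the two normalized totals share one rate."""
    pvals = np.empty(len(tot_a))
    for i, (ka, kb) in enumerate(zip(tot_a, tot_b)):
        ka_i, kb_i = int(round(ka)), int(round(kb))
        pvals[i] = stats.binomtest(ka_i, ka_i + kb_i, 0.5).pvalue
    return pvals


def call_kres(
    norm: pd.DataFrame,
    stim_cols: list[str],
    ctrl_cols: list[str],
    fc_threshold: float = LOG2_FC_DEFAULT,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify each element as activated / repressed / insensitive.

    log2FC is taken from replicate-mean normalized signals; significance from
    the two-sided rate test on replicate-summed totals, BH-adjusted across
    elements. activated: log2FC >= log2(fc) and padj < alpha; repressed:
    log2FC <= -log2(fc) and padj < alpha; else insensitive.
    """
    _check_ids(norm, stim_cols + ctrl_cols)
    mean_s = norm[stim_cols].to_numpy().mean(axis=1) + pseudocount
    mean_c = norm[ctrl_cols].to_numpy().mean(axis=1) + pseudocount
    lfc = np.log2(mean_s / mean_c)
    tot_s = norm[stim_cols].to_numpy().sum(axis=1) + pseudocount
    tot_c = norm[ctrl_cols].to_numpy().sum(axis=1) + pseudocount
    pvals = _rate_test_pvalues(tot_s, tot_c)
    padj = multipletests(pvals, method="fdr_bh")[1]
    cut = np.log2(fc_threshold)
    label = np.where(
        (lfc >= cut) & (padj < alpha), "activated",
        np.where((lfc <= -cut) & (padj < alpha), "repressed", "insensitive"),
    )
    return pd.DataFrame(
        {
            "element_id": norm["element_id"].to_numpy(),
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "label": label,
        }
    )


def call_egr1_sensitivity(
    norm_ctrl: pd.DataFrame,
    norm_pert: pd.DataFrame,
    calls_ctrl: pd.DataFrame,
    stim_cols_ctrl: list[str],
    ctrl_cols_ctrl: list[str],
    stim_cols_pert: list[str],
    ctrl_cols_pert: list[str],
    fc_threshold: float = LOG2_FC_DEFAULT,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """EGR1-sensitivity calls for elements responsive in the control genotype.

    Delta = |log2FC_ctrl - log2FC_pert|; the differential p comes from a
    Fisher exact test on the 2x2 table of stimulated/control normalized
    totals across genotypes, BH-adjusted over tested elements. Sensitive iff
    Delta >= log2(fc_threshold) and padj < alpha.
    """
    tested = calls_ctrl.loc[calls_ctrl["label"] != "insensitive", "element_id"]
    tested = list(tested)
    for name, tab in (("control", norm_ctrl), ("perturbed", norm_pert)):
        have = set(tab["element_id"])
        missing = [e for e in tested if e not in have]
        if missing:
            raise ValueError(
                f"elements absent from the {name} genotype table: {missing[:10]}"
            )
    ctrl = norm_ctrl.set_index("element_id").loc[tested]
    pert = norm_pert.set_index("element_id").loc[tested]

    def lfc_and_totals(tab, stim_cols, ctrl_cols):
        ms = tab[stim_cols].to_numpy().mean(axis=1) + pseudocount
        mc = tab[ctrl_cols].to_numpy().mean(axis=1) + pseudocount
        ts = tab[stim_cols].to_numpy().sum(axis=1) + pseudocount
        tc = tab[ctrl_cols].to_numpy().sum(axis=1) + pseudocount
        return np.log2(ms / mc), ts, tc

    lfc_c, ts_c, tc_c = lfc_and_totals(ctrl, stim_cols_ctrl, ctrl_cols_ctrl)
    lfc_p, ts_p, tc_p = lfc_and_totals(pert, stim_cols_pert, ctrl_cols_pert)
    delta = np.abs(lfc_c - lfc_p)
    pvals = np.empty(len(tested))
    for i in range(len(tested)):
        table = [
            [int(round(ts_c[i])), int(round(tc_c[i]))],
            [int(round(ts_p[i])), int(round(tc_p[i]))],
        ]
        pvals[i] = stats.fisher_exact(table)[1]
    padj = (
        multipletests(pvals, method="fdr_bh")[1] if len(tested) else np.array([])
    )
    cut = np.log2(fc_threshold)
    label = np.where(
        (delta >= cut) & (padj < alpha), "egr1_sensitive", "egr1_insensitive"
    )
    return pd.DataFrame(
        {
            "element_id": tested,
            "log2fc_ctrl": lfc_c,
            "log2fc_pert": lfc_p,
            "delta": delta,
            "pvalue": pvals,
            "padj": padj,
            "label": label,
        }
    )
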