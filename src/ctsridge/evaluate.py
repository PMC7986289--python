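"""Calling, confusion counts, performance metrics and collinearity
diagnostics.

Calls are signed (the direction is the sign of the test statistic): a
marker truly up-regulated in the tested cell type but called down counts as
a false positive, not a true positive.  Counts are subtotaled by the truly
associated cell type (plus a Null stratum), exactly partitioning the marker
set for every tested cell type.

The analytic collinearity diagnostic is the closed-form correlation of two
interaction terms W_h X and W_h' X for composition independent of the
centered trait:

    Cor[W_h X, W_h' X] = (Cor[W_h, W_h'] CV_h CV_h' + 1)
                         / (sqrt(CV_h^2 + 1) sqrt(CV_h'^2 + 1))

which approaches 1 as both CVs shrink regardless of the proportion
correlation — the mechanism that makes the full model unstable in tissues
with tightly controlled composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import OmicsDataset, marginal_design
from .scales import get_scale, normalize


# ---------------------------------------------------------------------------
# calling and confusion counts
# ---------------------------------------------------------------------------

def call_positives(results: pd.DataFrame, cell_type, procedure: str,
                   threshold: float) -> pd.Series:
    """Signed calls (-1/0/+1) per marker for one tested cell type.

    ``fixed_p`` calls markers with p < threshold; ``bh_fdr`` applies the
    Benjamini-Hochberg step-up within the tested cell type's p-value vector
    at FDR = threshold.  Missing p-values are never called.
    """
    if procedure not in ("fixed_p", "bh_fdr"):
        raise ValueError("procedure must be 'fixed_p' or 'bh_fdr'")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sub = results[results["cell_type"] == cell_type]
    p = sub["p"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    called = np.zeros(len(sub), dtype=bool)
    if procedure == "fixed_p":
        called[ok] = p[ok] < threshold
    elif ok.any():
        called[ok] = multipletests(p[ok], alpha=threshold,
                                   method="fdr_bh")[0]
    sign = np.sign(sub["statistic"].to_numpy(dtype=float))
    sign[~np.isfinite(sign)] = 0
    return pd.Series((called * sign).astype(int),
                     index=sub["marker"].to_numpy(), name=cell_type)


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN for one tested cell type, subtotaled by the truly
    associated cell type (strata include 'Null')."""

    cell_type: object
    by_stratum: pd.DataFrame  # index: stratum; columns: TP, TN, FP, FN

    @property
    def tp(self):
        return int(self.by_stratum["TP"].sum())

    @property
    def tn(self):
        return int(self.by_stratum["TN"].sum())

    @property
    def fp(self):
        return int(self.by_stratum["FP"].sum())

    @property
    def fn(self):
        return int(self.by_stratum["FN"].sum())

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


def confusion_subtotals(calls: pd.Series, truth, cell_type) -> ConfusionCounts:
    """Count outcomes of signed calls against the simulation truth.

    For markers truly associated in the tested cell type, a direction-
    matched call is a TP, no call is an FN, and an opposite-direction call
    is an FP.  Any call on a marker associated elsewhere (or null) is an FP
    in that stratum; no call there is a TN.
    """
    table = truth.table if hasattr(truth, "table") else truth
    if set(calls.index) != set(table["marker"]):
        raise ValueError("calls and truth cover different marker sets")
    t = table.set_index("marker").loc[calls.index]
    stratum = t["cell_type"].astype(object).where(t["direction"] != 0, "Null")
    true_dir = t["direction"].to_numpy()
    c = calls.to_numpy()

    own = (stratum == cell_type).to_numpy()
    tp = own & (c == true_dir)
    fn = own & (c == 0)
    fp = (own & (c == -true_dir) & (c != 0)) | (~own & (c != 0))
    tn = ~own & (c == 0)

    frame = pd.DataFrame({"stratum": stratum.to_numpy(), "TP": tp, "TN": tn,
                          "FP": fp, "FN": fn})
    by = frame.groupby("stratum", sort=False)[["TP", "TN", "FP", "FN"]].sum()
    return ConfusionCounts(cell_type=cell_type, by_stratum=by)


def performance_metrics(counts: ConfusionCounts):
    """(sensitivity, specificity, precision); precision is NaN when no
    marker was called positive."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    return sens, spec, prec


def performance_table(results: pd.DataFrame, truth, procedure: str,
                      threshold: float, method=None) -> pd.DataFrame:
    """Per-cell-type sensitivity/specificity/precision for one results set."""
    rows = []
    cell_types = pd.unique(results["cell_type"])
    for h in cell_types:
        calls = call_positives(results, h, procedure, threshold)
        counts = confusion_subtotals(calls, truth, h)
        sens, spec, prec = performance_metrics(counts)
        rows.append({"method": method or results["method"].iloc[0],
                     "cell_type": h, "sensitivity": sens,
                     "specificity": spec, "precision": prec,
                     "TP": counts.tp, "TN": counts.tn, "FP": counts.fp,
                     "FN": counts.fn})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# collinearity diagnostics
# ---------------------------------------------------------------------------

def interaction_correlation(cv_h: float, cv_h2: float, cor_hh2: float) -> float:
    """Closed-form correlation of the interaction terms W_h X and W_h' X.

    Assumes the composition is independent of the centered trait X.
    Symmetric in the two CV arguments; tends to 1 as both CVs tend to 0.
    """
    if cv_h < 0 or cv_h2 < 0:
        raise ValueError("coefficients of variation must be nonnegative")
    if not -1.0 <= cor_hh2 <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    num = cor_hh2 * cv_h * cv_h2 + 1.0
    den = np.sqrt(cv_h**2 + 1.0) * np.sqrt(cv_h2**2 + 1.0)
    return float(num / den)


def composition_diagnostics(W, X, cell_types=None, trait_name="X"):
    """Empirical per-cell-type moments and the three correlation tables.

    Returns a dict with 'summary' (mean, SD, CV), 'proportion_correlation'
    (proportions and the trait), and 'interaction_correlation' (between the
    empirical interaction terms W_h * X).  A zero-mean cell type gets a
    missing CV.
    """
    W = np.asarray(W, dtype=float)
    x = np.asarray(X, dtype=float).reshape(W.shape[0], -1)[:, 0]
    x = x - x.mean()
    H = W.shape[1]
    if cell_types is None:
        cell_types = [f"ct{h+1}" for h in range(H)]
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    summary = pd.DataFrame({"mean": mean, "SD": sd, "CV": cv},
                           index=cell_types)

    aug = np.column_stack([W, x])
    cor = np.corrcoef(aug, rowvar=False)
    prop_cor = pd.DataFrame(cor, index=cell_types + [trait_name],
                            columns=cell_types + [trait_name])

    inter = W * x[:, None]
    icor = pd.DataFrame(np.corrcoef(inter, rowvar=False),
                        index=cell_types, columns=cell_types)
    return {"summary": summary, "proportion_correlation": prop_cor,
            "interaction_correlation": icor}


def interaction_correlation_grid(cv_values, cor_values) -> pd.DataFrame:
    """Closed-form correlation over a (CV, Cor) grid with equal CVs, the
    contour-plot layout of the collinearity diagnostic."""
    rows = []
    for cv in cv_values:
        for cor in cor_values:
            rows.append({"CV": cv, "Cor_W": cor,
                         "Cor_interaction": interaction_correlation(cv, cv, cor)})
    return pd.DataFrame(rows)


def marginal_r2(data: OmicsDataset, marker, cell_type,
                normalized_input=False, scale="identity") -> float:
    """Coefficient of determination of the marginal model for one marker;
    R^2/(1-R^2) is the signal-to-noise ratio of the tested association."""
    y = (data.y_normalized(marker, scale) if normalized_input
         else data.y(marker))
    D = marginal_design(data, cell_type)
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return np.nan
    return 1.0 - float(np.sum(resid**2)) / tss
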