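"""Association statistics: ROC AUC (Mann-Whitney form), bootstrap
confidence intervals, window-size (blurring) deltas with sigma
classification, and ChIP-qPCR delta-delta-Ct enrichment arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, FormatError
from .tagmap import BLUR_WINDOW_SIZES, TagMap, site_center, window_average

SIGMA_CLASSES = ("<1sigma", "1-2sigma", ">=2sigma")


@dataclass
class RocResult:
    """ROC area under the curve with optional bootstrap CI."""

    auc: float
    n_pos: int
    n_neg: int
    ci: tuple[float, float] | None = None
    window: int | None = None
    orientation: str = "low_predicts_positive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
                raise ValueError("CI does not bracket the AUC")


def _auc_value(pos: np.ndarray, neg: np.ndarray,
               low_predicts_positive: bool) -> float:
    """AUC = P(pos ranked correctly vs neg), ties counting one half.

    Computed as the normalized Mann-Whitney U statistic via midranks, which
    is exact for ties.
    """
    n_pos, n_neg = pos.size, neg.size
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u_pos = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc_high = u_pos / (n_pos * n_neg)  # P(pos > neg) + 0.5 P(=)
    return 1.0 - auc_high if low_predicts_positive else auc_high


def roc_auc(pos_scores, neg_scores, low_predicts_positive: bool = True,
            window: int | None = None) -> RocResult:
    """ROC AUC for separating positive from negative scores.

    With ``low_predicts_positive`` (the convention for nucleosome depletion
    at bound sites) the AUC is P(score_pos < score_neg) + 0.5 P(equal).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("both score classes must be non-empty")
    auc = _auc_value(pos, neg, low_predicts_positive)
    return RocResult(
        auc=auc, n_pos=pos.size, n_neg=neg.size, window=window,
        orientation="low_predicts_positive" if low_predicts_positive
        else "high_predicts_positive",
    )


def bootstrap_auc(
    pos_scores,
    neg_scores,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    low_predicts_positive: bool = True,
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI for the ROC AUC.

    Both classes are resampled with replacement in each of ``B`` replicates.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("both score classes must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        p = pos[rng.integers(0, pos.size, pos.size)]
        n = neg[rng.integers(0, neg.size, neg.size)]
        vals[b] = _auc_value(p, n, low_predicts_positive)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def delta_auc(
    tm: TagMap,
    bound_sites: pd.DataFrame,
    control_loci: pd.DataFrame,
    sizes: tuple[int, ...] = BLUR_WINDOW_SIZES,
    low_predicts_positive: bool = True,
) -> dict:
    """AUC at each window size plus the blurring delta AUC(max) - AUC(min).

    Site scores are window averages centered on the motif (with the even-
    length extension rule); control scores use the same windows centered on
    single basepairs.  The same control set is reused across all sizes so
    the AUCs are directly comparable.
    """
    aucs: dict[int, RocResult] = {}
    centers = [
        (row.chrom, site_center(row.start, row.end),
         (row.end - row.start) % 2 == 0)
        for row in bound_sites.itertuples(index=False)
    ]
    controls = [(row.chrom, int(row.pos)) for row in
                control_loci.itertuples(index=False)]
    for size in sizes:
        pos = [window_average(tm, c, ctr, size, motif_even=ev)
               for c, ctr, ev in centers]
        neg = [window_average(tm, c, p, size) for c, p in controls]
        aucs[size] = roc_auc(pos, neg, low_predicts_positive, window=size)
    delta = aucs[max(sizes)].auc - aucs[min(sizes)].auc
    return {"aucs": aucs, "delta": delta}


def delta_auc_table(per_tf: dict[str, dict]) -> pd.DataFrame:
    """Tabulate per-TF window AUCs, deltas, and sigma classes."""
    rows = []
    for tf, res in per_tf.items():
        row = {"tf": tf, "delta": res["delta"]}
        for size, rr in res["aucs"].items():
            row[f"auc_{size}"] = rr.auc
        rows.append(row)
    table = pd.DataFrame(rows)
    table["sigma_class"] = classify_by_sigma(table["delta"].to_numpy())
    return table


def classify_by_sigma(deltas) -> list[str]:
    """Classify each |delta AUC| against the cross-TF distribution of
    absolute deltas: below 1 SD above the mean, 1-2 SD, or >= 2 SD.

    Sample SD (ddof=1).  If the SD is zero every TF is ``<1sigma``.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 3:
        raise DegenerateInputError("need at least 3 TFs for sigma classes")
    mag = np.abs(deltas)
    mean, sd = mag.mean(), mag.std(ddof=1)
    if sd == 0:
        return [SIGMA_CLASSES[0]] * deltas.size
    z = (mag - mean) / sd
    return [
        SIGMA_CLASSES[2] if zi >= 2 else SIGMA_CLASSES[1] if zi >= 1
        else SIGMA_CLASSES[0]
        for zi in z
    ]


def qpcr_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site fold enrichment from a Ct table by delta-delta-Ct.

    Per replicate: dCt = ct_ip - ct_input for every site; the reference is
    the mean dCt of the two control sites in that replicate.  Per site the
    fold enrichment is 2**(-mean over replicates of (dCt - reference)).

    Returns columns (site_id, fold, n_replicates); control sites are
    included (their folds are 1 when the two controls agree exactly).
    """
    required = {"site_id", "replicate", "ct_ip", "ct_input", "is_control"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"Ct table missing column(s): {sorted(missing)}")
    table = table.copy()
    table["dct"] = table["ct_ip"] - table["ct_input"]
    ref_by_rep = {}
    for rep, grp in table.groupby("replicate"):
        ctrl = grp.loc[grp["is_control"].astype(bool)]
        if ctrl["site_id"].nunique() != 2:
            raise FormatError(
                f"replicate {rep!r} must contain exactly two control sites"
            )
        ref_by_rep[rep] = ctrl.groupby("site_id")["dct"].mean().mean()
    table["ddct"] = table["dct"] - table["replicate"].map(ref_by_rep)
    agg = table.groupby("site_id").agg(
        mean_ddct=("ddct", "mean"), n_replicates=("replicate", "nunique")
    )
    agg["fold"] = 2.0 ** (-agg["mean_ddct"])
    return agg.reset_index()[["site_id", "fold", "n_replicates"]]


def clamp_for_fit(enrichments, tag_counts,
                  min_enrichment: float = 1.0,
                  max_tag: float = 600.0) -> tuple[np.ndarray, np.ndarray]:
    """Clamp fold enrichments below 1 up to 1, and tag counts above 600 down
    to 600, before correlation fitting."""
    e = np.maximum(np.asarray(enrichments, dtype=float), min_enrichment)
    t = np.minimum(np.asarray(tag_counts, dtype=float), max_tag)
    return e, t


def pearson_fit(log_enrichment, tag_counts) -> dict:
    """OLS of log2 enrichment on tag count, with Pearson r.

    Returns r, slope, intercept, the two-sided p-value, and a one-sided
    p-value for the alternative r < 0 (binding anti-correlated with
    occupancy).
    """
    y = np.asarray(log_enrichment, dtype=float)
    x = np.asarray(tag_counts, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    fit = sps.linregress(x, y)
    p_one = fit.pvalue / 2 if fit.rvalue < 0 else 1 - fit.pvalue / 2
    return {
        "r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pvalue": float(fit.pvalue),
        "pvalue_one_sided_neg": float(p_one),
    }
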