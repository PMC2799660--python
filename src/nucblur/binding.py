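"""Thermodynamic PWM model of TF-promoter binding with nucleosome weights.

Every sequence window of motif length, on both strands, is assigned a
relative association constant Ka from the PWM (likelihood ratio against a
uniform background).  Given a protein concentration c, each window is bound
with probability c*Ka / (1 + c*Ka), and the promoter is "bound" if at
least one window is (independent-window approximation), as in the GOMER
framework.

Nucleosome occupancy enters as multiplicative weights on Ka: the genome is
tiled into non-overlapping 15-bp segments; a segment's tag count, expressed
as Q standard deviations above zero, converts to the weight W**(-Q)
(W = 4 by default), so higher occupancy means exponentially lower
effective affinity and a segment with no mapped tags keeps weight exactly
1.  The occupancy may be the segment's local mean ("local", 15 bp) or the
mean over a larger centered window ("regional", 600 bp by default),
emulating blurred low-resolution data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, DegenerateInputError
from .genome import GenomeSequence, PwmRecord, encode_sequence
from .stats import RocResult, roc_auc
from .tagmap import TagMap, _sliding_mean

logger = logging.getLogger(__name__)

DEFAULT_SEGMENT = 15
DEFAULT_REGIONAL_WINDOW = 600
DEFAULT_WEIGHT_BASE = 4.0

VARIANTS = ("unweighted", "local15", "blurred600")


@dataclass
class AffinityLandscape:
    """Per-offset, per-strand relative association constants for one
    sequence.  Row 0 is the forward strand, row 1 the reverse; windows
    containing N are invalid (Ka set to 0 and masked out)."""

    ka: np.ndarray           # shape (2, n_windows)
    valid: np.ndarray        # shape (n_windows,), bool
    motif_length: int
    pwm_name: str

    @property
    def n_windows(self) -> int:
        return self.ka.shape[1]


def _likelihood_ratios(pwm: PwmRecord, pseudocount: float) -> np.ndarray:
    """Per-position likelihood ratio table vs the uniform background, with
    pseudocount smoothing; shape (m, 5) where column 4 (N) is 0."""
    p = (pwm.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
    lr = np.zeros((len(pwm), 5))
    lr[:, :4] = p / 0.25
    return lr


def ka_landscape(
    pwm: PwmRecord, sequence: str, pseudocount: float = 0.01
) -> AffinityLandscape:
    """Relative Ka for every motif-length window on both strands.

    Ka_rel(window) = prod_j p_j(base_j) / 0.25 with pseudocount-smoothed
    probabilities; the reverse strand scores the reverse complement.
    Windows overlapping an N are skipped (logged once per sequence).
    """
    m = len(pwm)
    if len(sequence) < m:
        raise DegenerateInputError("sequence shorter than the motif")
    codes = encode_sequence(sequence)
    nwin = codes.size - m + 1
    lr = _likelihood_ratios(pwm, pseudocount)
    lr_rc = lr[::-1, [3, 2, 1, 0, 4]]  # reverse positions, complement bases
    fwd = np.ones(nwin)
    rev = np.ones(nwin)
    for j in range(m):
        col = codes[j : j + nwin]
        fwd *= lr[j, col]
        rev *= lr_rc[j, col]
    has_n = np.cumsum(np.concatenate([[0], (codes == 4).astype(int)]))
    valid = (has_n[m:] - has_n[:-m]) == 0
    if not valid.all():
        logger.info("ka_landscape: skipped %d window(s) containing N",
                    int((~valid).sum()))
    ka = np.vstack([fwd, rev])
    ka[:, ~valid] = 0.0
    return AffinityLandscape(ka=ka, valid=valid, motif_length=m,
                             pwm_name=pwm.tf_name)


@dataclass
class WeightTrack:
    """Per-segment occupancy-derived Ka weights for one genome."""

    segment: int
    weight_base: float
    sd: float                      # SD of per-segment local means
    local: dict[str, np.ndarray]   # per-chrom local segment means
    regional: dict[str, np.ndarray]
    q: dict[str, np.ndarray]       # occupancy in SD-above-zero units
    weight: dict[str, np.ndarray]
    use_regional: bool = False

    def weight_at(self, chrom: str, pos: int) -> float:
        return float(self.weight[chrom][pos // self.segment])


def segment_weights(
    tagmap: TagMap,
    segment: int = DEFAULT_SEGMENT,
    regional_window: int = DEFAULT_REGIONAL_WINDOW,
    W: float = DEFAULT_WEIGHT_BASE,
    use_regional: bool = False,
) -> WeightTrack:
    """Convert a tag-count track into per-segment Ka weights.

    Q is the chosen occupancy (local segment mean, or the mean over the
    ``regional_window`` centered on the segment) divided by the genome-wide
    SD of the per-segment local means -- measured from zero, with no mean
    subtraction, so a segment with no tags has Q = 0 and weight exactly 1.
    The weight is W**(-Q).
    """
    locals_: dict[str, np.ndarray] = {}
    regionals: dict[str, np.ndarray] = {}
    for chrom, arr in tagmap.tracks.items():
        n_seg = -(-arr.size // segment)
        sums = np.add.reduceat(arr, np.arange(0, arr.size, segment))
        counts = np.minimum(
            np.arange(1, n_seg + 1) * segment, arr.size
        ) - np.arange(0, n_seg) * segment
        locals_[chrom] = sums / counts
        blurred = _sliding_mean(arr, regional_window)
        centers = np.minimum(
            np.arange(n_seg) * segment + segment // 2, arr.size - 1)
        regionals[chrom] = blurred[centers]
    pooled = np.concatenate(list(locals_.values()))
    sd = float(pooled.std(ddof=0))
    if sd == 0:
        raise DegenerateInputError(
            "per-segment occupancy has zero variance; weights undefined"
        )
    chosen = regionals if use_regional else locals_
    q = {c: v / sd for c, v in chosen.items()}
    weight = {c: W ** (-v) for c, v in q.items()}
    return WeightTrack(
        segment=segment, weight_base=W, sd=sd, local=locals_,
        regional=regionals, q=q, weight=weight, use_regional=use_regional,
    )


def weighted_ka(
    landscape: AffinityLandscape,
    weights: WeightTrack,
    chrom: str,
    sequence_start: int,
) -> AffinityLandscape:
    """Multiply each window's Ka by the weight of the 15-bp segment
    containing the window's center (both strands share the weight)."""
    m = landscape.motif_length
    centers = sequence_start + np.arange(landscape.n_windows) + m // 2
    w = weights.weight[chrom][centers // weights.segment]
    return AffinityLandscape(
        ka=landscape.ka * w[None, :],
        valid=landscape.valid,
        motif_length=m,
        pwm_name=landscape.pwm_name,
    )


def p_bound_promoter(landscape: AffinityLandscape, concentration: float) -> float:
    """Probability the TF is bound somewhere in the interval.

    Each window is occupied with probability c*Ka/(1 + c*Ka); windows are
    treated as independent, so
    P(bound) = 1 - prod over windows and strands of (1 - p_i).
    """
    if concentration <= 0:
        raise ConfigError("concentration must be > 0")
    cka = concentration * landscape.ka[:, landscape.valid]
    p = cka / (1.0 + cka)
    return float(-np.expm1(np.log1p(-p).sum()))


class GomerModel(BaseEstimator):
    """Scikit-learn-style estimator for PWM-based promoter binding.

    Parameters
    ----------
    pwm : PwmRecord.
    weighting : "none", "local", or "regional" -- whether and at what
        resolution nucleosome occupancy weights modify Ka.
    concentration : protein concentration c; ``None`` picks
        1 / max(unweighted Ka over the genome), i.e. the best genomic site
        is half occupied.
    segment, regional_window, weight_base, pseudocount : see module docs.

    After ``fit(genome, tagmap=...)``:

    weights_ : WeightTrack or None
    concentration_ : the c actually used
    max_ka_ : genome-wide maximum unweighted Ka
    """

    def __init__(
        self,
        pwm: PwmRecord,
        weighting: str = "none",
        concentration: float | None = None,
        segment: int = DEFAULT_SEGMENT,
        regional_window: int = DEFAULT_REGIONAL_WINDOW,
        weight_base: float = DEFAULT_WEIGHT_BASE,
        pseudocount: float = 0.01,
    ):
        self.pwm = pwm
        self.weighting = weighting
        self.concentration = concentration
        self.segment = segment
        self.regional_window = regional_window
        self.weight_base = weight_base
        self.pseudocount = pseudocount

    def fit(self, X: GenomeSequence, y=None, tagmap: TagMap | None = None):
        if self.weighting not in ("none", "local", "regional"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")
        if self.weighting != "none" and tagmap is None:
            raise ConfigError("weighting requires a tagmap")
        self.genome_ = X
        self.weights_ = (
            segment_weights(
                tagmap,
                segment=self.segment,
                regional_window=self.regional_window,
                W=self.weight_base,
                use_regional=(self.weighting == "regional"),
            )
            if self.weighting != "none"
            else None
        )
        max_ka = 0.0
        for name in X.names:
            ls = ka_landscape(self.pwm, X[name], self.pseudocount)
            if ls.valid.any():
                max_ka = max(max_ka, float(ls.ka.max()))
        if max_ka <= 0:
            raise DegenerateInputError("no valid motif window in genome")
        self.max_ka_ = max_ka
        self.concentration_ = (
            self.concentration if self.concentration is not None
            else 1.0 / max_ka
        )
        return self

    def landscape(self, chrom: str, start: int, end: int) -> AffinityLandscape:
        ls = ka_landscape(self.pwm, self.genome_[chrom][start:end],
                          self.pseudocount)
        if self.weights_ is not None:
            ls = weighted_ka(ls, self.weights_, chrom, start)
        return ls

    def predict_proba(self, promoters: pd.DataFrame) -> np.ndarray:
        """P(bound) for each promoter interval (columns chrom, start, end)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "concentration_")
        return np.array([
            p_bound_promoter(
                self.landscape(row.chrom, row.start, row.end),
                self.concentration_,
            )
            for row in promoters.itertuples(index=False)
        ])


def evaluate_variants(
    genome: GenomeSequence,
    tagmap: TagMap,
    pwm: PwmRecord,
    promoters: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
    concentration: float | None = None,
    regional_window: int = DEFAULT_REGIONAL_WINDOW,
) -> dict:
    """Score promoters under the three model variants and compare AUCs.

    ``promoters`` needs columns (chrom, start, end, bound).  Negatives are
    ``n_random`` promoters drawn at random with replacement (the random-
    promoter background); the same concentration and the same negatives are
    shared by all variants so the AUCs are directly comparable.

    Returns {"results": {variant: RocResult}, "scores": DataFrame,
    "delta_vs_unweighted": {variant: float}}.
    """
    rng = np.random.default_rng(seed)
    base = GomerModel(pwm, weighting="none",
                      concentration=concentration).fit(genome)
    c = base.concentration_
    models = {
        "unweighted": base,
        "local15": GomerModel(pwm, weighting="local", concentration=c,
                              regional_window=regional_window
                              ).fit(genome, tagmap=tagmap),
        "blurred600": GomerModel(pwm, weighting="regional", concentration=c,
                                 regional_window=regional_window
                                 ).fit(genome, tagmap=tagmap),
    }
    scores = pd.DataFrame({
        "chrom": promoters["chrom"],
        "start": promoters["start"],
        "end": promoters["end"],
        "bound": promoters["bound"].astype(bool),
    })
    neg_idx = rng.integers(0, len(promoters), size=n_random)
    results: dict[str, RocResult] = {}
    for name, model in models.items():
        p = model.predict_proba(promoters)
        scores[f"p_{name}"] = p
        results[name] = roc_auc(
            p[scores["bound"].to_numpy()], p[neg_idx],
            low_predicts_positive=False,
        )
    delta = {
        name: results[name].auc - results["unweighted"].auc
        for name in ("local15", "blurred600")
    }
    return {"results": results, "scores": scores,
            "delta_vs_unweighted": delta}
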