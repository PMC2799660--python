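"""Motif-site bookkeeping: ChIP p-value assignment, bound/unbound labels,
p-value bins, eligible TFs, and random promoter controls.

Motif sites live in a pandas DataFrame with columns
``tf, chrom, start, end, strand, chip_p`` (0-based half-open coordinates,
strand in {+,-}, chip_p in (0, 1]).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .genome import GenomeSequence

logger = logging.getLogger(__name__)

BOUND_ALPHA = 1e-3
PROMOTER_LENGTH = 600

#: right-closed p-value bin edges for unbound motifs
PVALUE_BIN_EDGES = (1e-3, 1e-2, 1e-1, 0.5, 1.0)
PVALUE_BIN_LABELS = ("0.001-0.01", "0.01-0.1", "0.1-0.5", ">0.5")


def assign_probe_pvalue(sites: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Give each site the chip_p of the microarray probe containing its center.

    Probes must be non-overlapping within a chromosome.  Sites whose center
    falls in no probe are dropped; the count is logged.  Existing chip_p
    values on the sites are replaced.
    """
    out_rows = []
    n_dropped = 0
    by_chrom = {c: g.sort_values("start") for c, g in probes.groupby("chrom")}
    for chrom, grp in sites.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            n_dropped += len(grp)
            continue
        p = by_chrom[chrom]
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        pvals = p["chip_p"].to_numpy()
        centers = (grp["start"] + (grp["end"] - grp["start"] - 1) // 2).to_numpy()
        idx = np.searchsorted(starts, centers, side="right") - 1
        inside = (idx >= 0) & (centers < ends[np.clip(idx, 0, len(ends) - 1)])
        n_dropped += int((~inside).sum())
        kept = grp.loc[inside].copy()
        kept["chip_p"] = pvals[idx[inside]]
        out_rows.append(kept)
    if n_dropped:
        logger.info("assign_probe_pvalue: dropped %d site(s) with no probe",
                    n_dropped)
    if not out_rows:
        return sites.iloc[0:0].copy()
    return pd.concat(out_rows).sort_index()


def classify_bound(sites: pd.DataFrame, alpha: float = BOUND_ALPHA) -> pd.DataFrame:
    """Add a boolean ``bound`` column: chip_p strictly below ``alpha``."""
    out = sites.copy()
    out["bound"] = out["chip_p"] < alpha
    return out


def bin_by_pvalue(sites: pd.DataFrame) -> pd.DataFrame:
    """Bin *unbound* motifs by chip_p into right-closed intervals
    (1e-3,1e-2], (1e-2,1e-1], (1e-1,0.5], (0.5,1].

    Returns the unbound sites with a categorical ``pvalue_bin`` column.
    Bound sites (chip_p < 1e-3) are excluded.
    """
    sites = classify_bound(sites)
    unbound = sites.loc[~sites["bound"]].copy()
    unbound["pvalue_bin"] = pd.cut(
        unbound["chip_p"],
        bins=list(PVALUE_BIN_EDGES),
        labels=list(PVALUE_BIN_LABELS),
        right=True,
    )
    return unbound


def eligible_tfs(sites: pd.DataFrame, min_bound: int = 50) -> list[str]:
    """TFs with at least ``min_bound`` bound sites."""
    sites = classify_bound(sites)
    counts = sites.loc[sites["bound"]].groupby("tf").size()
    return sorted(counts.index[counts >= min_bound])


def promoters_from_gene_starts(
    genome: GenomeSequence,
    gene_starts: pd.DataFrame,
    upstream: int = PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Promoter intervals: ``upstream`` bp 5' of each gene start (plus-strand
    genes; clipped at the chromosome start)."""
    rows = []
    for row in gene_starts.itertuples(index=False):
        rows.append(
            {
                "chrom": row.chrom,
                "start": max(row.gene_start - upstream, 0),
                "end": row.gene_start,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def random_promoter_sites(
    promoters: pd.DataFrame, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Sample ``n`` basepairs uniformly from the union of promoter intervals
    (with replacement).  Returns columns (chrom, pos)."""
    if len(promoters) == 0:
        raise DegenerateInputError("empty promoter set")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    lengths = (promoters["end"] - promoters["start"]).to_numpy()
    if (lengths <= 0).any():
        raise DegenerateInputError("promoter with non-positive length")
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    draws = rng.integers(0, offsets[-1], size=n)
    which = np.searchsorted(offsets, draws, side="right") - 1
    pos = promoters["start"].to_numpy()[which] + (draws - offsets[which])
    return pd.DataFrame(
        {"chrom": promoters["chrom"].to_numpy()[which], "pos": pos}
    )
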