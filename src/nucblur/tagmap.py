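"""Per-basepair nucleosome occupancy tracks and operations on them.

An MNase-protection experiment yields "tags": inferred 146-bp
nuclease-protected fragments.  The number of tags spanning a basepair is the
nucleosome occupancy at that basepair.  This module builds such tracks from
tag 5' starts, normalizes them, averages them over windows ("blurring", to
emulate lower-resolution data), extracts site-centered meta-profiles, and
forms crosslinked-minus-uncrosslinked difference maps.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BoundsError, DegenerateInputError, ShapeError
from .genome import GenomeSequence

logger = logging.getLogger(__name__)

TAG_LENGTH = 146

#: window sizes used to emulate progressively lower-resolution data
BLUR_WINDOW_SIZES = (15, 40, 75, 150, 300, 600)


@dataclass
class TagMap:
    """Chromosome name -> per-bp occupancy array.

    ``signed`` is False for ordinary coverage (values must be >= 0) and True
    for difference maps, whose values may be negative.
    """

    tracks: dict[str, np.ndarray]
    tag_length: int = TAG_LENGTH
    normalization: str = "raw"  # raw | mean1 | scaled_to_ref
    signed: bool = False

    def __post_init__(self) -> None:
        self.tracks = {
            name: np.asarray(arr, dtype=float) for name, arr in self.tracks.items()
        }
        for name, arr in self.tracks.items():
            if not np.isfinite(arr).all():
                raise ShapeError(f"track {name!r} contains non-finite values")
            if not self.signed and arr.size and arr.min() < 0:
                raise ShapeError(f"track {name!r} contains negative occupancy")

    @property
    def names(self) -> list[str]:
        return list(self.tracks)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: arr.size for name, arr in self.tracks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.tracks[name]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.tracks.values()))

    def n_bp(self) -> int:
        return int(sum(arr.size for arr in self.tracks.values()))

    def mean(self) -> float:
        """Genome-wide mean occupancy (pooled over chromosomes)."""
        return self.total() / self.n_bp()

    def copy(self) -> "TagMap":
        return TagMap(
            {name: arr.copy() for name, arr in self.tracks.items()},
            tag_length=self.tag_length,
            normalization=self.normalization,
            signed=self.signed,
        )

    def same_shape_as(self, other: "TagMap") -> bool:
        return self.lengths == other.lengths


@dataclass
class OccupancyProfile:
    """Mean occupancy at offsets -H..+H around a set of site centers."""

    values: np.ndarray
    n_sites: int
    n_dropped: int = 0
    symmetrized: bool = False
    source: str = "invivo"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size % 2 != 1:
            raise ShapeError("profile length must be odd (offsets -H..+H)")

    @property
    def half_width(self) -> int:
        return (self.values.size - 1) // 2

    @property
    def offsets(self) -> np.ndarray:
        h = self.half_width
        return np.arange(-h, h + 1)


def site_center(start: int, end: int) -> int:
    """Center basepair of a motif occupying [start, end).

    Even-length motifs have no central bp; the left of the two middle
    basepairs is used, and windowing compensates by extending one bp
    rightward (see :func:`window_average`).
    """
    return start + (end - start - 1) // 2


def coverage_from_tags(
    tag_starts, genome: GenomeSequence | dict[str, int], tag_length: int = TAG_LENGTH
) -> TagMap:
    """Pile up 146-bp tags into a per-bp occupancy track.

    Each tag covers ``[start, start + tag_length)``; tags running past the
    chromosome end contribute only their in-bounds basepairs.

    Parameters
    ----------
    tag_starts : DataFrame with columns (chrom, start), or mapping
        chromosome -> integer start array.  Starts are the leftmost bp of
        the protected fragment; any strand information is ignored.
    genome : GenomeSequence or chromosome->length mapping.
    """
    lengths = genome.lengths if isinstance(genome, GenomeSequence) else dict(genome)
    if isinstance(tag_starts, pd.DataFrame):
        grouped = {
            chrom: grp["start"].to_numpy(dtype=np.int64)
            for chrom, grp in tag_starts.groupby("chrom", sort=False)
        }
    else:
        grouped = {c: np.asarray(s, dtype=np.int64) for c, s in tag_starts.items()}

    tracks: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        starts = grouped.pop(chrom, np.empty(0, dtype=np.int64))
        if starts.size and (starts.min() < 0 or starts.max() >= length):
            raise BoundsError(
                f"tag start outside chromosome {chrom!r} (length {length})"
            )
        # difference-array trick: +1 at start, -1 at clipped end, then cumsum
        delta = np.zeros(length + 1)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, np.minimum(starts + tag_length, length), -1.0)
        tracks[chrom] = np.cumsum(delta[:-1])
    if grouped:
        raise BoundsError(f"tags on unknown chromosomes: {sorted(grouped)}")
    return TagMap(tracks, tag_length=tag_length)


def normalize_mean1(tm: TagMap) -> TagMap:
    """Scale so the genome-wide mean occupancy is exactly 1."""
    mean = tm.mean()
    if mean <= 0:
        raise DegenerateInputError("cannot normalize an all-zero map")
    out = tm.copy()
    for arr in out.tracks.values():
        arr /= mean
    out.normalization = "mean1"
    return out


def window_average(
    tm: TagMap, chrom: str, center: int, size: int, motif_even: bool = False
) -> float:
    """Mean occupancy in a ``size``-bp window centered on ``center``.

    The window starts at ``center - size // 2``.  When the focal motif has
    even length (``motif_even``) the window is extended one bp rightward, so
    a nominal 15-bp window covers 16 bp; this keeps windows symmetric about
    the two middle basepairs of even motifs.  Out-of-bounds basepairs are
    excluded from the mean; a fully off-chromosome window is an error.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    arr = tm[chrom]
    start = center - size // 2
    end = start + size + (1 if motif_even else 0)
    if end <= 0 or start >= arr.size:
        raise BoundsError(
            f"window [{start},{end}) lies entirely off chromosome {chrom!r}"
        )
    return float(arr[max(start, 0) : min(end, arr.size)].mean())


def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding mean; windows shrink at the array edges."""
    if w <= 1:
        return x.astype(float, copy=True)
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def blur(tm: TagMap, window_bp: int) -> TagMap:
    """Replace each bp by its mean over a centered ``window_bp`` window.

    This emulates data of lower spatial resolution.  Windows shrink at
    chromosome ends (partial windows) so no basepair is left undefined.
    For bp ``i`` the window is ``[i - w//2, i - w//2 + w)``, matching
    :func:`window_average` for odd-length motifs.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out = tm.copy()
    out.tracks = {name: _sliding_mean(arr, window_bp) for name, arr in tm.tracks.items()}
    return out


def extract_profile(
    tm: TagMap,
    sites: pd.DataFrame,
    half_width: int = 600,
    symmetrize: bool = False,
    source: str = "invivo",
) -> OccupancyProfile:
    """Average occupancy at offsets -H..+H around site centers.

    Minus-strand sites are reversed before averaging so positive offsets
    always mean "downstream of the motif".  Sites whose window would be
    clipped at a chromosome end are dropped (the count is logged and stored
    on the profile).  ``symmetrize`` averages the profile with its mirror
    image, as is conventional for palindromic display.
    """
    h = half_width
    total = np.zeros(2 * h + 1)
    n_used = 0
    n_dropped = 0
    for row in sites.itertuples(index=False):
        arr = tm[row.chrom]
        c = site_center(row.start, row.end)
        if c - h < 0 or c + h + 1 > arr.size:
            n_dropped += 1
            continue
        window = arr[c - h : c + h + 1]
        if row.strand == "-":
            window = window[::-1]
        total += window
        n_used += 1
    if n_dropped:
        logger.info("extract_profile: dropped %d clipped site(s)", n_dropped)
    if n_used == 0:
        raise DegenerateInputError("no usable sites for profile extraction")
    values = total / n_used
    if symmetrize:
        values = 0.5 * (values + values[::-1])
    return OccupancyProfile(
        values, n_sites=n_used, n_dropped=n_dropped, symmetrized=symmetrize,
        source=source,
    )


def scale_to_reference(
    tm: TagMap,
    ref: TagMap,
    mode: str = "genome_total",
    sites: pd.DataFrame | None = None,
    flank_range: tuple[int, int] = (100, 600),
) -> TagMap:
    """Multiply ``tm`` by one scalar so it matches ``ref``.

    mode="genome_total"
        match total genome-wide occupancy.
    mode="flank"
        match the mean occupancy over the union of basepairs lying
        ``flank_range`` bp (inclusive) from the given site centers, on
        either side.  Used to normalize a crosslinked library to an
        uncrosslinked one away from the binding sites themselves.
    """
    if not tm.same_shape_as(ref):
        raise ShapeError("maps cover different genomes")
    if mode == "genome_total":
        denom = tm.total()
        numer = ref.total()
    elif mode == "flank":
        if sites is None or len(sites) == 0:
            raise DegenerateInputError("flank mode requires sites")
        lo, hi = flank_range
        masks = {name: np.zeros(n, dtype=bool) for name, n in tm.lengths.items()}
        for row in sites.itertuples(index=False):
            c = site_center(row.start, row.end)
            m = masks[row.chrom]
            m[max(c - hi, 0) : max(c - lo + 1, 0)] = True
            m[min(c + lo, m.size) : min(c + hi + 1, m.size)] = True
        numer = np.mean(np.concatenate([ref[n][m] for n, m in masks.items()]))
        denom = np.mean(np.concatenate([tm[n][m] for n, m in masks.items()]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom <= 0:
        raise DegenerateInputError("zero reference mass; cannot scale")
    s = numer / denom
    out = tm.copy()
    for arr in out.tracks.values():
        arr *= s
    out.normalization = "scaled_to_ref"
    return out


def difference_map(xlink: TagMap, unxlink: TagMap) -> TagMap:
    """Crosslinked minus (scaled) uncrosslinked occupancy, per basepair.

    The uncrosslinked map is first scaled so its genome-wide total matches
    the crosslinked map; the resulting difference therefore sums to zero.
    Positive values mark excess protection in crosslinked chromatin
    ("labile" nucleosomes trapped by the crosslinker).
    """
    if not xlink.same_shape_as(unxlink):
        raise ShapeError("maps cover different genomes")
    scaled = scale_to_reference(unxlink, xlink, mode="genome_total")
    tracks = {name: xlink[name] - scaled[name] for name in xlink.names}
    return TagMap(tracks, tag_length=xlink.tag_length, normalization="raw",
                  signed=True)
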