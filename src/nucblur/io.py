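"""Readers and writers for the on-disk formats.

FASTA (genomes, via Biopython), bedGraph (occupancy tracks), and headered
TSV for motif sites, tag starts, PWMs, and qPCR Ct tables.  All coordinates
on disk are 0-based half-open, matching the in-memory convention.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BoundsError, FormatError
from .genome import GenomeSequence, PwmRecord
from .tagmap import TagMap

SITE_COLUMNS = ["tf", "chrom", "start", "end", "strand", "chip_p"]
CT_COLUMNS = ["site_id", "replicate", "ct_ip", "ct_input", "is_control"]


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file; sequences are uppercased, N is allowed."""
    path = Path(path)
    sequences: dict[str, str] = {}
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise FormatError(f"duplicate FASTA header {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bedgraph_track(path, genome: GenomeSequence | dict[str, int]) -> TagMap:
    """Per-bp track from a bedGraph file (0-based half-open intervals,
    non-overlapping per chromosome; uncovered basepairs are 0)."""
    lengths = genome.lengths if isinstance(genome, GenomeSequence) else dict(genome)
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(("track", "browser", "#"))
    ]
    tracks = {name: np.zeros(n) for name, n in lengths.items()}
    if lines:
        from io import StringIO

        try:
            df = pd.read_csv(
                StringIO("\n".join(lines)), sep=r"\s+", header=None,
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64,
                       "value": float},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"malformed bedGraph {path}: {exc}") from exc
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"]].iloc[0]
            raise FormatError(
                f"bedGraph interval with end <= start: {bad.tolist()}"
            )
        for chrom, grp in df.groupby("chrom", sort=False):
            if chrom not in tracks:
                raise BoundsError(f"unknown chromosome {chrom!r} in {path}")
            if int(grp["end"].max()) > tracks[chrom].size:
                raise BoundsError(
                    f"interval beyond end of chromosome {chrom!r}"
                )
            grp = grp.sort_values("start")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise FormatError(
                    f"overlapping bedGraph intervals on {chrom!r}"
                )
            for row in grp.itertuples(index=False):
                tracks[chrom][row.start : row.end] = row.value
    signed = any(arr.size and arr.min() < 0 for arr in tracks.values())
    return TagMap(tracks, signed=signed)


def write_bedgraph_track(tm: TagMap, path) -> None:
    """Write a track as bedGraph, run-length encoded; zero runs omitted."""
    with open(path, "w") as fh:
        for chrom, arr in tm.tracks.items():
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            bounds = np.concatenate([[0], change, [arr.size]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                v = arr[lo]
                if v != 0:
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{v:.12g}\n")


def read_sites_tsv(path) -> pd.DataFrame:
    """Motif sites with ChIP p-values (columns tf, chrom, start, end,
    strand, chip_p)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"sites file missing column(s): {sorted(missing)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    p = df["chip_p"].to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise FormatError("chip_p must lie in (0, 1]")
    if (df["end"] <= df["start"]).any():
        raise FormatError("site with end <= start")
    return df


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_tag_starts_tsv(path) -> pd.DataFrame:
    """Tag 5' starts (columns chrom, start); each start is the leftmost bp
    of an inferred 146-bp protected fragment."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start"} - set(df.columns)
    if missing:
        raise FormatError(
            f"tag-starts file missing column(s): {sorted(missing)}")
    return df[["chrom", "start"]]


def write_tag_starts_tsv(starts: pd.DataFrame, path) -> None:
    starts[["chrom", "start"]].to_csv(path, sep="\t", index=False)


def read_pwm_tsv(path, name: str | None = None) -> PwmRecord:
    """PWM as a headered TSV with columns pos, A, C, G, T (one row per
    motif position; probabilities sum to 1 per row)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"pos", "A", "C", "G", "T"} - set(df.columns)
    if missing:
        raise FormatError(f"PWM file missing column(s): {sorted(missing)}")
    df = df.sort_values("pos")
    matrix = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    return PwmRecord(tf_name=name or Path(path).stem, matrix=matrix)


def write_pwm_tsv(pwm: PwmRecord, path) -> None:
    df = pd.DataFrame(pwm.matrix, columns=["A", "C", "G", "T"])
    df.insert(0, "pos", np.arange(len(pwm)))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ct_table(path) -> pd.DataFrame:
    """qPCR Ct table (columns site_id, replicate, ct_ip, ct_input,
    is_control); exactly two distinct control site_ids are required."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing column(s): {sorted(missing)}")
    if not np.isfinite(df[["ct_ip", "ct_input"]].to_numpy(dtype=float)).all():
        raise FormatError("non-finite Ct value")
    n_ctrl = df.loc[df["is_control"].astype(bool), "site_id"].nunique()
    if n_ctrl != 2:
        raise FormatError(
            f"Ct table must have exactly two control sites, found {n_ctrl}"
        )
    return df


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def file_digest(path, n: int = 12) -> str:
    """Short sha256 prefix of a file, for audit logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:n]
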