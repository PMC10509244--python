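"""Readers and writers for the plain-text formats the toolkit consumes.

Contact matrices arrive as sparse COO text (``bin1 bin2 count`` with an
optional leading chromosome column) or dense TSV; interval annotations as
BED; loops as BEDPE (six columns minimum). All tracks are written as
bedGraph. Coordinates follow the BED convention (0-based half-open).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .matrix import BinTrack, ContactMatrix


class ParseError(ValueError):
    """Malformed input line, reported with its line number."""


def read_contact_matrix(
    path: str,
    format: str = "coo_text",
    chrom: str = "chr1",
    resolution: int = 25000,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Load a per-chromosome contact matrix.

    ``coo_text`` lines are ``bin1 bin2 count`` (whitespace- or
    tab-separated) with an optional leading chromosome column; entries may
    cover the upper triangle only or both triangles (symmetrized by
    assignment, so duplicated mirror entries must agree). ``dense_tsv`` is a
    full symmetric table. Bins absent from a sparse file are zero; bins with
    a zero marginal are masked invalid.
    """
    if format == "cooler":
        raise NotImplementedError(
            "cooler input is not supported in this build; export the "
            "chromosome as COO text (e.g. 'cooler dump --table pixels') "
            "and use format='coo_text'"
        )
    if format == "dense_tsv":
        vals = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        return ContactMatrix(chrom, resolution, vals)
    if format != "coo_text":
        raise ValueError(f"unknown format {format!r}")

    rows: list[tuple[int, int, float]] = []
    max_bin = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 4:  # chrom bin1 bin2 count
                parts = parts[1:]
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if i < 0 or j < 0 or c < 0:
                raise ParseError(f"{path}:{lineno}: negative bin index or count")
            rows.append((i, j, c))
            max_bin = max(max_bin, i, j)
    if n_bins is None:
        n_bins = max_bin + 1
    elif max_bin >= n_bins:
        raise ParseError(f"{path}: bin index {max_bin} >= n_bins {n_bins}")
    vals = np.zeros((n_bins, n_bins))
    for i, j, c in rows:
        vals[i, j] = c
        vals[j, i] = c
    return ContactMatrix(chrom, resolution, vals)


def write_contact_matrix_coo(m: ContactMatrix, path: str) -> None:
    """Write the upper triangle (incl. diagonal) of nonzero entries."""
    with open(path, "w") as fh:
        iu, ju = np.triu_indices(m.n_bins)
        for i, j in zip(iu, ju):
            v = m.values[i, j]
            if np.isfinite(v) and v != 0:
                fh.write(f"{m.chrom}\t{i}\t{j}\t{v:g}\n")


def write_bedgraph(track: BinTrack, path: str) -> None:
    """Write defined bins of a track as bedGraph."""
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if np.isfinite(v):
                s = i * track.resolution
                fh.write(f"{track.chrom}\t{s}\t{s + track.resolution}\t{v:g}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str,
    names: Iterable[str] | None = None,
) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                row.append(names[k])
            fh.write("\t".join(row) + "\n")


BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def read_bedpe(path: str) -> pd.DataFrame:
    """Read a loop list; the first six columns are the two anchors."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ParseError(f"{path}: BEDPE needs >= 6 columns")
    df = df.iloc[:, :6]
    df.columns = BEDPE_COLUMNS
    return df


def read_deg_table(path: str) -> pd.DataFrame:
    """Gene table: gene id, chrom, TSS position, per-sample sign columns."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: DEG table needs gene/chrom/tss columns")
    return df


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
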