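"""Readers and writers for the plain-text formats the pipeline touches.

Coordinates are 0-based half-open everywhere (BED convention), including
bedGraph output.  Window values are written as Python's shortest round-trip
decimal repr, so write-then-read reproduces values exactly.

Every writer accepts a ``meta`` mapping emitted as ``# key=value`` provenance
header lines (config hash, seed, method tags); readers collect such lines back
into ``DataFrame.attrs['meta']``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# window tracks
# ---------------------------------------------------------------------------

@dataclass
class WindowTrack:
    """Sorted, non-overlapping fixed-width genomic windows, one value each.

    ``frame`` has columns ``chrom, start, end, value``; ``value`` may be NaN
    for masked/missing windows.  Windows are validated to be sorted and
    non-overlapping within each chromosome on construction.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "value"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"WindowTrack frame missing columns {missing}")
        self.frame = self.frame[required].reset_index(drop=True)
        self.frame["start"] = self.frame["start"].astype(np.int64)
        self.frame["end"] = self.frame["end"].astype(np.int64)
        self.frame["value"] = self.frame["value"].astype(float)
        if (self.frame["end"] <= self.frame["start"]).any():
            bad = self.frame.index[self.frame["end"] <= self.frame["start"]][0]
            raise ValueError(f"window {bad}: end <= start")
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError(f"windows on {chrom} are not sorted by start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping windows on {chrom}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def with_values(self, values, meta: dict | None = None) -> "WindowTrack":
        """Same windows, new values (and optionally new metadata)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self),):
            raise ValueError("value array length does not match window count")
        frame = self.frame.copy()
        frame["value"] = values
        return WindowTrack(frame, dict(self.meta if meta is None else meta))

    def same_windows(self, other: "WindowTrack") -> bool:
        a = self.frame[["chrom", "start", "end"]]
        b = other.frame[["chrom", "start", "end"]]
        return len(a) == len(b) and bool((a.to_numpy() == b.to_numpy()).all())


def _format_value(v: float) -> str:
    if np.isnan(v):
        return "nan"
    return repr(float(v))


def write_windowtrack(track: WindowTrack, path: str | Path, dialect: str = "bedgraph",
                      meta: dict | None = None) -> None:
    """Write a track as bedGraph (4 columns, no header) or TSV (with header)."""
    if dialect not in ("bedgraph", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = {**track.meta, **(meta or {})}
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        if dialect == "tsv":
            fh.write("chrom\tstart\tend\tvalue\n")
        for row in track.frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{_format_value(row.value)}\n")


def read_windowtrack(path: str | Path) -> WindowTrack:
    """Read a bedGraph or 4-column TSV track (auto-detected by header line)."""
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("track"):
                continue
            parts = line.split("\t")
            if parts[:4] == ["chrom", "start", "end", "value"]:
                continue  # TSV dialect header
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return WindowTrack(frame, meta)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into a sorted interval frame.

    Returns columns ``chrom, start, end`` plus ``name``/``score`` when
    present.  Intervals are 0-based half-open.  If the file was not sorted by
    (chrom, start), the output is re-sorted and ``attrs['resorted']`` is True.
    """
    rows = []
    ncols = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            rows.append((parts[0], start, end, *parts[3:5]))
            ncols = max(ncols, min(len(parts), 5))
    columns = ["chrom", "start", "end", "name", "score"][:max(ncols, 3)]
    frame = pd.DataFrame([r[: len(columns)] for r in rows], columns=columns)
    if frame.empty:
        frame = pd.DataFrame(columns=columns)
    sorted_frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    resorted = not frame.reset_index(drop=True).equals(sorted_frame)
    if resorted:
        warnings.warn(f"{path}: intervals were not sorted; output re-sorted", stacklevel=2)
    sorted_frame.attrs["resorted"] = resorted
    return sorted_frame


def write_bed(frame: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in frame.columns]
        for row in frame[cols].itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA summaries
# ---------------------------------------------------------------------------

def read_fasta_summary(path: str | Path) -> dict:
    """Record count, total bp and median length of a FASTA repeat library.

    Median uses the average-of-middle-two convention for even record counts
    (reported under ``median_convention`` so the check is reproducible).
    Duplicate record ids are an error.
    """
    lengths = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        lengths.append(len(rec.seq))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA record ids: {dups}")
    return {
        "n_sequences": len(lengths),
        "total_bp": int(sum(lengths)),
        "median_length": float(np.median(lengths)) if lengths else float("nan"),
        "median_convention": "mean_of_middle_two",
    }


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables with provenance headers
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line.lstrip("# ").rstrip("\n")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh, sep="\t")
    frame.attrs["meta"] = meta
    return frame
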