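"""Plain-text readers and writers for counts, distributions, and results.

Accepted count/value inputs:

* CSV with header ``bin,count`` — one row per bin (bins are 1-based in files);
* CSV with header ``value`` — raw numeric observations, binned on read;
* bare whitespace- or comma-separated numbers (one histogram of counts).

Distribution files are CSV with header ``bin,probability``; probabilities are
written with 17 significant digits so a write/read round trip is exact.
Internally bins are 0-indexed; all file formats use the 1-based bin labels
``k = 1..K``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .distributions import BinGrid, BinnedDistribution, SampleCounts, default_grid, histogram_from_values

__all__ = ["read_counts", "read_distribution", "write_distribution", "write_counts"]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def _lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            out.append((i, stripped))
    if not out:
        raise ParseError(f"{path}: file contains no data")
    return out


def _int_count(token: str, path, lineno: int) -> int:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: not a number: {token!r}") from None
    if value != int(value):
        raise ParseError(f"{path}:{lineno}: count must be an integer, got {token!r}")
    if value < 0:
        raise ParseError(f"{path}:{lineno}: count must be non-negative, got {token!r}")
    return int(value)


def read_counts(path: str | Path, grid: BinGrid | None = None) -> SampleCounts:
    """Read a histogram (or raw values to be binned) from a text file.

    With a ``bin,count`` header the number of rows fixes K; with a ``value``
    header or bare numbers-as-counts, ``grid`` (defaulting to the K-bin
    benchmark grid) supplies the binning.
    """
    lines = _lines(path)
    header = lines[0][1].lower().replace(" ", "")
    if header.startswith("bin,count"):
        counts = []
        for lineno, line in lines[1:]:
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'bin,count', got {line!r}")
            counts.append(_int_count(parts[1], path, lineno))
        g = grid if grid is not None else default_grid(len(counts))
        if g.k != len(counts):
            raise ParseError(f"{path}: {len(counts)} rows but grid has {g.k} bins")
        return SampleCounts(g, np.array(counts, dtype=np.int64))
    if header == "value":
        values = []
        for lineno, line in lines[1:]:
            try:
                values.append(float(line))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: not a number: {line!r}") from None
        g = grid if grid is not None else default_grid()
        return histogram_from_values(values, g)
    # bare counts, whitespace/comma separated, possibly spread over lines
    counts = []
    for lineno, line in lines:
        for token in line.replace(",", " ").split():
            counts.append(_int_count(token, path, lineno))
    g = grid if grid is not None else default_grid(len(counts))
    if g.k != len(counts):
        raise ParseError(f"{path}: {len(counts)} counts but grid has {g.k} bins")
    return SampleCounts(g, np.array(counts, dtype=np.int64))


def read_distribution(path: str | Path, grid: BinGrid | None = None) -> BinnedDistribution:
    """Read a ``bin,probability`` CSV (or bare probabilities) as a distribution."""
    lines = _lines(path)
    header = lines[0][1].lower().replace(" ", "")
    probs = []
    rows = lines[1:] if header.startswith("bin,probability") else lines
    for lineno, line in rows:
        parts = line.replace(",", " ").split()
        token = parts[-1]
        try:
            p = float(token)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: not a number: {token!r}") from None
        if not 0.0 <= p <= 1.0:
            raise ParseError(f"{path}:{lineno}: probability {p} outside [0, 1]")
        probs.append(p)
    total = sum(probs)
    if abs(total - 1.0) > 1e-6:
        raise ParseError(f"{path}: probabilities sum to {total!r}, not 1")
    arr = np.array(probs) / total
    g = grid if grid is not None else default_grid(len(arr))
    if g.k != len(arr):
        raise ParseError(f"{path}: {len(arr)} probabilities but grid has {g.k} bins")
    return BinnedDistribution(g, arr)


def write_distribution(path: str | Path, dist: BinnedDistribution) -> None:
    """Write a distribution as ``bin,probability`` CSV (1-based bins, full precision)."""
    rows = ["bin,probability"]
    rows += [f"{k + 1},{p:.17g}" for k, p in enumerate(dist.probs)]
    Path(path).write_text("\n".join(rows) + "\n")


def write_counts(path: str | Path, counts: SampleCounts) -> None:
    """Write a histogram as ``bin,count`` CSV (1-based bins)."""
    rows = ["bin,count"]
    rows += [f"{k + 1},{c}" for k, c in enumerate(counts.counts)]
    Path(path).write_text("\n".join(rows) + "\n")
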