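"""Probe-level signal tracks: readers, probe-to-region assignment, summaries.

A track is a position-sorted set of tiling-array probes, each carrying one
log2 enrichment ratio (mark vs input) for one mark in one condition.  Probes
belong to a region when their midpoint falls inside it (configurable to
any-overlap); summaries are unweighted probe means, and regions with no
probes yield *missing* values, never zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .annotations import AnalysisParams, Region

__all__ = [
    "ProbeSignal",
    "SignalTrack",
    "SignalParseError",
    "read_signal_track",
    "assign_probes",
    "assign_probe_values",
    "region_mean_signal",
    "positive_fraction",
]


class SignalParseError(ValueError):
    """Raised on malformed signal input; names the offending line."""


@dataclass(frozen=True)
class ProbeSignal:
    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"probe [{self.start},{self.end}) is empty")
        if not np.isfinite(self.value):
            raise ValueError("probe value must be finite")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class SignalTrack:
    """Probes for one (mark, condition), sorted by (chrom, start)."""

    def __init__(self, mark: str, condition: str) -> None:
        if not mark or not condition:
            raise ValueError("mark and condition must be non-empty")
        self.mark = mark
        self.condition = condition
        # chrom -> dict(starts, ends, values, mids) as numpy arrays
        self._data: dict[str, dict[str, np.ndarray]] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        mark: str,
        condition: str,
        records: Iterable[tuple[str, int, int, float]],
        collapse_duplicates: bool = True,
    ) -> "SignalTrack":
        track = cls(mark, condition)
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, rows in by_chrom.items():
            arr = np.asarray(rows, dtype=float)
            starts = arr[:, 0].astype(np.int64)
            ends = arr[:, 1].astype(np.int64)
            values = arr[:, 2]
            track._set_chrom(chrom, starts, ends, values, collapse_duplicates)
        return track

    @classmethod
    def from_arrays(
        cls,
        mark: str,
        condition: str,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        values: np.ndarray,
    ) -> "SignalTrack":
        track = cls(mark, condition)
        track._set_chrom(
            chrom,
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(values, dtype=float),
            collapse_duplicates=True,
        )
        return track

    def _set_chrom(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        values: np.ndarray,
        collapse_duplicates: bool,
    ) -> None:
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: empty probe interval")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{chrom}: non-finite probe value")
        order = np.lexsort((ends, starts))
        starts, ends, values = starts[order], ends[order], values[order]
        if collapse_duplicates and len(starts) > 1:
            same = (np.diff(starts) == 0) & (np.diff(ends) == 0)
            if np.any(same):
                keys = np.stack([starts, ends], axis=1)
                uniq, inverse, counts = np.unique(
                    keys, axis=0, return_inverse=True, return_counts=True
                )
                sums = np.zeros(len(uniq))
                np.add.at(sums, inverse, values)
                warnings.warn(
                    f"{self.mark}/{self.condition} {chrom}: collapsed "
                    f"{len(starts) - len(uniq)} duplicate probe interval(s) by mean"
                )
                starts, ends = uniq[:, 0], uniq[:, 1]
                values = sums / counts
        self._data[chrom] = {
            "starts": starts,
            "ends": ends,
            "values": values,
            "mids": (starts + ends) // 2,
        }

    # -- access -------------------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._data))

    @property
    def n_probes(self) -> int:
        return sum(len(d["starts"]) for d in self._data.values())

    def arrays(self, chrom: str) -> dict[str, np.ndarray]:
        return self._data.get(
            chrom,
            {
                "starts": np.empty(0, np.int64),
                "ends": np.empty(0, np.int64),
                "values": np.empty(0, float),
                "mids": np.empty(0, np.int64),
            },
        )

    def iter_probes(self) -> Iterator[ProbeSignal]:
        for chrom in self.chroms:
            d = self._data[chrom]
            for s, e, v in zip(d["starts"], d["ends"], d["values"]):
                yield ProbeSignal(chrom, int(s), int(e), float(v))

    @property
    def probes(self) -> list[ProbeSignal]:
        return list(self.iter_probes())

    def select(self, region: Region, membership: str = "midpoint") -> np.ndarray:
        """Boolean-free fast path: indices of probes belonging to the region."""
        d = self.arrays(region.chrom)
        if membership == "midpoint":
            mids = d["mids"]
            if len(mids) > 1 and np.any(np.diff(mids) < 0):
                mask = (mids >= region.start) & (mids < region.end)
                return np.nonzero(mask)[0]
            lo = np.searchsorted(mids, region.start, side="left")
            hi = np.searchsorted(mids, region.end, side="left")
            return np.arange(lo, hi)
        if membership == "overlap":
            mask = (d["starts"] < region.end) & (d["ends"] > region.start)
            return np.nonzero(mask)[0]
        raise ValueError(f"unknown membership rule {membership!r}")


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

def assign_probe_values(
    track: SignalTrack, region: Region, params: AnalysisParams | None = None
) -> np.ndarray:
    """Values of the probes assigned to ``region`` (possibly empty)."""
    params = params or AnalysisParams()
    idx = track.select(region, params.membership)
    return track.arrays(region.chrom)["values"][idx]


def assign_probes(
    track: SignalTrack, region: Region, params: AnalysisParams | None = None
) -> list[ProbeSignal]:
    """Probes assigned to ``region``; strand-agnostic membership."""
    params = params or AnalysisParams()
    idx = track.select(region, params.membership)
    d = track.arrays(region.chrom)
    return [
        ProbeSignal(region.chrom, int(d["starts"][i]), int(d["ends"][i]), float(d["values"][i]))
        for i in idx
    ]


def region_mean_signal(
    track: SignalTrack, region: Region, params: AnalysisParams | None = None
) -> float | None:
    """Unweighted mean probe log2 ratio, or None with < min_probes probes."""
    params = params or AnalysisParams()
    values = assign_probe_values(track, region, params)
    if len(values) < params.min_probes:
        return None
    return float(values.mean())


def positive_fraction(
    track: SignalTrack, region: Region, params: AnalysisParams | None = None
) -> float | None:
    """Fraction of assigned probes strictly above ``theta_pos``.

    Returns None when no probe is assigned; a probe exactly at the threshold
    is not positive.
    """
    params = params or AnalysisParams()
    values = assign_probe_values(track, region, params)
    if len(values) == 0:
        return None
    return float(np.count_nonzero(values > params.theta_pos) / len(values))


# ---------------------------------------------------------------------------
# Readers: bedGraph, WIG, 4-column TSV (optionally bigWig)
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".bedgraph", ".bdg"):
        return "bedgraph"
    if suffix == ".wig":
        return "wig"
    if suffix in (".bw", ".bigwig"):
        return "bigwig"
    return "tsv4"


def _iter_bedgraph(path: Path) -> Iterator[tuple[str, int, int, float]]:
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise SignalParseError(f"line {lineno}: expected 4 columns")
            try:
                yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise SignalParseError(
                    f"line {lineno}: non-numeric value in {fields[1:4]!r}"
                ) from exc


def _iter_wig(path: Path) -> Iterator[tuple[str, int, int, float]]:
    mode = None  # ("fixed", chrom, pos, step, span) | ("variable", chrom, span)
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                kv = dict(
                    tok.split("=", 1) for tok in line.split()[1:] if "=" in tok
                )
                try:
                    span = int(kv.get("span", "1"))
                    if line.startswith("fixedStep"):
                        mode = [
                            "fixed", kv["chrom"], int(kv["start"]) - 1,
                            int(kv["step"]), span,
                        ]
                    else:
                        mode = ["variable", kv["chrom"], span]
                except (KeyError, ValueError) as exc:
                    raise SignalParseError(
                        f"line {lineno}: malformed WIG declaration"
                    ) from exc
                continue
            if mode is None:
                raise SignalParseError(f"line {lineno}: data before WIG declaration")
            try:
                if mode[0] == "fixed":
                    _, chrom, pos, step, span = mode
                    yield chrom, pos, pos + span, float(line.split()[0])
                    mode[2] = pos + step
                else:
                    _, chrom, span = mode
                    p, v = line.split()[:2]
                    start = int(p) - 1
                    yield chrom, start, start + span, float(v)
            except (ValueError, IndexError) as exc:
                raise SignalParseError(f"line {lineno}: bad WIG data line") from exc


def _iter_bigwig(path: Path) -> Iterator[tuple[str, int, int, float]]:
    import pyBigWig  # optional dependency; same contract as text readers

    bw = pyBigWig.open(str(path))
    try:
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or ():
                yield chrom, start, end, float(value)
    finally:
        bw.close()


def read_signal_track(
    path: str | Path,
    format: str | None = None,
    mark: str = "signal",
    condition: str = "NA",
) -> SignalTrack:
    """Read a probe-level log2-ratio track.

    Formats: ``bedgraph``, ``wig`` (fixed/variable step), ``tsv4``
    (chrom/start/end/value; one header line tolerated), ``bigwig``.  Probes
    come back sorted; duplicate identical intervals are collapsed by mean
    with a warning; unsorted input is sorted silently.
    """
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt in ("bedgraph", "tsv4"):
        rows = _iter_bedgraph_tolerant(path) if fmt == "tsv4" else _iter_bedgraph(path)
    elif fmt == "wig":
        rows = _iter_wig(path)
    elif fmt == "bigwig":
        rows = _iter_bigwig(path)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")
    return SignalTrack.from_records(mark, condition, rows)


def _iter_bedgraph_tolerant(path: Path) -> Iterator[tuple[str, int, int, float]]:
    """tsv4 dialect: identical to bedGraph but a single header line is allowed."""
    it = _iter_bedgraph_with_header_skip(path)
    yield from it


def _iter_bedgraph_with_header_skip(path: Path) -> Iterator[tuple[str, int, int, float]]:
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise SignalParseError(f"line {lineno}: expected 4 columns")
            try:
                yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                if lineno == 1 and not fields[1].lstrip("-").isdigit():
                    continue  # header row (non-numeric start column)
                raise SignalParseError(
                    f"line {lineno}: non-numeric value in {fields[1:4]!r}"
                ) from exc
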