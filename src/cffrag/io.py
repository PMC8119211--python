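"""Fragment-length I/O: BAM/BED/TSV readers and size-profile construction.

cfDNA fragment lengths are taken from paired-end alignments (absolute template
length of the first-in-pair primary alignment), from BED intervals
(``end - start``), or from pre-aggregated ``length<TAB>count`` tables.  A
:class:`SizeProfile` is the per-base-pair normalized frequency of fragment
lengths over a closed support window, the basic object every downstream
statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FragmentSet",
    "SizeProfile",
    "EmptyFragmentSetError",
    "MalformedRecordError",
    "DEFAULT_SUPPORT",
    "read_lengths_bam",
    "read_lengths_bed",
    "read_length_table",
    "write_length_table",
    "build_profile",
    "write_profile",
    "read_profile",
]

#: Default WGS support window in bp (lower/upper detection limits of
#: sequencing-based cfDNA sizing).
DEFAULT_SUPPORT = (30, 1000)

ASSAYS = ("DSP", "SSP", "RAW")


class EmptyFragmentSetError(ValueError):
    """No fragments were retained after filtering."""


class MalformedRecordError(ValueError):
    """A record in an input file violates the format contract."""


def _check_assay(assay: str) -> str:
    if assay not in ASSAYS:
        raise ValueError(f"assay must be one of {ASSAYS}, got {assay!r}")
    return assay


@dataclass
class FragmentSet:
    """Multiset of integer fragment lengths with an assay label.

    ``counts`` maps length (bp) -> number of fragments of that length.
    """

    assay: str = "RAW"
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_assay(self.assay)
        for length, count in self.counts.items():
            if length < 1:
                raise ValueError(f"fragment length must be >= 1, got {length}")
            if count < 1:
                raise ValueError(f"count must be >= 1 for length {length}, got {count}")

    @classmethod
    def from_lengths(cls, lengths: Iterable[int], assay: str = "RAW") -> "FragmentSet":
        arr = np.asarray(list(lengths), dtype=np.int64)
        if arr.size and arr.min() < 1:
            raise ValueError("fragment lengths must be >= 1")
        uniq, cnt = np.unique(arr, return_counts=True)
        return cls(assay=assay, counts={int(l): int(c) for l, c in zip(uniq, cnt)})

    @classmethod
    def from_arrays(
        cls, lengths: np.ndarray, counts: np.ndarray, assay: str = "RAW"
    ) -> "FragmentSet":
        """Build from aligned arrays of unique lengths and positive counts."""
        d: dict[int, int] = {}
        for l, c in zip(np.asarray(lengths), np.asarray(counts)):
            c = int(c)
            if c > 0:
                d[int(l)] = d.get(int(l), 0) + c
        return cls(assay=assay, counts=d)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def lengths(self) -> np.ndarray:
        """Sorted unique lengths present in the set."""
        return np.array(sorted(self.counts), dtype=np.int64)

    def merge(self, other: "FragmentSet") -> "FragmentSet":
        if other.assay != self.assay:
            raise ValueError(
                f"cannot merge assays {self.assay!r} and {other.assay!r}"
            )
        merged = dict(self.counts)
        for l, c in other.counts.items():
            merged[l] = merged.get(l, 0) + c
        return FragmentSet(assay=self.assay, counts=merged)

    def subset(self, lo: int, hi: int) -> "FragmentSet":
        """Fragments with lo <= length <= hi."""
        return FragmentSet(
            assay=self.assay,
            counts={l: c for l, c in self.counts.items() if lo <= l <= hi},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self.assay == other.assay and self.counts == other.counts


@dataclass
class SizeProfile:
    """Per-length normalized frequency over a closed support window.

    ``freqs[i]`` is the frequency of fragments of length ``support[0] + i``;
    frequencies sum to 1 over the support.  ``n_fragments`` is the absolute
    number of fragments the profile was normalized over.
    """

    assay: str
    support: tuple[int, int]
    freqs: np.ndarray
    n_fragments: int

    def __post_init__(self) -> None:
        _check_assay(self.assay)
        lo, hi = self.support
        if not (20 <= lo <= hi <= 1500):
            raise ValueError(f"support must lie within [20, 1500], got {self.support}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (hi - lo + 1,):
            raise ValueError("freqs length must match support width")
        if (self.freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 over the support")

    @property
    def lengths(self) -> np.ndarray:
        lo, hi = self.support
        return np.arange(lo, hi + 1, dtype=np.int64)

    @property
    def freq(self) -> Mapping[int, float]:
        """Mapping view length -> frequency (zero outside support)."""
        return {int(l): float(f) for l, f in zip(self.lengths, self.freqs)}

    def frequency(self, length: int) -> float:
        lo, hi = self.support
        if not lo <= length <= hi:
            return 0.0
        return float(self.freqs[length - lo])

    def renormalized(self, lo: int, hi: int) -> "SizeProfile":
        """Restrict to [lo, hi] (clipped to the support) and renormalize."""
        slo, shi = self.support
        lo, hi = max(lo, slo), min(hi, shi)
        if lo > hi:
            raise ValueError("requested window does not overlap the support")
        sub = self.freqs[lo - slo : hi - slo + 1]
        total = sub.sum()
        if total <= 0:
            raise EmptyFragmentSetError(
                f"no frequency mass within [{lo}, {hi}] for assay {self.assay}"
            )
        return SizeProfile(
            assay=self.assay,
            support=(lo, hi),
            freqs=sub / total,
            n_fragments=int(round(self.n_fragments * total)),
        )


def read_lengths_bam(
    path: str | Path,
    min_mapq: int = 20,
    length_window: tuple[int, int] = DEFAULT_SUPPORT,
    keep_duplicates: bool = False,
) -> FragmentSet:
    """Read fragment lengths from a coordinate-sorted, indexed BAM/SAM file.

    One length per properly paired fragment: the absolute template length
    (TLEN) of the first-in-pair, primary, non-supplementary alignment.
    Duplicate-flagged pairs are excluded unless ``keep_duplicates``.
    """
    import pysam

    lo, hi = length_window
    lengths: list[int] = []
    try:
        af = pysam.AlignmentFile(str(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {path}: {exc}") from exc
    with af:
        for read in af:
            if not read.is_proper_pair or not read.is_read1:
                continue
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            if read.is_duplicate and not keep_duplicates:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tlen = abs(read.template_length)
            if lo <= tlen <= hi:
                lengths.append(tlen)
    if not lengths:
        raise EmptyFragmentSetError(
            f"no proper pairs retained from {path} "
            f"(filters: MAPQ>={min_mapq}, window=[{lo},{hi}], "
            f"duplicates {'kept' if keep_duplicates else 'removed'})"
        )
    return FragmentSet.from_lengths(lengths, assay="RAW")


def read_lengths_bed(path: str | Path) -> FragmentSet:
    """Read fragment lengths from a BED3+ file (0-based half-open intervals)."""
    lengths: list[int] = []
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot open BED file {path}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedRecordError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise MalformedRecordError(
                    f"{path}:{lineno}: end ({end}) must be greater than start ({start})"
                )
            lengths.append(end - start)
    if not lengths:
        raise EmptyFragmentSetError(f"no intervals found in {path}")
    return FragmentSet.from_lengths(lengths, assay="RAW")


def read_length_table(path: str | Path, assay: str = "RAW") -> FragmentSet:
    """Read a ``length<TAB>count`` TSV (with header) into a FragmentSet."""
    counts: dict[int, int] = {}
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot open length table {path}: {exc}") from exc
    with handle:
        header = handle.readline()
        if not header.startswith("length"):
            raise MalformedRecordError(
                f"{path}:1: expected header starting with 'length'"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                length_s, count_s = line.split("\t")[:2]
                length, count = int(length_s), int(count_s)
            except ValueError as exc:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected 'length<TAB>count' integers"
                ) from exc
            if count < 0:
                raise MalformedRecordError(
                    f"{path}:{lineno}: negative count {count}"
                )
            if length < 1:
                raise MalformedRecordError(
                    f"{path}:{lineno}: length must be >= 1, got {length}"
                )
            if count > 0:
                counts[length] = counts.get(length, 0) + count
    if not counts:
        raise EmptyFragmentSetError(f"no fragments found in {path}")
    return FragmentSet(assay=assay, counts=counts)


def write_length_table(fragment_set: FragmentSet, path: str | Path) -> None:
    """Write a FragmentSet as a ``length<TAB>count`` TSV (LF, UTF-8)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("length\tcount\n")
        for length in sorted(fragment_set.counts):
            handle.write(f"{length}\t{fragment_set.counts[length]}\n")


def build_profile(
    fragment_set: FragmentSet, support: tuple[int, int] = DEFAULT_SUPPORT
) -> SizeProfile:
    """Normalize in-support fragment counts into a SizeProfile.

    freq(L) = count(L) / N where N counts only fragments with
    support[0] <= L <= support[1].
    """
    lo, hi = support
    freqs = np.zeros(hi - lo + 1, dtype=float)
    n = 0
    for length, count in fragment_set.counts.items():
        if lo <= length <= hi:
            freqs[length - lo] += count
            n += count
    if n == 0:
        raise EmptyFragmentSetError(
            f"no fragments within support [{lo}, {hi}] "
            f"(set holds {fragment_set.total} fragments)"
        )
    return SizeProfile(
        assay=fragment_set.assay, support=support, freqs=freqs / n, n_fragments=n
    )


def write_profile(profile: SizeProfile, path: str | Path) -> None:
    """Write a profile as ``length<TAB>count<TAB>frequency`` TSV."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("length\tcount\tfrequency\n")
        for length, f in zip(profile.lengths, profile.freqs):
            count = int(round(f * profile.n_fragments))
            handle.write(f"{length}\t{count}\t{f:.10g}\n")


def read_profile(path: str | Path, assay: str = "RAW") -> SizeProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    lengths: list[int] = []
    freqs: list[float] = []
    n = 0
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("length"):
            raise MalformedRecordError(f"{path}:1: unexpected header")
        for line in handle:
            line = line.strip()
            if not line:
                continue
            length_s, count_s, freq_s = line.split("\t")[:3]
            lengths.append(int(length_s))
            freqs.append(float(freq_s))
            n += int(count_s)
    if not lengths:
        raise EmptyFragmentSetError(f"no rows in profile {path}")
    lo, hi = min(lengths), max(lengths)
    dense = np.zeros(hi - lo + 1)
    for l, f in zip(lengths, freqs):
        dense[l - lo] = f
    dense = dense / dense.sum()
    return SizeProfile(assay=assay, support=(lo, hi), freqs=dense, n_fragments=n)
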