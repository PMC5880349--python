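"""Strand-specific nascent-transcription tracks: I/O, counting and normalization.

PRO-seq maps the active site of engaged RNA polymerase: each sequenced
molecule contributes a single base at the 3' end of the nascent RNA, on the
strand the polymerase transcribes.  All downstream statistics therefore
reduce to sums over per-base integer arrays, one per strand and chromosome.

Coordinate conventions (everywhere in this package):

* 0-based, half-open intervals, BED/bedGraph native.
* The TSS of a minus-strand gene is ``end - 1``.
* Minus-strand bedGraph files store non-negative magnitudes; the strand is
  encoded in the file name, not the sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GeneAnnotation",
    "Interval",
    "StrandTracks",
    "read_track",
    "write_track",
    "count_gene_body",
    "count_window",
    "rpkm",
    "signal_matrix",
    "GENE_BODY_OFFSET",
]

#: Gene-body windows start this many bp downstream of the TSS, skipping the
#: promoter-proximal pause peak so body counts reflect productive elongation.
GENE_BODY_OFFSET = 1000


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with strand; start/end are 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """A plain genomic interval (e.g. a TRE), optionally with GC content."""

    chrom: str
    start: int
    end: int
    id: str = ""
    gc_content: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval {self.id or '?'}: start must be < end")
        if self.gc_content is not None and not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


class ShortGeneWarning(UserWarning):
    """Raised when a gene is too short for the body-counting window."""


@dataclass
class StrandTracks:
    """Per-base 3'-end counts on each strand plus the library depth.

    ``total_mapped`` is carried separately from the stored arrays because a
    library's depth includes reads mapping outside the chromosomes held in
    memory; it is the denominator of RPKM normalization.
    """

    plus: dict[str, np.ndarray] = field(default_factory=dict)
    minus: dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if set(self.plus) != set(self.minus):
            raise ValueError("plus and minus tracks must cover the same chromosomes")
        for chrom in self.plus:
            if self.plus[chrom].shape != self.minus[chrom].shape:
                raise ValueError(f"{chrom}: strand arrays differ in length")
            if (self.plus[chrom] < 0).any() or (self.minus[chrom] < 0).any():
                raise ValueError(f"{chrom}: negative counts")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.plus.items()}

    def strand_array(self, chrom: str, strand: str) -> np.ndarray:
        return (self.plus if strand == "+" else self.minus)[chrom]


def read_track(path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-chromosome dense arrays.

    Values are stored as magnitudes; overlapping records or records beyond a
    chromosome end are errors (the offending line number is reported).
    Chromosomes present in ``chrom_sizes`` but absent from the file come back
    as all-zero arrays.
    """
    arrays = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in arrays:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > len(arrays[chrom]) or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: record {chrom}:{start}-{end} outside "
                    f"chromosome bounds (length {len(arrays[chrom])})"
                )
            if covered[chrom][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph interval")
            covered[chrom][start:end] = True
            arrays[chrom][start:end] = abs(value)
    return arrays


def write_track(arrays: Mapping[str, np.ndarray], path) -> None:
    """Write per-chromosome arrays as run-length-encoded bedGraph.

    Zero runs are omitted; integer values round-trip losslessly through
    :func:`read_track`.
    """
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            a = np.asarray(arrays[chrom])
            if a.size == 0:
                continue
            # run boundaries of constant value
            change = np.flatnonzero(a[1:] != a[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [a.size]))
            for s, e in zip(starts, ends):
                v = a[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v) if float(v).is_integer() else v}\n")


def count_gene_body(tracks: StrandTracks, gene: GeneAnnotation) -> int | None:
    """Sense-strand read count in the gene body window.

    The window runs from ``GENE_BODY_OFFSET`` bp downstream of the TSS to the
    annotation end (half-open, mirrored for minus-strand genes).  Antisense
    reads are never counted.  Genes shorter than the offset cannot host a
    body window; they are excluded with a :class:`ShortGeneWarning` and
    ``None`` is returned.
    """
    if gene.length <= GENE_BODY_OFFSET:
        warnings.warn(
            f"gene {gene.id} ({gene.length} bp) shorter than the "
            f"{GENE_BODY_OFFSET} bp body offset; excluded",
            ShortGeneWarning,
            stacklevel=2,
        )
        return None
    arr = tracks.strand_array(gene.chrom, gene.strand)
    if gene.strand == "+":
        lo, hi = gene.start + GENE_BODY_OFFSET, gene.end
    else:
        lo, hi = gene.start, gene.end - GENE_BODY_OFFSET
    return int(arr[lo:hi].sum())


def count_window(tracks: StrandTracks, interval: Interval) -> int:
    """Both-strand read count over a half-open interval (TRE activity)."""
    p = tracks.plus[interval.chrom][interval.start : interval.end].sum()
    m = tracks.minus[interval.chrom][interval.start : interval.end].sum()
    return int(p + m)


def rpkm(count: int, feature_len: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_len <= 0:
        raise ValueError("feature_len must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / (feature_len / 1e3) / (total_mapped / 1e6)


def signal_matrix(
    tracks: StrandTracks,
    sites: Sequence[Interval],
    flank: int,
    bins: int,
    other: StrandTracks | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned both-strand signal around site centers, one row per site.

    Row *i* holds counts in ``[center - flank, center + flank)`` split into
    ``bins`` equal bins.  When ``other`` is given the returned matrix is the
    difference ``tracks - other`` (e.g. treated minus untreated).  Sites too
    close to a chromosome edge are zero-padded and flagged in the second
    return value.

    Returns
    -------
    matrix : (n_sites, bins) float array
    clipped : (n_sites,) bool array, True where a row needed edge padding
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if bins < 1 or (2 * flank) % bins != 0:
        raise ValueError("bins must be >= 1 and divide 2*flank")
    binw = 2 * flank // bins
    mat = np.zeros((len(sites), bins))
    clipped = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        lo = site.center - flank
        hi = site.center + flank
        chrom_len = len(tracks.plus[site.chrom])
        clo, chi = max(lo, 0), min(hi, chrom_len)
        if clo != lo or chi != hi:
            clipped[i] = True
        window = np.zeros(2 * flank)
        combined = (
            tracks.plus[site.chrom][clo:chi].astype(float)
            + tracks.minus[site.chrom][clo:chi]
        )
        if other is not None:
            combined = combined - (
                other.plus[site.chrom][clo:chi] + other.minus[site.chrom][clo:chi]
            )
        window[clo - lo : chi - lo] = combined
        mat[i] = window.reshape(bins, binw).sum(axis=1)
    return mat, clipped
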