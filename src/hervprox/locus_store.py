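"""Queryable store of HERV-like genomic loci.

Human endogenous retroviruses (HERVs) and related long terminal repeat (LTR)
elements are annotated here as *loci*: genomic intervals carrying a BLAST
E-value and the identifier of the matching reference element.  Loci are
ingested from BLAST tabular output (the genome as BLAST subject) or from
RepeatMasker ``.out`` annotation restricted to the LTR class, normalized to
0-based half-open coordinates, and indexed per chromosome so that
neighborhood queries — "which loci lie within *d* bp of this region, at an
E-value of at most *e*?" — run in logarithmic time while returning exactly
what a linear scan would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from intervaltree import IntervalTree

__all__ = [
    "STRAND_FORWARD",
    "STRAND_REVERSE",
    "STRAND_UNKNOWN",
    "DEFAULT_BUILD_EVALUE",
    "DEFAULT_MAX_DISTANCE",
    "ParseError",
    "GenomicInterval",
    "HervLocus",
    "QueryParams",
    "LocusStore",
    "gap",
    "parse_blast_tabular",
    "parse_repeatmasker_out",
    "read_bed",
    "build_store",
]

STRAND_FORWARD = "+"
STRAND_REVERSE = "-"
STRAND_UNKNOWN = "."

#: E-value ceiling applied when building the store from BLAST hits.
DEFAULT_BUILD_EVALUE = 1e-10
#: Default query distance in bp.
DEFAULT_MAX_DISTANCE = 1000


class ParseError(ValueError):
    """A malformed line in a locus source file.

    Carries the 1-based ``line_number`` of the offending line.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A chromosome-anchored half-open range ``[start, end)`` with strand.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; ``strand`` is
    ``"+"``, ``"-"`` or ``"."`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in (STRAND_FORWARD, STRAND_REVERSE, STRAND_UNKNOWN):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class HervLocus:
    """One stored HERV-like hit: an interval plus its alignment E-value.

    ``source_id`` names the matching reference element (a reference HERV
    sequence for BLAST hits, a repeat name for RepeatMasker rows).  ``score``
    is the optional bit score / Smith-Waterman score.
    """

    interval: GenomicInterval
    evalue: float
    source_id: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0 or math.isnan(self.evalue):
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


@dataclass(frozen=True, slots=True)
class QueryParams:
    """Neighborhood-query predicate.

    ``max_distance`` is the largest allowed gap in bp between nearest edges
    (0 keeps only overlapping/abutting loci).  ``max_evalue`` is an inclusive
    ceiling; the default ``inf`` imposes no similarity restriction.  The
    optional inclusive length bounds restrict the stored locus length in bp;
    ``None`` means no size restriction.
    """

    max_distance: int = DEFAULT_MAX_DISTANCE
    max_evalue: float = math.inf
    min_length: int | None = None
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if self.min_length is not None and self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.max_length < self.min_length
        ):
            raise ValueError("max_length must be >= min_length")

    def matches(self, locus: HervLocus, gap_bp: int) -> bool:
        """Whether ``locus`` at distance ``gap_bp`` satisfies this predicate."""
        if gap_bp > self.max_distance:
            return False
        if locus.evalue > self.max_evalue:
            return False
        n = locus.interval.length
        if self.min_length is not None and n < self.min_length:
            return False
        if self.max_length is not None and n > self.max_length:
            return False
        return True


def gap(region: GenomicInterval, other: GenomicInterval) -> int:
    """Distance in bp between nearest edges; 0 when overlapping or abutting.

    Strand plays no role.  Both intervals must lie on the same chromosome.
    """
    if region.chrom != other.chrom:
        raise ValueError(
            f"gap undefined across chromosomes ({region.chrom} vs {other.chrom})"
        )
    return max(0, other.start - region.end, region.start - other.end)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def parse_blast_tabular(
    stream: Iterable[str], max_evalue: float = DEFAULT_BUILD_EVALUE
) -> list[HervLocus]:
    """Parse BLAST tabular (outfmt 6) hits into loci, keeping evalue <= ceiling.

    The genome is the BLAST *subject*: ``sseqid`` is the chromosome and
    ``sstart``/``send`` are 1-based inclusive subject coordinates, converted
    here to 0-based half-open.  ``sstart > send`` signals a minus-strand hit;
    ``sstart == send`` is a valid 1-bp locus.  Lines starting with ``#`` and
    blank lines are skipped; a line with fewer than 12 fields or non-numeric
    coordinates raises :class:`ParseError` with its line number.
    """
    loci: list[HervLocus] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 12:
            raise ParseError(
                f"expected >= 12 tab-separated fields, got {len(fields)}", lineno
            )
        try:
            sstart = int(fields[8])
            send = int(fields[9])
            evalue = float(fields[10])
            score = float(fields[11])
        except ValueError as exc:
            raise ParseError(f"non-numeric field ({exc})", lineno) from None
        if evalue > max_evalue:
            continue
        strand = STRAND_REVERSE if send < sstart else STRAND_FORWARD
        lo, hi = min(sstart, send), max(sstart, send)
        try:
            interval = GenomicInterval(fields[1], lo - 1, hi, strand)
            loci.append(HervLocus(interval, evalue, fields[0], score))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return loci


def parse_repeatmasker_out(
    stream: Iterable[str], class_filter: str = "LTR"
) -> list[HervLocus]:
    """Parse RepeatMasker ``.out`` rows whose repeat class starts with a prefix.

    Standard layout: two header lines plus a blank line, then whitespace-
    delimited columns (SW score, divergences, query sequence, 1-based
    inclusive begin/end, left, strand ``+``/``C``, repeat name, class/family,
    ...).  RepeatMasker reports no E-value, so retained loci get
    ``evalue = 0.0`` and therefore pass any E-value ceiling.
    """
    loci: list[HervLocus] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        # header lines begin with "SW" / "score"; data lines with the SW score
        try:
            score = float(fields[0])
        except ValueError:
            continue
        if len(fields) < 11:
            raise ParseError(
                f"expected >= 11 whitespace-separated columns, got {len(fields)}",
                lineno,
            )
        rclass = fields[10]
        if not rclass.startswith(class_filter):
            continue
        try:
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ParseError(f"non-numeric coordinate ({exc})", lineno) from None
        strand = STRAND_REVERSE if fields[8] == "C" else STRAND_FORWARD
        try:
            interval = GenomicInterval(fields[4], begin - 1, end, strand)
            loci.append(HervLocus(interval, 0.0, fields[9], score))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return loci


def read_bed(stream: Iterable[str]) -> list[tuple[str, GenomicInterval]]:
    """Read BED3/BED6 regions as ``(name, interval)`` pairs.

    BED is already 0-based half-open, so coordinates are taken as-is.  The
    name defaults to ``chrom:start-end`` when column 4 is absent.
    """
    regions: list[tuple[str, GenomicInterval]] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError("BED line needs >= 3 columns", lineno)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-numeric coordinate ({exc})", lineno) from None
        strand = STRAND_UNKNOWN
        if len(fields) >= 6 and fields[5] in (STRAND_FORWARD, STRAND_REVERSE):
            strand = fields[5]
        name = fields[3] if len(fields) >= 4 else f"{fields[0]}:{start}-{end}"
        try:
            regions.append((name, GenomicInterval(fields[0], start, end, strand)))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return regions


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------


class LocusStore:
    """Per-chromosome interval index over HERV-like loci.

    Any query result is identical (as a set) to a brute-force linear scan of
    all stored loci under the same predicate; the index only accelerates the
    scan.  Duplicate loci are retained as distinct records.
    """

    def __init__(self, loci: Iterable[HervLocus] = (), provenance: Iterable[str] = ()):
        self._loci: list[HervLocus] = list(loci)
        self.provenance: list[str] = list(provenance)
        self._trees: dict[str, IntervalTree] = {}
        for i, locus in enumerate(self._loci):
            tree = self._trees.setdefault(locus.interval.chrom, IntervalTree())
            # payload is the record index so equal duplicate loci survive the
            # set semantics of IntervalTree
            tree.addi(locus.interval.start, locus.interval.end, i)

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[HervLocus]:
        return iter(self._loci)

    @property
    def count(self) -> int:
        return len(self._loci)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def chromosome_counts(self) -> dict[str, int]:
        return {chrom: len(tree) for chrom, tree in sorted(self._trees.items())}

    def query(
        self, region: GenomicInterval, params: QueryParams | None = None
    ) -> list[tuple[HervLocus, int]]:
        """Loci near ``region`` passing ``params``, as ``(locus, gap_bp)`` pairs.

        Results are sorted by ``(gap, locus start, locus end, source_id)``.
        A chromosome absent from the store yields an empty result.
        """
        if params is None:
            params = QueryParams()
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        d = params.max_distance
        hits: list[tuple[HervLocus, int]] = []
        for iv in tree.overlap(region.start - d - 1, region.end + d + 1):
            locus = self._loci[iv.data]
            g = gap(region, locus.interval)
            if params.matches(locus, g):
                hits.append((locus, g))
        hits.sort(
            key=lambda h: (h[1], h[0].interval.start, h[0].interval.end, h[0].source_id)
        )
        return hits

    # -- flat-file serialization -------------------------------------------

    TSV_COLUMNS = ("chrom", "start", "end", "strand", "evalue", "source_id", "score")

    def to_tsv(self, sink: TextIO) -> int:
        """Write one TSV row per locus; returns the number of rows written."""
        sink.write("\t".join(self.TSV_COLUMNS) + "\n")
        for locus in self._loci:
            iv = locus.interval
            score = "." if locus.score is None else repr(locus.score)
            sink.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{locus.evalue!r}\t{locus.source_id}\t{score}\n"
            )
        return len(self._loci)

    @classmethod
    def from_tsv(cls, stream: Iterable[str]) -> "LocusStore":
        loci: list[HervLocus] = []
        for lineno, raw in enumerate(stream, 1):
            line = raw.strip()
            if not line or line.startswith("chrom\t") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"expected >= 6 columns, got {len(fields)}", lineno)
            try:
                interval = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[3]
                )
                score = None if len(fields) < 7 or fields[6] == "." else float(fields[6])
                loci.append(HervLocus(interval, float(fields[4]), fields[5], score))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
        return cls(loci)


def build_store(
    loci: Iterable[HervLocus], provenance: Iterable[str] = ()
) -> LocusStore:
    """Build a :class:`LocusStore` from parsed loci (empty input allowed)."""
    return LocusStore(loci, provenance)
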