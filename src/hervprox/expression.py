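"""Expression matrices and the quantile fold-change filter.

Differential expression between two sample groups is decided by a robust
ratio rule: a probe set counts as up-regulated when its median (50th
percentile) signal in one group is at least ``fold`` times the 75th
percentile of the other group.  Using quantiles on both sides keeps single
outlier samples from dominating the ratio.  No log transform and no
multiple-testing correction are applied — the rule is a plain fold change on
raw intensities.

Probe sets are tied to the genome through a probe-set → coordinate table;
probes absent from the table are reported as unmapped and excluded from all
downstream proximity percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .locus_store import GenomicInterval, STRAND_UNKNOWN

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "FilterParams",
    "ProbeSetMap",
    "quantile_fold_filter",
    "map_probe_sets",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_probe_map_tsv",
    "write_probe_map_tsv",
    "read_design_tsv",
    "write_design_tsv",
]

#: probe_id -> genomic interval; probes absent from the map have no coordinates
ProbeSetMap = dict[str, GenomicInterval]


class ExpressionMatrix:
    """Nonnegative signal intensities, probes as rows and samples as columns."""

    def __init__(self, signal: pd.DataFrame):
        if signal.index.has_duplicates:
            dup = signal.index[signal.index.duplicated()][0]
            raise ValueError(f"duplicate probe identifier {dup!r}")
        if signal.columns.has_duplicates:
            dup = signal.columns[signal.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier {dup!r}")
        values = signal.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("signal values must be numeric")
        if np.isnan(values).any():
            raise ValueError("signal values must not be missing")
        if (values < 0).any():
            raise ValueError("signal values must be >= 0")
        self.signal = signal.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signal.index)

    @property
    def samples(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.signal.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.signal.equals(other.signal)


class GroupDesign:
    """Sample → group labeling with exactly two nonempty groups.

    Group order follows first appearance in the assignment; the first group
    is the "up" direction of :func:`quantile_fold_filter` (probes high in the
    first group relative to the second are *up*).
    """

    def __init__(self, assignment: Mapping[str, str]):
        if not assignment:
            raise ValueError("design must label at least one sample")
        self.assignment = dict(assignment)
        groups: list[str] = []
        for g in self.assignment.values():
            if g not in groups:
                groups.append(g)
        if len(groups) != 2:
            raise ValueError(f"design must have exactly 2 groups, got {len(groups)}")
        self.groups: tuple[str, str] = (groups[0], groups[1])

    @property
    def samples(self) -> list[str]:
        return list(self.assignment)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def swapped(self) -> "GroupDesign":
        """The same labeling with group order reversed."""
        design = GroupDesign(self.assignment)
        design.groups = (self.groups[1], self.groups[0])
        return design


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the quantile fold-change rule.

    ``fold`` is the ratio threshold k (default 10, must exceed 1);
    ``numerator_quantile`` / ``denominator_quantile`` are the quantiles taken
    in the candidate group and the reference group respectively.  Quantiles
    interpolate linearly between order statistics.
    """

    fold: float = 10.0
    numerator_quantile: float = 0.50
    denominator_quantile: float = 0.75

    def __post_init__(self) -> None:
        if not self.fold > 1:
            raise ValueError("fold threshold must be > 1")
        for q in (self.numerator_quantile, self.denominator_quantile):
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"quantile must lie in [0, 1], got {q}")


def quantile_fold_filter(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    params: FilterParams | None = None,
) -> tuple[set[str], set[str]]:
    """Split probes into up- and down-regulated sets by the quantile ratio rule.

    A probe is *up* iff its numerator quantile (default: median) over the
    first group is >= ``fold`` times the denominator quantile (default: 75th
    percentile) over the second group; *down* is the mirror image.  A zero
    denominator passes iff the numerator is positive, so all-zero probes
    never pass.  For ``fold > 1`` the two sets are provably disjoint.
    """
    if params is None:
        params = FilterParams()
    present = set(matrix.samples)
    for sample in design.samples:
        if sample not in present:
            raise ValueError(f"design sample {sample!r} missing from matrix")

    group_a, group_b = design.groups
    a = matrix.signal[design.samples_in(group_a)].to_numpy()
    b = matrix.signal[design.samples_in(group_b)].to_numpy()

    num_a = np.quantile(a, params.numerator_quantile, axis=1)
    num_b = np.quantile(b, params.numerator_quantile, axis=1)
    den_a = np.quantile(a, params.denominator_quantile, axis=1)
    den_b = np.quantile(b, params.denominator_quantile, axis=1)

    up_mask = np.where(den_b > 0, num_a >= params.fold * den_b, num_a > 0)
    down_mask = np.where(den_a > 0, num_b >= params.fold * den_a, num_b > 0)

    probes = matrix.signal.index
    return set(probes[up_mask]), set(probes[down_mask])


def map_probe_sets(
    ids: Sequence[str], probe_map: ProbeSetMap
) -> tuple[list[tuple[str, GenomicInterval]], list[str]]:
    """Partition probe ids into coordinate-bearing regions and unmapped ids.

    Input order is preserved on both sides; every id lands in exactly one of
    the two outputs.  Downstream association percentages use the mapped
    regions as denominator.
    """
    regions: list[tuple[str, GenomicInterval]] = []
    unmapped: list[str] = []
    for pid in ids:
        interval = probe_map.get(pid)
        if interval is None:
            unmapped.append(pid)
        else:
            regions.append((pid, interval))
    return regions, unmapped


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_expression_tsv(stream: TextIO) -> ExpressionMatrix:
    """Load a probe × sample signal matrix from TSV (header = sample names)."""
    frame = pd.read_csv(stream, sep="\t", index_col=0)
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric signal value: {exc}") from None
    return ExpressionMatrix(frame)


def write_expression_tsv(matrix: ExpressionMatrix, sink: TextIO) -> None:
    matrix.signal.to_csv(sink, sep="\t", index_label="probe_id")


def read_probe_map_tsv(stream: TextIO) -> ProbeSetMap:
    """Load a probe-set coordinate table (probe_id, chrom, start, end[, strand])."""
    frame = pd.read_csv(stream, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"probe map missing columns: {sorted(missing)}")
    if frame["probe_id"].duplicated().any():
        dup = frame["probe_id"][frame["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in probe map")
    has_strand = "strand" in frame.columns
    probe_map: ProbeSetMap = {}
    for row in frame.itertuples(index=False):
        strand = getattr(row, "strand", STRAND_UNKNOWN) if has_strand else STRAND_UNKNOWN
        probe_map[row.probe_id] = GenomicInterval(
            row.chrom, int(row.start), int(row.end), strand
        )
    return probe_map


def write_probe_map_tsv(probe_map: ProbeSetMap, sink: TextIO) -> None:
    sink.write("probe_id\tchrom\tstart\tend\tstrand\n")
    for pid, iv in probe_map.items():
        sink.write(f"{pid}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")


def read_design_tsv(stream: TextIO) -> GroupDesign:
    """Load a two-column (sample, group) design table."""
    frame = pd.read_csv(stream, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(frame.columns):
        raise ValueError("design table needs 'sample' and 'group' columns")
    if frame["sample"].duplicated().any():
        dup = frame["sample"][frame["sample"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample {dup!r} in design")
    return GroupDesign(dict(zip(frame["sample"], frame["group"])))


def write_design_tsv(design: GroupDesign, sink: TextIO) -> None:
    sink.write("sample\tgroup\n")
    for sample, group in design.assignment.items():
        sink.write(f"{sample}\t{group}\n")
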