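"""Proximity association statistics between region sets and the locus store.

The central statistic is the *associated fraction*: the proportion of query
regions (typically probe-set footprints) that have at least one HERV-like
locus within the query predicate (distance / E-value / length).  Sweeping
the distance or the E-value ceiling over a grid yields association curves
for an up-regulated and a down-regulated region set together with their
ratio; the distance at which the ratio peaks localizes the enrichment.  A
random sample of probe sets provides the background level of association.

Fractions are monotone non-decreasing along a relaxing sweep, reach 100%
once the distance covers every chromosome bearing a region (given loci on
each such chromosome), and the up/down ratio then reaches its limit of 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .expression import ProbeSetMap
from .locus_store import GenomicInterval, HervLocus, LocusStore, QueryParams

__all__ = [
    "DEFAULT_DISTANCE_GRID",
    "AssociationResult",
    "AssociationCurve",
    "associate",
    "associated_fraction",
    "distance_sweep",
    "evalue_sweep",
    "random_baseline",
]

#: Default distance grid in bp, spanning 1 bp to 10 kb.
DEFAULT_DISTANCE_GRID: tuple[int, ...] = (
    1, 5, 10, 25, 50, 100, 150, 200, 300, 400, 600, 1000, 1600, 2500, 4000, 6300, 10000,
)


@dataclass(frozen=True)
class AssociationResult:
    """Neighborhood of one query region: every passing locus with its gap."""

    region_id: str
    region: GenomicInterval
    hits: tuple[tuple[HervLocus, int], ...]

    @property
    def associated(self) -> bool:
        return len(self.hits) > 0


@dataclass(frozen=True)
class AssociationCurve:
    """Per-grid-point associated fractions of two region sets and their ratio.

    ``ratio[i]`` is ``fraction_up[i] / fraction_down[i]`` and is NaN
    (undefined, never infinity) wherever ``fraction_down[i] == 0``.
    """

    variable: str  # "distance_bp" or "max_evalue"
    grid: tuple[float, ...]
    fraction_up: tuple[float, ...]
    fraction_down: tuple[float, ...]

    @property
    def ratio(self) -> tuple[float, ...]:
        return tuple(
            up / down if down > 0 else math.nan
            for up, down in zip(self.fraction_up, self.fraction_down)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.variable: self.grid,
                "fraction_up": self.fraction_up,
                "fraction_down": self.fraction_down,
                "ratio": self.ratio,
            }
        )

    def write_tsv(self, sink: TextIO) -> int:
        """Write the curve as TSV; undefined ratios become ``.``; returns row count."""
        frame = self.to_frame()
        frame["ratio"] = [
            "." if math.isnan(r) else repr(r) for r in self.ratio
        ]
        frame.to_csv(sink, sep="\t", index=False)
        return len(frame)

    def peak_ratio_at(self) -> float:
        """Grid value where the ratio is largest (NaN points ignored)."""
        best, best_x = -math.inf, math.nan
        for x, r in zip(self.grid, self.ratio):
            if not math.isnan(r) and r > best:
                best, best_x = r, x
        return best_x


def associate(
    regions: Iterable[tuple[str, GenomicInterval]],
    store: LocusStore,
    params: QueryParams | None = None,
) -> list[AssociationResult]:
    """Query the store for every (id, region) pair."""
    if params is None:
        params = QueryParams()
    return [
        AssociationResult(rid, region, tuple(store.query(region, params)))
        for rid, region in regions
    ]


def associated_fraction(
    regions: Sequence[GenomicInterval],
    store: LocusStore,
    params: QueryParams | None = None,
) -> float:
    """Proportion of regions with at least one locus passing the predicate."""
    if len(regions) == 0:
        raise ValueError("associated_fraction needs at least one region")
    if params is None:
        params = QueryParams()
    hit = sum(1 for region in regions if store.query(region, params))
    return hit / len(regions)


def _validate_grid(grid: Sequence[float]) -> None:
    if len(grid) == 0:
        raise ValueError("sweep grid must be nonempty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("sweep grid must be strictly increasing")


def distance_sweep(
    up: Sequence[GenomicInterval],
    down: Sequence[GenomicInterval],
    store: LocusStore,
    distances: Sequence[int] = DEFAULT_DISTANCE_GRID,
    base_params: QueryParams | None = None,
) -> AssociationCurve:
    """Associated fractions of both sets over an increasing distance grid.

    The E-value and length filters of ``base_params`` apply at every point;
    only ``max_distance`` varies.
    """
    _validate_grid(distances)
    if base_params is None:
        base_params = QueryParams()
    f_up, f_down = [], []
    for d in distances:
        params = replace(base_params, max_distance=int(d))
        f_up.append(associated_fraction(up, store, params))
        f_down.append(associated_fraction(down, store, params))
    return AssociationCurve(
        "distance_bp", tuple(float(d) for d in distances), tuple(f_up), tuple(f_down)
    )


def evalue_sweep(
    up: Sequence[GenomicInterval],
    down: Sequence[GenomicInterval],
    store: LocusStore,
    evalues: Sequence[float],
    base_params: QueryParams | None = None,
) -> AssociationCurve:
    """Associated fractions of both sets over increasing E-value ceilings."""
    _validate_grid(evalues)
    if base_params is None:
        base_params = QueryParams()
    f_up, f_down = [], []
    for e in evalues:
        params = replace(base_params, max_evalue=float(e))
        f_up.append(associated_fraction(up, store, params))
        f_down.append(associated_fraction(down, store, params))
    return AssociationCurve(
        "max_evalue", tuple(float(e) for e in evalues), tuple(f_up), tuple(f_down)
    )


def random_baseline(
    probe_map: ProbeSetMap,
    n: int,
    seed: int,
    store: LocusStore,
    params: QueryParams | None = None,
) -> tuple[list[str], float]:
    """Associated fraction of ``n`` probe sets sampled without replacement.

    Sampling is over the coordinate-bearing probe sets of ``probe_map`` and
    is reproducible under ``seed``.  This is the background against which
    enrichment of a differentially-expressed set is judged.
    """
    population = sorted(probe_map)
    if n > len(population):
        raise ValueError(
            f"sample size {n} exceeds mapped population {len(population)}"
        )
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [population[i] for i in rng.choice(len(population), size=n, replace=False)]
    fraction = associated_fraction([probe_map[i] for i in ids], store, params)
    return ids, fraction
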