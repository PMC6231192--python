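"""Synthetic genomes, locus stores, probe sets and expression matrices.

Every pipeline stage is testable without reference-genome or micro-array
downloads: this module plants the structure the analysis is meant to
recover.  A synthetic genome gets HERV-like loci placed uniformly (with a
log-uniform length distribution and log-uniform E-value exponents); two
probe-set populations are placed so that a chosen fraction of each sits at
a controlled gap around an enrichment offset D from a locus; and an
expression matrix gives one population a multiplicative effect in the first
sample group and the other population the mirror effect, so the quantile
fold-change filter reconstructs the two populations and the distance sweep
should peak near D.

Truth tables (which loci exist, which probes were proximity-planted) are
returned alongside, so tests can score recovery by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import (
    ExpressionMatrix,
    GroupDesign,
    ProbeSetMap,
    write_design_tsv,
    write_expression_tsv,
    write_probe_map_tsv,
)
from .locus_store import (
    STRAND_FORWARD,
    STRAND_REVERSE,
    GenomicInterval,
    HervLocus,
    LocusStore,
)

__all__ = ["SimParams", "SimDataset", "gen_store", "gen_probes", "gen_expression",
           "simulate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Defaults describe a small but structurally realistic study: a 4.5 Mb
    genome in three chromosomes; 250 loci with lengths log-uniform on
    300–7,000 bp (solo LTRs up to near-complete proviruses) and E-value
    exponents uniform on [-200, -10] (the range the store and query ceilings
    operate in); 2,000 probe sets per region set with a 120 bp footprint;
    half of the "up" population planted at a gap of about 200 bp from a
    locus versus 5% of the "down" population; a 50-fold expression effect
    over log-normal noise; and 5 vs 11 samples, echoing a small case group
    against a larger panel of normal controls.
    """

    chrom_lengths: tuple[int, ...] = (2_000_000, 1_500_000, 1_000_000)
    locus_count: int = 250
    loci_per_chrom: int | None = None  # exact per-chromosome allocation if set
    locus_length_range: tuple[int, int] = (300, 7_000)  # bp, log-uniform
    evalue_exponent_range: tuple[float, float] = (-200.0, -10.0)  # 10**U(lo, hi)
    probe_count: int = 2_000  # per region set
    enriched_fraction: float = 0.5  # π of the "up" set
    down_enriched_fraction: float = 0.05  # π of the "down" set
    enrichment_offset: int = 200  # D, bp
    probe_length: int = 120  # bp
    effect_size: float = 50.0  # multiplicative, must be > 1
    noise_sigma: float = 0.4  # sd of log-normal noise on log scale
    baseline_log_mean: float = 5.0  # mean log intensity of probes
    samples_per_group: tuple[int, int] = (5, 11)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) < 1 or any(l < 1 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.locus_count < 1 or self.probe_count < 1:
            raise ValueError("counts must be >= 1")
        if self.loci_per_chrom is not None and self.loci_per_chrom < 1:
            raise ValueError("loci_per_chrom must be >= 1")
        lo, hi = self.locus_length_range
        if not 1 <= lo <= hi:
            raise ValueError("locus length bounds must satisfy 1 <= lo <= hi")
        if hi > min(self.chrom_lengths):
            raise ValueError("locus length may exceed the shortest chromosome")
        for pi in (self.enriched_fraction, self.down_enriched_fraction):
            if not 0.0 <= pi <= 1.0:
                raise ValueError("enriched fraction must lie in [0, 1]")
        if self.enrichment_offset < 0:
            raise ValueError("enrichment offset must be >= 0")
        if self.probe_length < 1 or self.probe_length > min(self.chrom_lengths):
            raise ValueError("probe length must fit in every chromosome")
        if not self.effect_size > 1:
            raise ValueError("effect size must be > 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if any(n < 1 for n in self.samples_per_group):
            raise ValueError("each group needs >= 1 sample")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))


def _rng(params: SimParams, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(params.seed)


def gen_store(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[LocusStore, pd.DataFrame]:
    """Place loci uniformly on the synthetic genome; every chromosome gets >= 1.

    Returns the store and a truth table (one row per locus).  With
    ``loci_per_chrom`` set, each chromosome receives exactly that many loci;
    otherwise one locus seeds each chromosome and the rest are assigned with
    probability proportional to chromosome length.
    """
    rng = _rng(params, rng)
    names = params.chrom_names
    lengths = np.asarray(params.chrom_lengths, dtype=float)

    if params.loci_per_chrom is not None:
        chrom_idx = np.repeat(np.arange(len(names)), params.loci_per_chrom)
    else:
        n_extra = max(0, params.locus_count - len(names))
        seeds = np.arange(len(names))[: params.locus_count]
        extra = rng.choice(len(names), size=n_extra, p=lengths / lengths.sum())
        chrom_idx = np.concatenate([seeds, extra])

    lo, hi = params.locus_length_range
    log_len = rng.uniform(np.log(lo), np.log(hi + 1), size=len(chrom_idx))
    locus_len = np.minimum(np.exp(log_len).astype(int), hi)
    locus_len = np.maximum(locus_len, lo)
    e_lo, e_hi = params.evalue_exponent_range
    evalues = 10.0 ** rng.uniform(e_lo, e_hi, size=len(chrom_idx))

    loci: list[HervLocus] = []
    rows = []
    for i, (ci, n, ev) in enumerate(zip(chrom_idx, locus_len, evalues)):
        chrom, clen = names[ci], params.chrom_lengths[ci]
        start = int(rng.integers(0, clen - int(n) + 1))
        strand = STRAND_FORWARD if rng.random() < 0.5 else STRAND_REVERSE
        locus = HervLocus(
            GenomicInterval(chrom, start, start + int(n), strand),
            float(ev),
            f"SIMHERV{i:05d}",
        )
        loci.append(locus)
        rows.append(
            (locus.source_id, chrom, start, start + int(n), strand, float(ev))
        )
    truth = pd.DataFrame(
        rows, columns=["source_id", "chrom", "start", "end", "strand", "evalue"]
    )
    return LocusStore(loci, provenance=["synthetic"]), truth


def gen_probes(
    params: SimParams,
    store: LocusStore,
    rng: np.random.Generator | None = None,
    prefix: str = "PS",
) -> tuple[ProbeSetMap, set[str]]:
    """Place probe-set footprints; a fraction π is planted near loci.

    Planted probes sit at a gap drawn uniformly on [D/2, 3D/2] from a
    randomly chosen locus (left or right side); D = 0 degenerates to an
    abutting placement with gap 0.  The remainder are uniform over the
    genome.  Returns the coordinate map and the planted-id truth set.
    """
    rng = _rng(params, rng)
    if store.count == 0:
        raise ValueError("gen_probes needs a nonempty store")
    loci = list(store)
    lengths = np.asarray(params.chrom_lengths, dtype=float)
    chrom_len = dict(zip(params.chrom_names, params.chrom_lengths))
    n_planted = int(round(params.enriched_fraction * params.probe_count))
    d = params.enrichment_offset
    g_lo, g_hi = d - d // 2, d + d // 2
    plen = params.probe_length

    probe_map: ProbeSetMap = {}
    planted: set[str] = set()
    for i in range(params.probe_count):
        pid = f"{prefix}{i:06d}"
        if i < n_planted:
            start = None
            for _ in range(200):  # rejection-sample until the probe fits
                locus = loci[int(rng.integers(len(loci)))]
                g = int(rng.integers(g_lo, g_hi + 1))
                clen = chrom_len[locus.interval.chrom]
                if rng.random() < 0.5:
                    cand = locus.interval.start - g - plen
                else:
                    cand = locus.interval.end + g
                if 0 <= cand and cand + plen <= clen:
                    start, chrom = cand, locus.interval.chrom
                    break
            if start is None:
                raise RuntimeError("could not place planted probe; genome too small")
            planted.add(pid)
        else:
            ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
            chrom = params.chrom_names[ci]
            start = int(rng.integers(0, params.chrom_lengths[ci] - plen + 1))
        probe_map[pid] = GenomicInterval(chrom, start, start + plen)
    return probe_map, planted


def gen_expression(
    params: SimParams,
    planted_up: set[str],
    all_ids: Sequence[str],
    rng: np.random.Generator | None = None,
    planted_down: set[str] = frozenset(),
) -> tuple[ExpressionMatrix, GroupDesign]:
    """Log-normal intensities with a multiplicative group effect on planted probes.

    Each probe gets a log-normal baseline; ``planted_up`` probes are
    multiplied by the effect size in the first group only, ``planted_down``
    probes in the second group only.  Signals are strictly positive.
    """
    rng = _rng(params, rng)
    unknown = (set(planted_up) | set(planted_down)) - set(all_ids)
    if unknown:
        raise ValueError(f"planted ids not in all_ids: {sorted(unknown)[:3]}")
    n_a, n_b = params.samples_per_group
    samples = [f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)]
    n_probes = len(all_ids)

    baseline = np.exp(rng.normal(params.baseline_log_mean, 1.0, size=n_probes))
    noise = np.exp(rng.normal(0.0, params.noise_sigma, size=(n_probes, n_a + n_b)))
    signal = baseline[:, None] * noise

    up_rows = np.fromiter((pid in planted_up for pid in all_ids), bool, n_probes)
    down_rows = np.fromiter((pid in planted_down for pid in all_ids), bool, n_probes)
    signal[up_rows, :n_a] *= params.effect_size
    signal[down_rows, n_a:] *= params.effect_size

    frame = pd.DataFrame(signal, index=list(all_ids), columns=samples)
    design = GroupDesign({s: ("A" if s.startswith("A") else "B") for s in samples})
    return ExpressionMatrix(frame), design


@dataclass(frozen=True)
class SimDataset:
    """A complete synthetic study with its ground truth."""

    params: SimParams
    store: LocusStore
    loci_truth: pd.DataFrame
    probe_map: ProbeSetMap  # up + down populations combined
    up_ids: tuple[str, ...]  # expression-up population ("PSU…")
    down_ids: tuple[str, ...]  # expression-down population ("PSD…")
    proximity_planted_up: frozenset[str]
    proximity_planted_down: frozenset[str]
    matrix: ExpressionMatrix
    design: GroupDesign


def simulate_dataset(params: SimParams, seed: int | None = None) -> SimDataset:
    """Generate a full study: store, two probe populations, expression, design.

    The "up" population is proximity-planted at rate ``enriched_fraction``
    and up-regulated in group A; the "down" population at rate
    ``down_enriched_fraction`` and up-regulated in group B.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    store, loci_truth = gen_store(params, rng)
    up_map, planted_up = gen_probes(params, store, rng, prefix="PSU")
    down_params = replace(params, enriched_fraction=params.down_enriched_fraction)
    down_map, planted_down = gen_probes(down_params, store, rng, prefix="PSD")
    probe_map = {**up_map, **down_map}
    all_ids = list(up_map) + list(down_map)
    matrix, design = gen_expression(
        params, set(up_map), all_ids, rng, planted_down=set(down_map)
    )
    return SimDataset(
        params=params,
        store=store,
        loci_truth=loci_truth,
        probe_map=probe_map,
        up_ids=tuple(up_map),
        down_ids=tuple(down_map),
        proximity_planted_up=frozenset(planted_up),
        proximity_planted_down=frozenset(planted_down),
        matrix=matrix,
        design=design,
    )


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the formats the pipeline reads, plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "store": outdir / "store.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "probes_bed": outdir / "probes.bed",
        "truth_loci": outdir / "truth_loci.tsv",
        "truth_probes": outdir / "truth_probes.tsv",
    }
    with open(paths["store"], "w") as fh:
        dataset.store.to_tsv(fh)
    with open(paths["probe_map"], "w") as fh:
        write_probe_map_tsv(dataset.probe_map, fh)
    with open(paths["expression"], "w") as fh:
        write_expression_tsv(dataset.matrix, fh)
    with open(paths["design"], "w") as fh:
        write_design_tsv(dataset.design, fh)
    with open(paths["probes_bed"], "w") as fh:
        for pid, iv in dataset.probe_map.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pid}\n")
    dataset.loci_truth.to_csv(paths["truth_loci"], sep="\t", index=False)
    planted = dataset.proximity_planted_up | dataset.proximity_planted_down
    with open(paths["truth_probes"], "w") as fh:
        fh.write("probe_id\tpopulation\tproximity_planted\n")
        for pid in dataset.probe_map:
            pop = "up" if pid in set(dataset.up_ids) else "down"
            fh.write(f"{pid}\t{pop}\t{int(pid in planted)}\n")
    return paths
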