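"""Genome-architecture statistics and Spearman correlation support.

Conventions: N50 is the length of the shortest sequence in the smallest
prefix of the descending-sorted lengths whose cumulative sum reaches half
the assembly; GC% is computed per sequence over unambiguous bases (N
excluded from the denominator) and averaged unweighted across sequences;
intergenic distance is the count of bases strictly between two adjacent
non-overlapping gene spans, with genes overlapping any other gene (either
strand) excluded first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import AnnotationSet, GenomeSequence
from .errors import UndefinedResultError


@dataclass
class GenomeStats:
    n_sequences: int
    total_length: int
    min_length: int
    mean_length: float
    max_length: int
    q1_length: float
    q2_length: float
    q3_length: float
    n50: int
    mean_gc: float = float("nan")
    mean_intergenic: float = float("nan")
    median_intergenic: float = float("nan")
    prop_overlapping_genes: float = float("nan")


def n50(lengths: list[int]) -> int:
    """Shortest sequence in the smallest descending-sorted prefix whose sum
    reaches half the total length."""
    if not lengths:
        raise UndefinedResultError("N50 of an empty genome")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_stats(genome: list[GenomeSequence] | dict[str, GenomeSequence]) -> GenomeStats:
    if isinstance(genome, dict):
        genome = list(genome.values())
    if not genome:
        raise UndefinedResultError("assembly statistics of an empty genome")
    lengths = np.array([g.length for g in genome])
    q1, q2, q3 = np.percentile(lengths, [25, 50, 75])
    return GenomeStats(
        n_sequences=len(lengths),
        total_length=int(lengths.sum()),
        min_length=int(lengths.min()),
        mean_length=float(lengths.mean()),
        max_length=int(lengths.max()),
        q1_length=float(q1),
        q2_length=float(q2),
        q3_length=float(q3),
        n50=n50([int(x) for x in lengths]),
    )


def gc_percent(seq: str) -> float:
    """GC% of one sequence over unambiguous (ACGT) bases."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise UndefinedResultError("GC% of a sequence with no unambiguous bases")
    return 100.0 * gc / acgt


def mean_gc(
    genome: list[GenomeSequence] | dict[str, GenomeSequence], pooled: bool = False
) -> float:
    """Unweighted mean of per-sequence GC% (default), or pooled GC% over all
    bases with ``pooled=True``. Sequences with no unambiguous bases are
    excluded."""
    if isinstance(genome, dict):
        genome = list(genome.values())
    if pooled:
        return gc_percent("".join(g.residues for g in genome))
    values = []
    for g in genome:
        try:
            values.append(gc_percent(g.residues))
        except UndefinedResultError:
            continue
    if not values:
        raise UndefinedResultError("no sequence had unambiguous bases")
    return float(np.mean(values))


def intergenic_distances(
    annotations: AnnotationSet,
) -> tuple[list[int], float]:
    """Distances between adjacent non-overlapping gene spans per sequence.

    Genes whose span overlaps any other gene's span (any strand, ≥ 1 base)
    are excluded before adjacency is formed. Returns the distance list and
    the proportion of genes excluded.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for g in annotations:
        by_seq.setdefault(g.seq_id, []).append((g.start, g.end))
    n_total = sum(len(v) for v in by_seq.values())
    if n_total == 0:
        return [], 0.0
    distances: list[int] = []
    n_excluded = 0
    for spans in by_seq.values():
        spans.sort()
        overlapping = [False] * len(spans)
        max_end = -1
        for i, (s, e) in enumerate(spans):
            if s < max_end:
                overlapping[i] = True
                # mark every earlier gene still covering s
                for j in range(i - 1, -1, -1):
                    if spans[j][1] > s:
                        overlapping[j] = True
            max_end = max(max_end, e)
        kept = [spans[i] for i in range(len(spans)) if not overlapping[i]]
        n_excluded += sum(overlapping)
        for (s1, e1), (s2, e2) in zip(kept, kept[1:]):
            distances.append(s2 - e1)
    return distances, n_excluded / n_total


def spearman(x, y) -> float:
    """Spearman rank correlation (midrank ties), via Pearson on ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman expects two equal-length 1-D vectors")
    if len(x) < 3:
        raise UndefinedResultError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("spearman undefined for a constant vector")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def correlation_matrix(stats: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman coefficients over the numeric columns of a
    per-genome statistics table (rows = genomes)."""
    numeric = stats.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise UndefinedResultError("correlation matrix requires >= 3 genomes")
    cols = list(numeric.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                rho = spearman(numeric[a].to_numpy(), numeric[b].to_numpy())
                mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat


def genome_report(
    genome: dict[str, GenomeSequence], annotations: AnnotationSet | None = None
) -> GenomeStats:
    """Assembly stats plus GC and gene-spacing metrics in one record."""
    gs = assembly_stats(genome)
    gs.mean_gc = mean_gc(genome)
    if annotations is not None and len(annotations):
        dists, prop = intergenic_distances(annotations)
        gs.prop_overlapping_genes = prop
        if dists:
            gs.mean_intergenic = float(np.mean(dists))
            gs.median_intergenic = float(np.median(dists))
    return gs


def write_stats_tsv(stats: GenomeStats, path: str | Path, genome_id: str = "genome") -> None:
    fields = [
        "genome_id", "n_sequences", "total_length", "min_length", "mean_length",
        "max_length", "q1_length", "q2_length", "q3_length", "n50", "mean_gc",
        "mean_intergenic", "median_intergenic", "prop_overlapping_genes",
    ]
    values = [
        genome_id, stats.n_sequences, stats.total_length, stats.min_length,
        f"{stats.mean_length:.2f}", stats.max_length, f"{stats.q1_length:.1f}",
        f"{stats.q2_length:.1f}", f"{stats.q3_length:.1f}", stats.n50,
        f"{stats.mean_gc:.4f}", f"{stats.mean_intergenic:.2f}",
        f"{stats.median_intergenic:.1f}", f"{stats.prop_overlapping_genes:.4f}",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        fh.write("\t".join(str(v) for v in values) + "\n")
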