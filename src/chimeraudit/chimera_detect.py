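"""The chimera filter cascade.

A reference gene is a chimera candidate when

1. the median query coverage of its database hits is < 60% while the
   pooled median query coverage of its linked alternate genes' hits is
   > 70% (a two-part chimera aligned to either component shows ~50%
   coverage, with a 10% buffer for size variation; split alternate models
   align near-fully);
2. the alternate genes' hit targets are a subset of the reference gene's
   hit targets (differences reflect splitting, not unrelated predictions);
3. the hit coordinates along the reference protein, shrunk by 10% to
   suppress noise from overlapping alignments, form ≥ 2 distinct clusters
   whose original (unshrunk) union covers > 50% of the protein.

All threshold comparisons are strict, as stated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyranges as pr

from .annotation_io import AnnotationSet
from .errors import ConsistencyError
from .homology import Hit, HitTable, median_query_coverage, pooled_median_query_coverage
from .linking import GeneLink

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Tunable thresholds of the cascade (defaults are the published ones)."""

    ref_median_cov_max: float = 0.60   # filter 1, strict <
    alt_median_cov_min: float = 0.70   # filter 1, strict >
    shrink_fraction: float = 0.10      # total; split evenly per end
    min_clusters: int = 2              # filter 3
    min_total_query_cov: float = 0.50  # filter 3, strict >
    max_e_value: float = 1e-5          # applied when loading hit tables

    def __post_init__(self):
        for name in ("ref_median_cov_max", "alt_median_cov_min",
                     "shrink_fraction", "min_total_query_cov"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_clusters < 1:
            raise ValueError("min_clusters must be >= 1")


@dataclass(frozen=True)
class QueryInterval:
    """A 1-based inclusive residue interval on the reference protein."""

    start: int
    end: int
    source_hit: Hit | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Cluster:
    """A maximal chain of pairwise-overlapping query intervals."""

    intervals: list[QueryInterval]
    span: tuple[int, int]  # merged [start, end], 1-based inclusive


@dataclass
class ChimeraCall:
    """The verdict for one assessed reference gene."""

    ref_gene_id: str
    seq_id: str = ""
    strand: str = ""
    n_ref_hits: int = 0
    ref_median_cov: float | None = None
    linked_alt_gene_ids: list[str] = field(default_factory=list)
    alt_pooled_median_cov: float | None = None
    subset_ok: bool = False
    cluster_count: int = 0
    total_query_cov: float = 0.0
    verdict: str = "rejected"        # candidate | rejected
    failed_filter: str = "none"      # none | coverage | subset | clustering


def coverage_filter(
    ref_hits: list[Hit], alt_hits_pooled: list[Hit], cfg: FilterConfig
) -> tuple[bool, float | None, float | None]:
    """Filter 1: ref median q_cov < threshold AND pooled alt median q_cov
    > threshold, both strict. Returns (passed, ref_median, alt_median)."""
    if not ref_hits:
        return False, None, None
    ref_med = median_query_coverage(ref_hits)
    if not alt_hits_pooled:
        return False, ref_med, None
    alt_med = pooled_median_query_coverage([alt_hits_pooled])
    passed = ref_med < cfg.ref_median_cov_max and alt_med > cfg.alt_median_cov_min
    return passed, ref_med, alt_med


def subset_filter(ref_hits: list[Hit], alt_hits_pooled: list[Hit]) -> bool:
    """Filter 2: alternate hit targets ⊆ reference hit targets. An empty
    alternate target set fails (the vacuous subset is rejected)."""
    alt_targets = {h.target_id for h in alt_hits_pooled}
    if not alt_targets:
        return False
    ref_targets = {h.target_id for h in ref_hits}
    return alt_targets <= ref_targets


def shrink_interval(iv: QueryInterval, shrink_fraction: float) -> QueryInterval:
    """Remove floor(L × shrink/2) residues from each end; an interval that
    would vanish collapses to its midpoint residue."""
    trim = int(iv.length * shrink_fraction / 2)
    start, end = iv.start + trim, iv.end - trim
    if start > end:
        mid = (iv.start + iv.end) // 2
        return QueryInterval(mid, mid, iv.source_hit)
    return QueryInterval(start, end, iv.source_hit)


def cluster_intervals(ivs: list[QueryInterval]) -> list[Cluster]:
    """Single-linkage clustering of intervals: two intervals share a cluster
    iff connected by a chain of pairwise overlaps (≥ 1 shared residue,
    closed coordinates — abutting intervals do not merge). Clustering is
    delegated to pyranges on half-open coordinates with slack −1, which is
    exactly the closed-coordinate overlap rule. Output sorted by merged-span
    start."""
    if not ivs:
        return []
    df = pd.DataFrame(
        {
            "Chromosome": "q",
            "Start": [iv.start - 1 for iv in ivs],  # to 0-based half-open
            "End": [iv.end for iv in ivs],
            "idx": range(len(ivs)),
        }
    )
    clustered = pr.PyRanges(df).cluster(slack=-1).df
    out: list[Cluster] = []
    for _, grp in clustered.groupby("Cluster"):
        members = [ivs[i] for i in sorted(grp["idx"])]
        span = (int(grp["Start"].min()) + 1, int(grp["End"].max()))
        out.append(Cluster(intervals=members, span=span))
    out.sort(key=lambda c: c.span)
    return out


def _union_length(ivs: list[QueryInterval]) -> int:
    """Total residues covered by the union of closed intervals."""
    if not ivs:
        return 0
    spans = sorted((iv.start, iv.end) for iv in ivs)
    total = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e + 1:  # overlapping or abutting both extend coverage
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def clustering_filter(
    ref_hits: list[Hit], ref_protein_len: int, cfg: FilterConfig
) -> tuple[bool, int, float]:
    """Filter 3: ≥ min_clusters clusters of shrunk hit intervals AND
    union of original intervals covering > min_total_query_cov of the
    protein (strict). Returns (passed, cluster_count, total_query_cov)."""
    ivs = [QueryInterval(h.q_start, h.q_end, h) for h in ref_hits]
    shrunk = [shrink_interval(iv, cfg.shrink_fraction) for iv in ivs]
    clusters = cluster_intervals(shrunk)
    total_cov = _union_length(ivs) / ref_protein_len if ref_protein_len else 0.0
    passed = len(clusters) >= cfg.min_clusters and total_cov > cfg.min_total_query_cov
    return passed, len(clusters), total_cov


def scan(
    ref: AnnotationSet,
    alt: AnnotationSet,
    ref_hits: HitTable,
    alt_hits: HitTable,
    links: list[GeneLink],
    cfg: FilterConfig | None = None,
) -> list[ChimeraCall]:
    """Run the full cascade over every reference gene that has hits.

    All three filters are evaluated for every assessed gene (the candidate
    set is therefore independent of evaluation order); ``failed_filter``
    reports the first failure in the canonical order
    coverage → subset → clustering. Reference genes without hits are
    skipped and counted in the log.
    """
    cfg = cfg or FilterConfig()
    for qid in ref_hits.query_ids:
        if qid not in ref:
            raise ConsistencyError(
                f"hit query {qid!r} absent from the reference annotation"
            )
    for qid in alt_hits.query_ids:
        if qid not in alt:
            raise ConsistencyError(
                f"hit query {qid!r} absent from the alternate annotation"
            )
    links_by_ref = {l.ref_gene_id: l for l in links}

    calls: list[ChimeraCall] = []
    n_skipped = 0
    for gene in ref:
        g_hits = ref_hits.by_query(gene.gene_id)
        if not g_hits:
            n_skipped += 1
            continue
        link = links_by_ref.get(gene.gene_id)
        alt_ids = link.alt_gene_ids if link else []
        pooled = [h for gid in alt_ids for h in alt_hits.by_query(gid)]

        cov_ok, ref_med, alt_med = coverage_filter(g_hits, pooled, cfg)
        sub_ok = subset_filter(g_hits, pooled)
        protein_len = g_hits[0].q_len
        clu_ok, n_clusters, total_cov = clustering_filter(g_hits, protein_len, cfg)

        if cov_ok and sub_ok and clu_ok:
            verdict, failed = "candidate", "none"
        elif not cov_ok:
            verdict, failed = "rejected", "coverage"
        elif not sub_ok:
            verdict, failed = "rejected", "subset"
        else:
            verdict, failed = "rejected", "clustering"

        calls.append(
            ChimeraCall(
                ref_gene_id=gene.gene_id,
                seq_id=gene.seq_id,
                strand=gene.strand,
                n_ref_hits=len(g_hits),
                ref_median_cov=ref_med,
                linked_alt_gene_ids=alt_ids,
                alt_pooled_median_cov=alt_med,
                subset_ok=sub_ok,
                cluster_count=n_clusters,
                total_query_cov=total_cov,
                verdict=verdict,
                failed_filter=failed,
            )
        )
    if n_skipped:
        logger.info("%d reference genes had no hits and were not assessed", n_skipped)
    return calls


_TSV_COLUMNS = [
    "ref_gene_id", "seq_id", "strand", "n_ref_hits", "ref_median_cov",
    "linked_alt_genes", "alt_pooled_median_cov", "subset_ok",
    "cluster_count", "total_query_cov", "verdict", "failed_filter",
]


def write_calls_tsv(calls: list[ChimeraCall], path: str | Path) -> None:
    """One row per assessed reference gene; coverages to 4 decimals."""
    def fnum(x):
        return "NA" if x is None else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.ref_gene_id, c.seq_id, c.strand, str(c.n_ref_hits),
                        fnum(c.ref_median_cov),
                        ",".join(c.linked_alt_gene_ids),
                        fnum(c.alt_pooled_median_cov),
                        str(c.subset_ok).lower(),
                        str(c.cluster_count),
                        f"{c.total_query_cov:.4f}",
                        c.verdict, c.failed_filter,
                    ]
                )
                + "\n"
            )
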