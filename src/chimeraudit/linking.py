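"""Link reference genes to overlapping alternate-annotation genes.

Linking uses CDS-footprint overlap (union of CDS intervals) on the same
strand with a ≥ 1 base threshold. No minimum overlap fraction is applied:
a chimera component may overlap an alternate model only partially.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_io import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass
class GeneLink:
    """One reference gene and the alternate genes sharing CDS bases with it,
    sorted by alternate gene start coordinate."""

    ref_gene_id: str
    alt_gene_ids: list[str] = field(default_factory=list)
    overlap_bases: dict[str, int] = field(default_factory=dict)


def _overlap_bases(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Shared bases between two sorted, merged interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def link_annotations(ref: AnnotationSet, alt: AnnotationSet) -> list[GeneLink]:
    """One GeneLink per reference gene with ≥ 1 same-strand CDS-overlapping
    alternate gene; unlinked reference genes are omitted and counted."""
    # bucket alternate genes by (seq, strand) with precomputed footprints
    alt_by_key: dict[tuple[str, str], list] = {}
    for g in alt:
        fp = g.cds_footprint()
        if fp:
            alt_by_key.setdefault((g.seq_id, g.strand), []).append((g, fp))

    links: list[GeneLink] = []
    n_unlinked = 0
    for rg in ref:
        rf = rg.cds_footprint()
        if not rf:
            n_unlinked += 1
            continue
        matches = []
        for ag, af in alt_by_key.get((rg.seq_id, rg.strand), []):
            # quick span rejection before interval sweep
            if af[-1][1] <= rf[0][0] or af[0][0] >= rf[-1][1]:
                continue
            ob = _overlap_bases(rf, af)
            if ob >= 1:
                matches.append((ag.start, ag.gene_id, ob))
        if not matches:
            n_unlinked += 1
            continue
        matches.sort()
        links.append(
            GeneLink(
                ref_gene_id=rg.gene_id,
                alt_gene_ids=[gid for _, gid, _ in matches],
                overlap_bases={gid: ob for _, gid, ob in matches},
            )
        )
    if n_unlinked:
        logger.info("%d reference genes had no alternate-annotation link", n_unlinked)
    return links


def read_links_tsv(path: str | Path) -> list[GeneLink]:
    """Import an externally produced linking table (ref_gene_id, alt_gene_id
    per row; a header row is skipped if present)."""
    grouped: dict[str, list[str]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "ref_gene_id":
                continue
            grouped.setdefault(row[0], []).append(row[1])
    return [GeneLink(ref_gene_id=k, alt_gene_ids=v) for k, v in grouped.items()]


def write_links_tsv(links: list[GeneLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_gene_id\talt_gene_id\toverlap_bases\n")
        for link in links:
            for gid in link.alt_gene_ids:
                fh.write(f"{link.ref_gene_id}\t{gid}\t{link.overlap_bases.get(gid, '')}\n")
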