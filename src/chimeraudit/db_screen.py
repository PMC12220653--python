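"""Database-level screens for chimeric mis-annotation signatures.

Two analyses over a protein-vs-protein hit table:

* **coverage signature** — each retained hit contributes a (query coverage,
  target coverage) point; a population of chimeric queries hit by their
  full-length components piles up at high target coverage with fractional
  query coverage (a two-equal-part chimera sits at exactly (0.5, 1.0)).
  Points are binned on a 2D histogram and summarised per query.
* **length-ratio audit** — log2(query length / target length) per
  high-confidence hit; a k-part chimera clusters near log2(k).

Self-hits (query_id == target_id) carry no mis-annotation signal and are
excluded from both screens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import ProteinRecord
from .homology import Hit, HitTable

logger = logging.getLogger(__name__)


@dataclass
class ScreenFilter:
    """Hit-retention thresholds for the coverage-signature screen."""

    max_e_value: float = 1e-10
    min_aln_len: int = 100
    min_bit_score: float = 200.0     # strict >
    name_pattern: str | None = None  # case-insensitive substring on header

    def __post_init__(self):
        if self.max_e_value <= 0 or self.min_aln_len <= 0 or self.min_bit_score <= 0:
            raise ValueError("ScreenFilter thresholds must be positive")


#: the header substring used in the published screen of uncurated entries
UNCHARACTERIZED_PATTERN = "uncharacterized protein"


@dataclass
class CoverageSignature:
    """Per-hit coverage pairs, their 2D histogram, and per-query means."""

    pairs: list[tuple[float, float]] = field(default_factory=list)
    histogram: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    bin_edges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    per_query_means: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return len(self.pairs)


def apply_screen_filter(
    hits: HitTable,
    headers: dict[str, str] | None = None,
    screen: ScreenFilter | None = None,
) -> HitTable:
    """Retain hits with e ≤ max_e_value, alignment length ≥ min_aln_len,
    bit score > min_bit_score (strict) and, when ``name_pattern`` is set,
    a query header containing the pattern case-insensitively."""
    screen = screen or ScreenFilter()
    pattern = screen.name_pattern.lower() if screen.name_pattern else None
    kept: list[Hit] = []
    for h in hits:
        if h.e_value > screen.max_e_value:
            continue
        if h.aln_len < screen.min_aln_len:
            continue
        if h.bit_score <= screen.min_bit_score:
            continue
        if pattern is not None:
            header = (headers or {}).get(h.query_id)
            if header is None:
                logger.warning(
                    "query %s has no header; hit dropped from name screen",
                    h.query_id,
                )
                continue
            if pattern not in header.lower():
                continue
        kept.append(h)
    return HitTable(kept)


def coverage_signature(hits: HitTable, n_bins: int = 50) -> CoverageSignature:
    """Bin (q_cov, t_cov) pairs of non-self hits on an equal-width
    [0,1]×[0,1] grid and compute per-query mean coverages."""
    informative = [h for h in hits if h.query_id != h.target_id]
    if not informative:
        return CoverageSignature(
            histogram=np.zeros((n_bins, n_bins), dtype=int),
            bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        )
    qc = np.array([h.q_cov for h in informative])
    tc = np.array([h.t_cov for h in informative])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(qc, tc, bins=[edges, edges])
    df = pd.DataFrame(
        {"query_id": [h.query_id for h in informative], "q_cov": qc, "t_cov": tc}
    )
    means = df.groupby("query_id", sort=True)[["q_cov", "t_cov"]].mean()
    return CoverageSignature(
        pairs=list(zip(qc.tolist(), tc.tolist())),
        histogram=hist.astype(int),
        bin_edges=edges,
        per_query_means={
            q: (row["q_cov"], row["t_cov"]) for q, row in means.iterrows()
        },
    )


@dataclass
class LengthRatioAudit:
    """Per-hit log2 length ratios with an optional corrected-length marker
    per query (e.g. the matching alternate-annotation model's length)."""

    ratios: pd.DataFrame = field(default_factory=pd.DataFrame)
    histogram: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    bin_edges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    corrected_markers: dict[str, float] = field(default_factory=dict)


def length_ratio_audit(
    queries: list[ProteinRecord],
    hits: HitTable,
    max_e_value: float = 1e-30,
    corrected_lengths: dict[str, int] | None = None,
    n_bins: int = 60,
    ratio_range: tuple[float, float] = (-3.0, 3.0),
) -> LengthRatioAudit:
    """log2(q_len / t_len) per non-self hit with e-value < max_e_value
    (strict), plus markers at log2(q_len / corrected_length)."""
    q_len = {r.protein_id: r.length for r in queries}
    rows = []
    for h in hits:
        if h.query_id == h.target_id:
            continue
        if h.e_value >= max_e_value:
            continue
        ql = q_len.get(h.query_id, h.q_len)
        rows.append(
            {
                "query_id": h.query_id,
                "target_id": h.target_id,
                "q_len": ql,
                "t_len": h.t_len,
                "log2_ratio": math.log2(ql / h.t_len),
            }
        )
    df = pd.DataFrame(
        rows, columns=["query_id", "target_id", "q_len", "t_len", "log2_ratio"]
    )
    edges = np.linspace(*ratio_range, n_bins + 1)
    hist, _ = np.histogram(df["log2_ratio"].to_numpy(), bins=edges)
    markers = {}
    for qid, clen in (corrected_lengths or {}).items():
        if qid in q_len and clen > 0:
            markers[qid] = math.log2(q_len[qid] / clen)
    return LengthRatioAudit(
        ratios=df, histogram=hist, bin_edges=edges, corrected_markers=markers
    )


def write_signature_tsvs(sig: CoverageSignature, out_prefix: str | Path) -> None:
    """Write per-hit pairs, per-query means, and the histogram as TSVs."""
    prefix = str(out_prefix)
    with open(prefix + ".hits.tsv", "w") as fh:
        fh.write("q_cov\tt_cov\n")
        for qc, tc in sig.pairs:
            fh.write(f"{qc:.6f}\t{tc:.6f}\n")
    with open(prefix + ".query_means.tsv", "w") as fh:
        fh.write("query_id\tmean_q_cov\tmean_t_cov\n")
        for qid, (mq, mt) in sig.per_query_means.items():
            fh.write(f"{qid}\t{mq:.6f}\t{mt:.6f}\n")
    with open(prefix + ".histogram.tsv", "w") as fh:
        fh.write("bin_x\tbin_y\tcount\n")
        for i in range(sig.histogram.shape[0]):
            for j in range(sig.histogram.shape[1]):
                fh.write(f"{i}\t{j}\t{int(sig.histogram[i, j])}\n")
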