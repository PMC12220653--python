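"""Reciprocal best hits and the log2 length-ratio fusion/split classifier.

For an RBH pair (a, b) the statistic is ``r = log2(len_a / len_b)``. A gene
split into k models in the other annotation sits near r = log2(k); a fused
one near −log2(k). Categories are closed intervals around those points:

=============  ==================
category       log2-ratio range
=============  ==================
2:1 split      [0.8, 1.2]
3:1 split      [1.4, 1.7]
4:1 split      [1.9, 2.1]
1:2 fusion     [−1.2, −0.8]
1:3 fusion     [−1.7, −1.4]
1:4 fusion     [−2.1, −1.9]
1:1 match      [−0.3, 0.3]
other          anything else
=============  ==================

Endpoints are inclusive; ratios in the gaps are "other". Ratios are rounded
to 3 decimals before interval comparison so that integer length pairs
constructed to land on a boundary (e.g. round(1000·2^0.8) vs 1000) are
classified by the boundary they target rather than by floating-point dust.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .homology import Hit, HitTable

CATEGORY_INTERVALS: list[tuple[str, float, float]] = [
    ("2:1 split", 0.8, 1.2),
    ("3:1 split", 1.4, 1.7),
    ("4:1 split", 1.9, 2.1),
    ("1:2 fusion", -1.2, -0.8),
    ("1:3 fusion", -1.7, -1.4),
    ("1:4 fusion", -2.1, -1.9),
    ("1:1 match", -0.3, 0.3),
]

CATEGORIES: list[str] = [name for name, _, _ in CATEGORY_INTERVALS] + ["other"]

_RATIO_DECIMALS = 3


@dataclass(frozen=True)
class RBHPair:
    """A mutual best-hit pair with its length-ratio category."""

    id_a: str
    id_b: str
    len_a: int
    len_b: int

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.len_a / self.len_b)

    @property
    def category(self) -> str:
        return classify_ratio(self.len_a, self.len_b)


def classify_ratio(len_q: int, len_t: int) -> str:
    """Assign the fusion/split category for a query/target length pair."""
    if len_q <= 0 or len_t <= 0:
        raise ValueError(f"lengths must be positive, got ({len_q}, {len_t})")
    r = round(math.log2(len_q / len_t), _RATIO_DECIMALS)
    for name, lo, hi in CATEGORY_INTERVALS:
        if lo <= r <= hi:
            return name
    return "other"


def _best_hit(hits: list[Hit]) -> Hit:
    """Best hit: maximal bit score, ties by smaller e-value, then
    lexicographically smallest target ID."""
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.target_id))


def reciprocal_best_hits(hits_ab: HitTable, hits_ba: HitTable) -> list[RBHPair]:
    """Pairs (a, b) where b is a's best hit in A→B and a is b's best hit in
    B→A. Output sorted by id_a for determinism."""
    best_ab = {qid: _best_hit(hits_ab.by_query(qid)) for qid in hits_ab.query_ids}
    best_ba = {qid: _best_hit(hits_ba.by_query(qid)) for qid in hits_ba.query_ids}
    pairs: list[RBHPair] = []
    for a, hit_ab in best_ab.items():
        b = hit_ab.target_id
        back = best_ba.get(b)
        if back is not None and back.target_id == a:
            pairs.append(
                RBHPair(id_a=a, id_b=b, len_a=hit_ab.q_len, len_b=hit_ab.t_len)
            )
    pairs.sort(key=lambda p: p.id_a)
    return pairs


def tabulate_categories(pairs: list[RBHPair]) -> dict[str, int]:
    """Frequency of each category (all categories present, zeros kept)."""
    counts = Counter(p.category for p in pairs)
    return {name: counts.get(name, 0) for name in CATEGORIES}


def write_pairs_tsv(pairs: list[RBHPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlen_a\tlen_b\tlog2_ratio\tcategory\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.len_a}\t{p.len_b}\t"
                f"{p.log2_ratio:.4f}\t{p.category}\n"
            )


def write_category_summary_tsv(counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\n")
        for name in CATEGORIES:
            fh.write(f"{name}\t{counts.get(name, 0)}\n")
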