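"""Classify annotation differences from RBH protein-length ratios.

Builds a toy pair of hit tables in which one gene is split 2:1 between the
annotations, then tabulates the log2 length-ratio categories.
"""

from chimeraudit.homology import Hit, HitTable
from chimeraudit.rbh_fusion import reciprocal_best_hits, tabulate_categories


def hit(q, t, q_len, t_len, bits):
    span = min(q_len, t_len)
    return Hit(query_id=q, target_id=t, percent_identity=95.0, aln_len=span,
               q_start=1, q_end=span, t_start=1, t_end=span,
               e_value=1e-50, bit_score=bits, q_len=q_len, t_len=t_len)


# annotation A gene a2 (1000 aa) corresponds to a 500-aa model in B: a split
ab = HitTable([hit("a1", "b1", 450, 452, 900), hit("a2", "b2", 1000, 500, 990)])
ba = HitTable([hit("b1", "a1", 452, 450, 900), hit("b2", "a2", 500, 1000, 990)])

pairs = reciprocal_best_hits(ab, ba)
for p in pairs:
    print(f"{p.id_a} ~ {p.id_b}: len {p.len_a} vs {p.len_b}, "
          f"log2 ratio {p.log2_ratio:+.3f} -> {p.category}")
print("category counts:", {k: v for k, v in tabulate_categories(pairs).items() if v})
# a log2 ratio near +1 means the first annotation's model is about twice the
# other's: one gene annotated as two in the comparator (a 2:1 split).
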