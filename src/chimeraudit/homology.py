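"""Homology hits: the m8 tabular format, coverage fractions, and an
internal exact-match search oracle for synthetic fixtures.

Coverage is defined over 1-based inclusive aligned spans:
``q_cov = (q_end - q_start + 1) / q_len`` and analogously for the target,
matching BLAST/MMseqs2 tabular conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_io import ProteinRecord
from .errors import HitTableError, UndefinedResultError

logger = logging.getLogger(__name__)

#: the three accepted tabular dialects
DIALECT_M8 = "m8"                # 12 standard columns
DIALECT_M8_LENS = "m8+lens"      # 12 columns + qlen, tlen
DIALECT_M8_COV = "m8+cov"        # 12 columns + qcov, tcov


@dataclass(frozen=True)
class Hit:
    """One homology alignment between a query and a target protein."""

    query_id: str
    target_id: str
    percent_identity: float
    aln_len: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    e_value: float
    bit_score: float
    q_len: int
    t_len: int
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self):
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise HitTableError(
                f"invalid query span [{self.q_start},{self.q_end}] for "
                f"{self.query_id} (length {self.q_len})"
            )
        if not (1 <= self.t_start <= self.t_end <= self.t_len):
            raise HitTableError(
                f"invalid target span [{self.t_start},{self.t_end}] for "
                f"{self.target_id} (length {self.t_len})"
            )
        if self.e_value < 0:
            raise HitTableError(f"negative e-value on {self.query_id}")

    @property
    def q_cov(self) -> float:
        return (self.q_end - self.q_start + 1) / self.q_len

    @property
    def t_cov(self) -> float:
        return (self.t_end - self.t_start + 1) / self.t_len

    def swapped(self) -> "Hit":
        """The same alignment viewed with query and target roles exchanged."""
        return Hit(
            query_id=self.target_id,
            target_id=self.query_id,
            percent_identity=self.percent_identity,
            aln_len=self.aln_len,
            q_start=self.t_start,
            q_end=self.t_end,
            t_start=self.q_start,
            t_end=self.q_end,
            e_value=self.e_value,
            bit_score=self.bit_score,
            q_len=self.t_len,
            t_len=self.q_len,
            mismatches=self.mismatches,
            gap_opens=self.gap_opens,
        )


@dataclass
class HitTable:
    """An ordered list of hits with a query-id index."""

    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self):
        self._by_query: dict[str, list[Hit]] = {}
        for h in self.hits:
            self._by_query.setdefault(h.query_id, []).append(h)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def by_query(self, query_id: str) -> list[Hit]:
        return self._by_query.get(query_id, [])

    @property
    def query_ids(self) -> list[str]:
        return list(self._by_query)

    @property
    def target_ids(self) -> set[str]:
        return {h.target_id for h in self.hits}


def _fmt(x: float) -> str:
    return repr(x) if isinstance(x, float) else str(x)


def read_hits(
    path: str | Path,
    dialect: str | None = None,
    query_lengths: dict[str, int] | None = None,
    target_lengths: dict[str, int] | None = None,
    max_e_value: float | None = None,
) -> HitTable:
    """Read a BLAST/MMseqs2 tabular ("m8") hit table.

    The dialect is auto-detected from the column count when not given:
    12 columns is plain m8 (sequence lengths must then come from
    ``query_lengths``/``target_lengths``), 14 columns carries either
    qlen/tlen or qcov/tcov in the last two columns (fractions ≤ 1 are
    read as coverages). Rows with coordinates outside [1, len] are
    rejected with a logged line number. ``max_e_value`` drops hits above
    the threshold at load time.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            row_dialect = dialect
            if row_dialect is None:
                if len(cols) == 12:
                    row_dialect = DIALECT_M8
                elif len(cols) == 14:
                    try:
                        a, b = float(cols[12]), float(cols[13])
                    except ValueError as exc:
                        raise HitTableError(
                            f"{path}:{lineno}: unparseable extra columns"
                        ) from exc
                    row_dialect = (
                        DIALECT_M8_COV if a <= 1.0 and b <= 1.0 else DIALECT_M8_LENS
                    )
                else:
                    raise HitTableError(
                        f"{path}:{lineno}: expected 12 or 14 columns, "
                        f"found {len(cols)}"
                    )
            try:
                qid, tid = cols[0], cols[1]
                pident = float(cols[2])
                aln_len = int(cols[3])
                mism, gaps = int(cols[4]), int(cols[5])
                qs, qe = int(cols[6]), int(cols[7])
                ts, te = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bits = float(cols[11])
            except (ValueError, IndexError) as exc:
                raise HitTableError(f"{path}:{lineno}: malformed row: {exc}") from exc

            if row_dialect == DIALECT_M8_LENS:
                qlen, tlen = int(cols[12]), int(cols[13])
            elif row_dialect == DIALECT_M8_COV:
                qcov, tcov = float(cols[12]), float(cols[13])
                if qcov <= 0 or tcov <= 0:
                    logger.warning("%s:%d: non-positive coverage; row rejected", path, lineno)
                    continue
                # recover lengths from span and coverage (exact for fractions
                # written by write_hits; rounded otherwise)
                qlen = round((qe - qs + 1) / qcov)
                tlen = round((te - ts + 1) / tcov)
            else:
                if query_lengths is None or target_lengths is None:
                    raise HitTableError(
                        f"{path}: 12-column dialect requires query and target "
                        "lengths (supply FASTA-derived length maps)"
                    )
                try:
                    qlen = query_lengths[qid]
                    tlen = target_lengths[tid]
                except KeyError as exc:
                    raise HitTableError(
                        f"{path}:{lineno}: no length known for {exc.args[0]!r}"
                    ) from exc

            try:
                hit = Hit(
                    query_id=qid, target_id=tid, percent_identity=pident,
                    aln_len=aln_len, mismatches=mism, gap_opens=gaps,
                    q_start=qs, q_end=qe, t_start=ts, t_end=te,
                    e_value=evalue, bit_score=bits, q_len=qlen, t_len=tlen,
                )
            except HitTableError as exc:
                logger.warning("%s:%d: %s; row rejected", path, lineno, exc)
                continue
            if max_e_value is not None and hit.e_value > max_e_value:
                continue
            hits.append(hit)
    return HitTable(hits)


def write_hits(table: HitTable, path: str | Path, dialect: str = DIALECT_M8_LENS) -> None:
    """Write a hit table in one of the m8 dialects (tab-separated)."""
    with open(path, "w") as fh:
        for h in table:
            cols = [
                h.query_id, h.target_id, _fmt(h.percent_identity),
                str(h.aln_len), str(h.mismatches), str(h.gap_opens),
                str(h.q_start), str(h.q_end), str(h.t_start), str(h.t_end),
                _fmt(h.e_value), _fmt(h.bit_score),
            ]
            if dialect == DIALECT_M8_LENS:
                cols += [str(h.q_len), str(h.t_len)]
            elif dialect == DIALECT_M8_COV:
                cols += [repr(h.q_cov), repr(h.t_cov)]
            elif dialect != DIALECT_M8:
                raise ValueError(f"unknown dialect {dialect!r}")
            fh.write("\t".join(cols) + "\n")


def median_query_coverage(hits: list[Hit]) -> float:
    """Median of q_cov over a gene's hits (even count: mean of the two
    central values)."""
    if not hits:
        raise UndefinedResultError("median coverage of an empty hit list")
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise UndefinedResultError(
            f"median_query_coverage expects one query, got {sorted(queries)}"
        )
    covs = sorted(h.q_cov for h in hits)
    n = len(covs)
    mid = n // 2
    if n % 2 == 1:
        return covs[mid]
    return (covs[mid - 1] + covs[mid]) / 2


def pooled_median_query_coverage(hit_groups: list[list[Hit]]) -> float:
    """Median of q_cov pooled across several genes' hit lists."""
    covs = sorted(h.q_cov for group in hit_groups for h in group)
    if not covs:
        raise UndefinedResultError("median coverage of an empty pooled hit list")
    n = len(covs)
    mid = n // 2
    if n % 2 == 1:
        return covs[mid]
    return (covs[mid - 1] + covs[mid]) / 2


def oracle_search(
    queries: list[ProteinRecord], targets: list[ProteinRecord]
) -> HitTable:
    """Exact-substring search oracle used for synthetic fixtures.

    Emits one hit per occurrence of a full target inside a query (and,
    symmetrically, of a full query inside a longer target), with 100%
    identity, e-value 0 and bit score 2 × alignment length. This idealises
    what a real aligner reports for the planted, mutually non-homologous
    component proteins of the simulator; it is not a general aligner.
    """
    hits: list[Hit] = []
    for q in queries:
        for t in targets:
            if t.length <= q.length:
                # full target inside query
                start = q.sequence.find(t.sequence)
                while start != -1:
                    hits.append(
                        Hit(
                            query_id=q.protein_id, target_id=t.protein_id,
                            percent_identity=100.0, aln_len=t.length,
                            q_start=start + 1, q_end=start + t.length,
                            t_start=1, t_end=t.length,
                            e_value=0.0, bit_score=2.0 * t.length,
                            q_len=q.length, t_len=t.length,
                        )
                    )
                    start = q.sequence.find(t.sequence, start + 1)
            else:
                # full query inside longer target
                start = t.sequence.find(q.sequence)
                while start != -1:
                    hits.append(
                        Hit(
                            query_id=q.protein_id, target_id=t.protein_id,
                            percent_identity=100.0, aln_len=q.length,
                            q_start=1, q_end=q.length,
                            t_start=start + 1, t_end=start + q.length,
                            e_value=0.0, bit_score=2.0 * q.length,
                            q_len=q.length, t_len=t.length,
                        )
                    )
                    start = t.sequence.find(q.sequence, start + 1)
    return HitTable(hits)
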