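"""Seeded simulator of genomes with planted chimeric gene models.

The generator emits a complete audit bundle: a genome FASTA, a reference
GFF3 in which each planted chimera appears as one fused gene, an alternate
GFF3 in which the same locus appears as its k component genes, a trusted
protein database holding every component protein, idealized reference and
alternate hit tables in the m8 dialect, and a truth table.

Construction guarantees exact arithmetic everywhere:

* a fused gene concatenates complete component CDS structures, with the
  components' intergenic DNA retained inside the fused model as intron-like
  spacers, so the fused protein is the exact concatenation of the component
  proteins and a component hit has query coverage component_len/fused_len
  with full target coverage;
* component proteins are mutually non-homologous by construction (each is
  drawn from its own small residue alphabet under a seeded shuffle), so the
  exact-match search oracle produces no cross-hits;
* the default component-count mixture (k = 2..6 weighted 499:81:12:6:2)
  mirrors the composition observed across real curated genomes, where
  two-gene fusions dominate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    ProteinRecord,
    TranscriptModel,
    reverse_complement,
    write_gff3,
    write_protein_fasta,
)
from .errors import SimulationError
from .homology import DIALECT_M8_LENS, Hit, HitTable, write_hits

# codon choices per amino acid, standard code (stops handled separately)
_CODONS: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]
# alphabet pool for protein bodies; 'M' reserved for the start codon
_AA_POOL = "ACDEFGHIKLNPQRSTVWY"


@dataclass
class SimulationConfig:
    """The study conditions of the synthetic audit.

    Defaults give 50 multi-exon genes on 2 sequences with 5 planted
    chimeras whose component counts follow the observed 499:81:12:6:2
    mixture for k = 2..6.
    """

    seed: int = 7
    n_sequences: int = 2
    n_genes: int = 50
    n_chimeras: int = 5
    gene_length_range: tuple[int, int] = (120, 400)        # aa
    exons_per_gene_range: tuple[int, int] = (2, 6)
    intron_length_range: tuple[int, int] = (40, 120)       # bases
    intergenic_gap_range: tuple[int, int] = (150, 600)     # bases
    gc_target: float = 0.40
    component_count_weights: dict[int, float] = field(
        default_factory=lambda: {2: 499, 3: 81, 4: 12, 5: 6, 6: 2}
    )
    coverage_noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_chimeras > self.n_genes:
            raise SimulationError("n_chimeras cannot exceed n_genes")
        w = self.component_count_weights
        if not w or any(v < 0 for v in w.values()) or sum(w.values()) == 0:
            raise SimulationError("component_count_weights must be non-negative, not all zero")


@dataclass
class TruthRecord:
    ref_gene_id: str
    is_chimera: bool
    component_count: int
    component_protein_ids: list[str]


@dataclass
class SimulationBundle:
    """In-memory result of :func:`simulate`; ``write`` emits the files."""

    config: SimulationConfig
    genome: dict[str, GenomeSequence]
    reference: AnnotationSet
    alternate: AnnotationSet
    database: list[ProteinRecord]
    ref_hits: HitTable
    alt_hits: HitTable
    truth: list[TruthRecord]

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write the six-file bundle plus a manifest with checksums."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "reference_gff3": out / "reference.gff3",
            "alternate_gff3": out / "alternate.gff3",
            "proteins": out / "proteins.fasta",
            "ref_hits": out / "ref_hits.m8",
            "alt_hits": out / "alt_hits.m8",
            "truth": out / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for seq in self.genome.values():
                fh.write(f">{seq.seq_id}\n")
                for i in range(0, seq.length, 60):
                    fh.write(seq.residues[i : i + 60] + "\n")
        write_gff3(self.reference, paths["reference_gff3"])
        write_gff3(self.alternate, paths["alternate_gff3"])
        write_protein_fasta(self.database, paths["proteins"])
        write_hits(self.ref_hits, paths["ref_hits"], dialect=DIALECT_M8_LENS)
        write_hits(self.alt_hits, paths["alt_hits"], dialect=DIALECT_M8_LENS)
        write_truth_tsv(self.truth, paths["truth"])
        manifest = {
            "config": _jsonable_config(self.config),
            "checksums": {
                name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in paths.items()
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {name: str(p) for name, p in paths.items()}


def _jsonable_config(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["component_count_weights"] = {str(k): v for k, v in cfg.component_count_weights.items()}
    return d


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_gene_id\tis_chimera\tcomponent_count\tcomponent_protein_ids\n")
        for t in truth:
            fh.write(
                f"{t.ref_gene_id}\t{str(t.is_chimera).lower()}\t"
                f"{t.component_count}\t{','.join(t.component_protein_ids)}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            gid, chim, k, prots = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(gid, chim == "true", int(k), prots.split(",") if prots else [])
            )
    return out


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """A protein over its own 4-letter alphabet (plus the leading M), so
    distinct proteins are non-homologous with overwhelming probability."""
    alphabet = rng.choice(list(_AA_POOL), size=4, replace=False)
    body = rng.choice(alphabet, size=length - 1)
    return "M" + "".join(body)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


@dataclass
class _GeneUnit:
    """A gene structure laid out on a local plus-strand construct."""

    protein: str
    dna: str
    cds_rel: list[tuple[int, int]]  # 0-based half-open on the construct


def _build_unit(
    rng: np.random.Generator, cfg: SimulationConfig, protein: str, with_stop: bool
) -> _GeneUnit:
    cds = _reverse_translate(rng, protein)
    if with_stop:
        cds += _STOPS[rng.integers(0, len(_STOPS))]
    n_exons = int(rng.integers(cfg.exons_per_gene_range[0], cfg.exons_per_gene_range[1] + 1))
    n_exons = min(n_exons, len(cds) // 30 or 1)
    # exon boundaries at arbitrary base offsets (phases exercise the parser)
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0] + [int(c) for c in cuts] + [len(cds)]
    dna_parts: list[str] = []
    cds_rel: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_exons):
        exon = cds[bounds[i] : bounds[i + 1]]
        cds_rel.append((pos, pos + len(exon)))
        dna_parts.append(exon)
        pos += len(exon)
        if i < n_exons - 1:
            ilen = int(rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1))
            dna_parts.append(_random_dna(rng, ilen, cfg.gc_target))
            pos += ilen
    return _GeneUnit(protein=protein, dna="".join(dna_parts), cds_rel=cds_rel)


def _phases(cds_rel: list[tuple[int, int]]) -> list[int]:
    """GFF3 phases for segments listed in transcription order."""
    out, consumed = [], 0
    for s, e in cds_rel:
        out.append((3 - consumed % 3) % 3)
        consumed += e - s
    return out


def simulate(cfg: SimulationConfig, out_dir: str | Path | None = None) -> SimulationBundle:
    """Generate the bundle; byte-identical output under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)

    # assign chimera slots and component counts up front
    chimera_slots = set(
        int(i) for i in rng.choice(cfg.n_genes, size=cfg.n_chimeras, replace=False)
    )
    ks = sorted(cfg.component_count_weights)
    weights = np.array([cfg.component_count_weights[k] for k in ks], dtype=float)
    weights /= weights.sum()

    seq_ids = [f"seq{i + 1}" for i in range(cfg.n_sequences)]
    seq_parts: dict[str, list[str]] = {s: [] for s in seq_ids}
    seq_pos: dict[str, int] = {s: 0 for s in seq_ids}

    ref_genes: list[GeneModel] = []
    alt_genes: list[GeneModel] = []
    database: list[ProteinRecord] = []
    truth: list[TruthRecord] = []
    ref_hit_rows: list[Hit] = []
    alt_hit_rows: list[Hit] = []
    protein_counter = 0

    def next_protein_id() -> str:
        nonlocal protein_counter
        protein_counter += 1
        return f"dbp{protein_counter:04d}"

    for gi in range(cfg.n_genes):
        seq_id = seq_ids[gi % cfg.n_sequences]
        strand = "+" if rng.random() < 0.5 else "-"
        ref_id = f"rg{gi + 1:04d}"
        is_chimera = gi in chimera_slots
        k = int(rng.choice(ks, p=weights)) if is_chimera else 1

        # build k units and the local construct (plus-strand orientation)
        units: list[_GeneUnit] = []
        for ci in range(k):
            plen = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
            protein = _random_protein(rng, plen)
            units.append(_build_unit(rng, cfg, protein, with_stop=(k == 1)))
        construct_parts: list[str] = []
        unit_offsets: list[int] = []
        pos = 0
        for ci, unit in enumerate(units):
            if ci > 0:
                gap = int(rng.integers(cfg.intergenic_gap_range[0], cfg.intergenic_gap_range[1] + 1))
                construct_parts.append(_random_dna(rng, gap, cfg.gc_target))
                pos += gap
            unit_offsets.append(pos)
            construct_parts.append(unit.dna)
            pos += len(unit.dna)
        construct = "".join(construct_parts)

        # place the construct on the genome after an intergenic gap
        lead = int(rng.integers(cfg.intergenic_gap_range[0], cfg.intergenic_gap_range[1] + 1))
        seq_parts[seq_id].append(_random_dna(rng, lead, cfg.gc_target))
        seq_pos[seq_id] += lead
        g_start = seq_pos[seq_id]
        seq_parts[seq_id].append(construct if strand == "+" else reverse_complement(construct))
        seq_pos[seq_id] += len(construct)
        g_end = seq_pos[seq_id]

        def to_genome(rel: tuple[int, int]) -> tuple[int, int]:
            s, e = rel
            if strand == "+":
                return (g_start + s, g_start + e)
            L = len(construct)
            return (g_start + L - e, g_start + L - s)

        # per-unit genome CDS segments, transcription order == unit order
        unit_segments: list[list[tuple[int, int]]] = []
        for off, unit in zip(unit_offsets, units):
            segs_tx = [to_genome((off + s, off + e)) for s, e in unit.cds_rel]
            unit_segments.append(segs_tx)

        # fused reference gene: all segments of all units
        fused_tx_segments = [seg for segs in unit_segments for seg in segs]
        fused_phases = _phases(
            [seg for unit in units for seg in unit.cds_rel]
        )
        ref_tm = TranscriptModel(transcript_id=f"{ref_id}.t1")
        ref_tm.cds_segments = sorted(
            (s, e, p) for (s, e), p in zip(fused_tx_segments, fused_phases)
        )
        ref_genes.append(
            GeneModel(
                gene_id=ref_id, seq_id=seq_id, strand=strand,
                start=g_start, end=g_end, transcripts=[ref_tm],
            )
        )

        # alternate annotation: one gene per unit
        comp_ids: list[str] = []
        fused_protein_len = sum(len(u.protein) for u in units)
        q_offset = 0
        for ci, (unit, segs) in enumerate(zip(units, unit_segments)):
            pid = next_protein_id()
            comp_ids.append(pid)
            database.append(
                ProteinRecord(
                    protein_id=pid, sequence=unit.protein, source="database",
                    gene_id=ref_id,
                )
            )
            alt_id = f"ag{gi + 1:04d}" if k == 1 else f"ag{gi + 1:04d}_{ci + 1}"
            alt_tm = TranscriptModel(transcript_id=f"{alt_id}.t1")
            alt_tm.cds_segments = sorted(
                (s, e, p) for (s, e), p in zip(segs, _phases(unit.cds_rel))
            )
            a_start = min(s for s, _, _ in alt_tm.cds_segments)
            a_end = max(e for _, e, _ in alt_tm.cds_segments)
            alt_genes.append(
                GeneModel(
                    gene_id=alt_id, seq_id=seq_id, strand=strand,
                    start=a_start, end=a_end, transcripts=[alt_tm],
                )
            )
            plen = len(unit.protein)
            # ideal hits: component protein vs fused reference gene ...
            ref_hit_rows.append(
                Hit(
                    query_id=ref_id, target_id=pid, percent_identity=100.0,
                    aln_len=plen, q_start=q_offset + 1, q_end=q_offset + plen,
                    t_start=1, t_end=plen, e_value=0.0, bit_score=2.0 * plen,
                    q_len=fused_protein_len, t_len=plen,
                )
            )
            # ... and vs its own split alternate gene (full coverage)
            alt_hit_rows.append(
                Hit(
                    query_id=alt_id, target_id=pid, percent_identity=100.0,
                    aln_len=plen, q_start=1, q_end=plen, t_start=1, t_end=plen,
                    e_value=0.0, bit_score=2.0 * plen, q_len=plen, t_len=plen,
                )
            )
            q_offset += plen
        truth.append(
            TruthRecord(
                ref_gene_id=ref_id, is_chimera=is_chimera,
                component_count=k, component_protein_ids=comp_ids,
            )
        )

    # trailing intergenic DNA on every sequence
    for seq_id in seq_ids:
        tail = int(rng.integers(cfg.intergenic_gap_range[0], cfg.intergenic_gap_range[1] + 1))
        seq_parts[seq_id].append(_random_dna(rng, tail, cfg.gc_target))
        seq_pos[seq_id] += tail

    genome = {
        s: GenomeSequence(seq_id=s, residues="".join(seq_parts[s])) for s in seq_ids
    }

    # guard: no database protein may occur in a reference protein except as
    # planted (violations are astronomically unlikely under the disjoint
    # alphabets, but the contract is checked, not assumed)
    _check_no_spurious_matches(database, truth)

    ref_table = HitTable(ref_hit_rows)
    if cfg.coverage_noise_sd > 0:
        ref_table = perturb_hits(ref_table, cfg)
    bundle = SimulationBundle(
        config=cfg, genome=genome,
        reference=AnnotationSet(ref_genes), alternate=AnnotationSet(alt_genes),
        database=database, ref_hits=ref_table, alt_hits=HitTable(alt_hit_rows),
        truth=truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _check_no_spurious_matches(
    database: list[ProteinRecord], truth: list[TruthRecord]
) -> None:
    by_gene: dict[str, set[str]] = {t.ref_gene_id: set(t.component_protein_ids) for t in truth}
    by_id = {p.protein_id: p for p in database}
    for t in truth:
        fused = "".join(by_id[pid].sequence for pid in t.component_protein_ids)
        for p in database:
            planted = p.protein_id in by_gene[t.ref_gene_id]
            if not planted and p.sequence in fused:
                raise SimulationError(
                    f"spurious homology: {p.protein_id} occurs in {t.ref_gene_id}"
                )


def perturb_hits(hits: HitTable, cfg: SimulationConfig) -> HitTable:
    """Jitter query coverage with seeded Gaussian noise of sd
    ``coverage_noise_sd`` by moving q_start/q_end consistently; all hit
    invariants are preserved. sd = 0 is the identity."""
    if cfg.coverage_noise_sd <= 0:
        return hits
    rng = np.random.default_rng(cfg.seed + 1)
    out: list[Hit] = []
    for h in hits:
        delta = float(rng.normal(0.0, cfg.coverage_noise_sd))
        new_cov = min(1.0, max(1.0 / h.q_len, h.q_cov + delta))
        new_len = max(1, round(new_cov * h.q_len))
        center = (h.q_start + h.q_end) / 2
        new_start = int(round(center - new_len / 2))
        new_start = max(1, min(new_start, h.q_len - new_len + 1))
        out.append(
            Hit(
                query_id=h.query_id, target_id=h.target_id,
                percent_identity=h.percent_identity, aln_len=new_len,
                q_start=new_start, q_end=new_start + new_len - 1,
                t_start=h.t_start, t_end=h.t_end,
                e_value=h.e_value, bit_score=h.bit_score,
                q_len=h.q_len, t_len=h.t_len,
                mismatches=h.mismatches, gap_opens=h.gap_opens,
            )
        )
    return HitTable(out)
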