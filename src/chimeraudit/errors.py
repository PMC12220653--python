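"""Exception hierarchy.

All data-level failures raise :class:`ChimeraAuditError` subclasses so the
CLI can map them to exit code 1 while genuine bugs propagate normally.
"""


class ChimeraAuditError(Exception):
    """Base class for all data errors raised by this package."""


class Gff3ParseError(ChimeraAuditError):
    """A GFF3 line could not be parsed; the message names the line number."""


class Gff3StructuralError(ChimeraAuditError):
    """Features parsed but the gene/mRNA/CDS hierarchy is inconsistent."""


class FrameError(ChimeraAuditError):
    """A CDS length is not a codon multiple after applying its phase."""


class FastaError(ChimeraAuditError):
    """Invalid FASTA content or records that violate protein invariants."""


class HitTableError(ChimeraAuditError):
    """A homology hit table could not be read or lacks required lengths."""


class UndefinedResultError(ChimeraAuditError):
    """A statistic is undefined for the given input (empty, constant...)."""


class ConsistencyError(ChimeraAuditError):
    """Cross-input consistency violated (e.g. hit IDs absent from GFF)."""


class SimulationError(ChimeraAuditError):
    """Synthetic-genome construction is infeasible for the configuration."""
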