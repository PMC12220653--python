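import textwrap

import pytest

from chimeraudit.homology import Hit
from chimeraudit.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic audit: 50 genes, 5 planted chimeras, seed 7."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture
def gff_file(tmp_path):
    """Write a dedented GFF3 string (with spaces as column separators
    converted to tabs) to a temp file and return its path."""

    def _write(text, name="test.gff3"):
        body = textwrap.dedent(text).strip("\n")
        lines = []
        for line in body.splitlines():
            if line.startswith("#"):
                lines.append(line)
            else:
                lines.append("\t".join(line.split(maxsplit=8)))
        path = tmp_path / name
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def make_hit(
    query_id="q1",
    target_id="t1",
    q_start=1,
    q_end=100,
    q_len=100,
    t_start=1,
    t_end=None,
    t_len=None,
    e_value=0.0,
    bit_score=200.0,
    percent_identity=100.0,
    aln_len=None,
):
    """Hit builder with target defaults mirroring the aligned query span."""
    span = q_end - q_start + 1
    if t_end is None:
        t_end = t_start + span - 1
    if t_len is None:
        t_len = t_end
    return Hit(
        query_id=query_id,
        target_id=target_id,
        percent_identity=percent_identity,
        aln_len=aln_len if aln_len is not None else span,
        q_start=q_start,
        q_end=q_end,
        t_start=t_start,
        t_end=t_end,
        e_value=e_value,
        bit_score=bit_score,
        q_len=q_len,
        t_len=t_len,
    )
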