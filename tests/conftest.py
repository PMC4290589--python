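import textwrap
from pathlib import Path

import pytest

from draftrank.assembly_metrics import Assembly, Level


@pytest.fixture
def write_fasta(tmp_path):
    """Write a FASTA file from (id, seq) pairs and return its path."""

    def _write(records, name="test.fasta", wrap=0):
        lines = []
        for rid, seq in records:
            lines.append(f">{rid}")
            if wrap:
                lines.extend(textwrap.wrap(seq, wrap))
            else:
                lines.append(seq)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def assembly_from_lengths():
    """Build an Assembly of A-runs with the given lengths."""

    def _make(lengths, name="asm", level=Level.CONTIGS):
        records = tuple(
            (f"c{i}", "A" * length) for i, length in enumerate(lengths)
        )
        return Assembly(name=name, level=level, records=records)

    return _make
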