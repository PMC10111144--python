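import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from compbias.sequence_io import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20220404)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return the path."""

    def _write(text: str, name: str = "input.fasta") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def association_frame():
    def _frame(rows):
        return pd.DataFrame(rows, columns=["gene_id", "doid"])

    return _frame


def make_record(rec_id: str, sequence: str, gene: str | None = None,
                doids: list[str] | None = None) -> ProteinRecord:
    desc = f"test protein gene:{gene}" if gene else "test protein"
    return ProteinRecord(id=rec_id, description=desc, sequence=sequence,
                         doids=doids or [])
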