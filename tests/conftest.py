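import numpy as np
import pandas as pd
import pytest

from atacploidy import FragmentSet


@pytest.fixture
def toy_fragments() -> FragmentSet:
    """One barcode, three fragments with one overlapping pair."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [100, 150, 300],
            "end": [200, 250, 400],
            "barcode": ["A"] * 3,
        }
    )
    return FragmentSet(df)


@pytest.fixture
def write_fragments_file(tmp_path):
    """Write raw fragment lines (list of tuples) to a TSV and return its path."""

    def _write(rows, name="frags.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)
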