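import io

import numpy as np
import pytest

from molemstat import MolemClass, RatingTable, read_ratings
from molemstat.ratings import CountMatrix


@pytest.fixture
def toy_csv(tmp_path):
    """Three raters on one lesion: (I, I, III)."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "lesion_id,rater_id,molem_class,confidence\n"
        "L1,P1,I,1\nL1,P2,I,2\nL1,P3,III,3\n"
    )
    return path


@pytest.fixture
def unanimous_table():
    """Six lesions, every rater agrees; spans several classes."""
    rows = []
    for i, cls in enumerate(["I", "I", "II", "III", "IV", "V"]):
        for r in range(4):
            rows.append(f"U{i},P{r},{cls},1")
    return _table_from_rows(rows)


def _table_from_rows(rows, header="lesion_id,rater_id,molem_class,confidence"):
    import pandas as pd

    return RatingTable(pd.read_csv(io.StringIO(header + "\n" + "\n".join(rows))))


@pytest.fixture
def table_from_rows():
    return _table_from_rows


def random_count_matrix(rng, max_lesions=30, max_raters=5, q=5):
    """A random per-lesion count matrix, some lesions with a single rating."""
    n = int(rng.integers(2, max_lesions + 1))
    rows = np.zeros((n, q), dtype=int)
    for i in range(n):
        m = int(rng.integers(1, max_raters + 1)) if i > 1 else int(rng.integers(2, max_raters + 1))
        cats = rng.integers(0, q, size=m)
        for c in cats:
            rows[i, c] += 1
    return CountMatrix(tuple(f"L{i}" for i in range(n)), rows)
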