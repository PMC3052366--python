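import numpy as np
import pytest

from coevostab import AA_ORDER, Alignment


def make_alignment(rows, ids=None, labels=None):
    ids = ids or [f"s{k}" for k in range(len(rows))]
    return Alignment(ids=ids, rows=list(rows), labels=labels)


def random_alignment(n, L, seed, gap_rate=0.0):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 20, size=(n, L))
    aa = np.array(list(AA_ORDER))
    rows = []
    for k in range(n):
        chars = aa[codes[k]]
        if gap_rate:
            chars[rng.random(L) < gap_rate] = "-"
        rows.append("".join(chars))
    return make_alignment(rows)


@pytest.fixture
def toy_alignment():
    # 4 rows, 4 columns: col1/col2 perfectly covarying, col3 conserved,
    # col4 independent of col1
    return make_alignment(["ALGK", "ALGR", "RKGK", "RKGR"])
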