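import itertools

import numpy as np
import pytest

from coexistkit import PresenceAbsenceMatrix


def brute_force_cscore(cells: np.ndarray) -> float:
    """Independent normalized C-score: explicit double loop from scratch."""
    cells = np.asarray(cells)
    n, S = cells.shape
    total = 0
    for i in range(S):
        for j in range(i + 1, S):
            r_i = sum(cells[s, i] for s in range(n))
            r_j = sum(cells[s, j] for s in range(n))
            x = sum(1 for s in range(n) if cells[s, i] == 1 and cells[s, j] == 1)
            total += (r_i - x) * (r_j - x)
    return total / ((S * (S - 1) / 2) * (n * (n - 1) / 2))


def enumerate_fixed_margin(row_sums, col_sums):
    """All binary matrices with the given margins, by exhaustive search."""
    col_sums = np.asarray(col_sums)
    ncol = len(col_sums)
    row_opts = [
        [np.array(c) for c in itertools.product((0, 1), repeat=ncol) if sum(c) == r]
        for r in row_sums
    ]
    out = []
    for combo in itertools.product(*row_opts):
        m = np.vstack(combo)
        if (m.sum(axis=0) == col_sums).all():
            out.append(m)
    return out


def pam(cells) -> PresenceAbsenceMatrix:
    """Wrap a raw 0/1 array with generated labels."""
    cells = np.asarray(cells)
    return PresenceAbsenceMatrix(
        site_ids=tuple(f"s{i}" for i in range(cells.shape[0])),
        species_ids=tuple(f"sp{j}" for j in range(cells.shape[1])),
        cells=cells,
    )


@pytest.fixture
def perfect_checkerboard():
    return pam(np.array([[1, 0], [0, 1]]))
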