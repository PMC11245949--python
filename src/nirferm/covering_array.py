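"""Construction and verification of covering arrays CA(N; t, k, v).

A covering array of strength t is an N x k matrix over {0..v-1} such that
every choice of t distinct columns contains every one of the v^t symbol
tuples in at least one row.  Covering arrays give maximal t-way coverage with
few rows (N grows like log k at fixed t, v), which is what makes them useful
as include/exclude screening designs over feature bands.

The builder is a one-row-at-a-time greedy: each new row is chosen, from a
deterministic marginal-count candidate plus a seeded pool of random
candidates, to cover as many still-uncovered tuples as possible.  Strengths
up to 3 are supported with explicit tuple bookkeeping, which is all the
feature-selection use case needs and keeps verification exhaustive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


class CoveringArrayError(ValueError):
    """Raised on invalid parameters or out-of-range symbols."""


@dataclass
class CoveringArray:
    """An N x k matrix over v symbols with declared strength t."""

    matrix: np.ndarray
    strength: int
    alphabet_size: int
    method: str = "greedy-density"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise CoveringArrayError("matrix must be a non-empty 2-D array")
        if self.strength < 1 or self.strength > self.n_columns:
            raise CoveringArrayError("need 1 <= t <= k")
        if self.alphabet_size < 2:
            raise CoveringArrayError("alphabet size v must be >= 2")
        if self.matrix.min() < 0 or self.matrix.max() >= self.alphabet_size:
            raise CoveringArrayError("symbol out of range {0..v-1}")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _tuple_tables(t: int, k: int, v: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column combinations, symbol decode table and mixed-radix weights."""
    combos = np.array(list(itertools.combinations(range(k), t)), dtype=np.int64)
    weights = v ** np.arange(t - 1, -1, -1)
    codes = np.arange(v**t)
    symbols = np.stack([(codes // w) % v for w in weights], axis=1)
    return combos, symbols, weights


def _coverage_codes(rows: np.ndarray, combos: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Tuple code per (row, column-combination); rows is (n, k)."""
    # (n, m) where m = number of column combinations
    return sum(rows[:, combos[:, pos]] * weights[pos] for pos in range(combos.shape[1]))


def build_covering_array(
    t: int,
    k: int,
    v: int = 2,
    seed: int = 0,
    *,
    n_candidates: int = 30,
) -> CoveringArray:
    """Greedily build a covering array CA(N; t, k, v).

    Each row is the best of ``n_candidates`` seeded random rows plus one
    deterministic candidate that picks, per column, the symbol appearing in
    the most uncovered tuples.  The result always passes
    :func:`verify_coverage`; N is whatever the greedy run needed.
    """
    if t < 1:
        raise CoveringArrayError("strength t must be >= 1")
    if t > k:
        raise CoveringArrayError(f"strength t={t} exceeds column count k={k}")
    if v < 2:
        raise CoveringArrayError("alphabet size v must be >= 2")
    if t > 3:
        raise CoveringArrayError(
            "strengths above 3 are not supported (explicit tuple bookkeeping)"
        )

    rng = np.random.default_rng(seed)
    combos, symbols, weights = _tuple_tables(t, k, v)
    m = combos.shape[0]
    uncovered = np.ones((m, v**t), dtype=bool)
    rows: list[np.ndarray] = []
    # v^t * ceil-log bound is loose; this cap only guards against bugs
    max_rows = v**t * (10 + 5 * t * int(np.ceil(np.log2(max(k, 2)))))

    flat_cols = np.concatenate(
        [np.repeat(combos[:, pos], v**t) for pos in range(t)]
    )
    flat_syms = np.concatenate([np.tile(symbols[:, pos], m) for pos in range(t)])

    while uncovered.any():
        if len(rows) > max_rows:  # pragma: no cover - safety net
            raise CoveringArrayError("greedy construction failed to converge")
        # deterministic candidate: per-column symbol with the largest count
        # of uncovered tuples mentioning it (ties -> lower symbol)
        counts = np.zeros((k, v))
        np.add.at(counts, (flat_cols, flat_syms), np.tile(uncovered.ravel(), t))
        dense = counts.argmax(axis=1)
        candidates = np.vstack(
            [dense, rng.integers(0, v, size=(n_candidates, k), dtype=np.int64)]
        )
        # fallback candidate: force the first uncovered tuple into the
        # density row, guaranteeing progress every iteration
        combo_idx, code = np.argwhere(uncovered)[0]
        forced = dense.copy()
        forced[combos[combo_idx]] = symbols[code]
        candidates = np.vstack([candidates, forced])
        codes = _coverage_codes(candidates, combos, weights)
        gains = uncovered[np.arange(m)[None, :], codes].sum(axis=1)
        best = candidates[int(np.argmax(gains))]
        rows.append(best)
        uncovered[np.arange(m), _coverage_codes(best[None, :], combos, weights)[0]] = False

    return CoveringArray(
        matrix=np.array(rows), strength=t, alphabet_size=v, method="greedy-density"
    )


def verify_coverage(ca: CoveringArray) -> tuple[bool, tuple | None]:
    """Exhaustively check t-way coverage.

    Returns ``(True, None)`` when every t-column symbol tuple is covered,
    otherwise ``(False, (columns, symbols))`` with the first uncovered
    combination as a concrete witness.
    """
    t, v = ca.strength, ca.alphabet_size
    combos, symbols, weights = _tuple_tables(t, ca.n_columns, v)
    codes = _coverage_codes(ca.matrix, combos, weights)  # (N, m)
    for j in range(combos.shape[0]):
        seen = np.zeros(v**t, dtype=bool)
        seen[codes[:, j]] = True
        if not seen.all():
            code = int(np.flatnonzero(~seen)[0])
            return False, (tuple(combos[j]), tuple(symbols[code]))
    return True, None


def write_covering_array(ca: CoveringArray, path) -> None:
    """Plain-text export: a 3-line header then one row of symbols per line."""
    with open(path, "w") as fh:
        fh.write("covering-array\n")
        fh.write(f"{ca.n_rows} {ca.strength} {ca.n_columns} {ca.alphabet_size}\n")
        fh.write(f"{ca.method}\n")
        for row in ca.matrix:
            fh.write(" ".join(str(int(s)) for s in row) + "\n")


def read_covering_array(path) -> CoveringArray:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != "covering-array":
            raise CoveringArrayError("not a covering-array file")
        n, t, k, v = (int(x) for x in fh.readline().split())
        method = fh.readline().strip()
        matrix = np.array(
            [[int(x) for x in fh.readline().split()] for _ in range(n)]
        )
    if matrix.shape != (n, k):
        raise CoveringArrayError("matrix shape does not match header")
    return CoveringArray(matrix=matrix, strength=t, alphabet_size=v, method=method)
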