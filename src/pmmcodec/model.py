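"""Alphabets, state spaces, transition counting and conditional laws.

An order-``o`` Markov chain over a finite alphabet ``A`` has state space
``S = A^o`` (states are the ``o``-tuples of past symbols).  The gapped
variant used for genomic sequences augments the state with the symbol at a
distant lag ``G > o``, so each state is a pair ``(x[t-G], x[t-o..t-1])``
and ``|S| = |A|^(o+1)``.

A Partition Markov Model (PMM) groups states into parts that share one
conditional law ``P(a | L)``; all counting here is done at state level and
aggregated to part level on demand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlphabetError,
    InvalidSpecError,
    MissingRowError,
    NoDataError,
    SampleTooShortError,
)

__all__ = [
    "Alphabet",
    "ModelSpec",
    "StateSpace",
    "CountTable",
    "Partition",
    "PMM",
    "enumerate_states",
    "count_transitions",
    "aggregate_counts",
    "transition_probs",
    "block_transition_probs",
    "DNA",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite alphabet; the given order defines lexical order everywhere."""

    symbols: tuple

    def __init__(self, symbols: Iterable):
        object.__setattr__(self, "symbols", tuple(symbols))
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError("alphabet symbols must be distinct")
        if len(self.symbols) < 1:
            raise AlphabetError("alphabet must contain at least one symbol")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise AlphabetError(f"symbol {symbol!r} not in alphabet") from None

    def __contains__(self, symbol) -> bool:
        return symbol in self._index

    def encode(self, sequence: Sequence) -> np.ndarray:
        """Map a sequence of symbols to their 0-based lexical positions."""
        idx = self._index
        out = np.empty(len(sequence), dtype=np.int64)
        for t, sym in enumerate(sequence):
            code = idx.get(sym)
            if code is None:
                raise AlphabetError(
                    f"symbol {sym!r} at position {t} not in alphabet"
                )
            out[t] = code
        return out

    def decode(self, codes: Iterable[int]):
        """Inverse of :meth:`encode`; returns a string when symbols are 1-char strings."""
        syms = [self.symbols[int(c)] for c in codes]
        if all(isinstance(s, str) and len(s) == 1 for s in self.symbols):
            return "".join(syms)
        return syms

    @property
    def position_width(self) -> int:
        """Bits needed to write a 1-based symbol position: floor(log2 m) + 1."""
        return self.size.bit_length()

    @property
    def symbol_width(self) -> int:
        """Bits per symbol of the uncompressed representation: floor(log2(m-1)) + 1."""
        if self.size < 2:
            return 1
        return (self.size - 1).bit_length()


DNA = Alphabet("acgt")


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration: memory order, optional interstice lag, block size.

    Parameters
    ----------
    order:
        Contiguous memory ``o >= 1``.
    gap:
        Optional interstice lag ``G > o``; when set, the symbol at lag ``G``
        is part of the state.
    block_size:
        Number of symbols coded per codeword (``b >= 1``).
    """

    order: int
    gap: int | None = None
    block_size: int = 1

    def __post_init__(self):
        if self.order < 1:
            raise InvalidSpecError(f"order must be >= 1, got {self.order}")
        if self.gap is not None and self.gap <= self.order:
            raise InvalidSpecError(
                f"gap G={self.gap} must exceed the order o={self.order}"
            )
        if self.block_size < 1:
            raise InvalidSpecError(f"block size must be >= 1, got {self.block_size}")

    @property
    def window(self) -> int:
        """Past symbols needed before the first codable position (G with gap, else o)."""
        return self.gap if self.gap is not None else self.order

    @property
    def state_length(self) -> int:
        return self.order + (1 if self.gap is not None else 0)

    def check_recommended_order(self, n: int, alphabet_size: int) -> bool:
        """Check o < floor(log_|A|(n)) - 1; warns (never raises) when violated."""
        bound = math.floor(math.log(n) / math.log(alphabet_size)) - 1
        ok = self.order < bound
        if not ok:
            warnings.warn(
                f"order o={self.order} is not below the recommended bound "
                f"floor(log_{alphabet_size}({n})) - 1 = {bound}; "
                "estimated frequencies may be unreliable",
                stacklevel=2,
            )
        return ok


class StateSpace:
    """All states in lexical order, indexable without materialising tuples."""

    def __init__(self, alphabet: Alphabet, spec: ModelSpec):
        self.alphabet = alphabet
        self.spec = spec
        self.n_states = alphabet.size ** spec.state_length

    def __len__(self) -> int:
        return self.n_states

    def state_tuple(self, index: int) -> tuple:
        """State at a lexical index.

        With a gap the first component is the lag-G symbol and the rest the
        contiguous o-tuple (lags o..1).
        """
        m = self.alphabet.size
        k = self.spec.state_length
        digits = []
        for _ in range(k):
            digits.append(index % m)
            index //= m
        digits.reverse()
        return tuple(self.alphabet.symbols[d] for d in digits)

    def label(self, index: int) -> str:
        tup = self.state_tuple(index)
        if all(isinstance(s, str) for s in tup):
            return "".join(tup)
        return str(tup)

    @property
    def states(self) -> list[tuple]:
        return [self.state_tuple(i) for i in range(self.n_states)]

    def index_of_tuple(self, state: tuple) -> int:
        if len(state) != self.spec.state_length:
            raise InvalidSpecError(
                f"state tuple of length {len(state)}; expected {self.spec.state_length}"
            )
        idx = 0
        for sym in state:
            idx = idx * self.alphabet.size + self.alphabet.index(sym)
        return idx


def enumerate_states(alphabet: Alphabet, spec: ModelSpec) -> StateSpace:
    """State space of the model in lexical order (|A|^o states, |A|^(o+1) with gap)."""
    return StateSpace(alphabet, spec)


def _state_indices(codes: np.ndarray, alphabet: Alphabet, spec: ModelSpec) -> np.ndarray:
    """Lexical state index for every position t in [window, n); vectorised."""
    m = alphabet.size
    o = spec.order
    n = len(codes)
    W = spec.window
    # contiguous part: tuple (x[t-o], ..., x[t-1])
    idx = np.zeros(n - W, dtype=np.int64)
    for k in range(o):  # lag o-k contributes digit k (most significant first)
        idx = idx * m + codes[W - o + k : n - o + k]
    if spec.gap is not None:
        gap_digit = codes[0 : n - W]  # symbol at lag G
        idx = gap_digit * (m**o) + idx
    return idx


@dataclass
class CountTable:
    """Transition counts N_n(s, a) over the full state space.

    ``counts[s, a]`` is the number of windows where state ``s`` is followed
    by symbol ``a``; rows for never-observed states are all zero.
    """

    counts: np.ndarray  # (|S|, |A|) int64
    n: int
    alphabet: Alphabet
    spec: ModelSpec

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.state_space = StateSpace(self.alphabet, self.spec)
        if self.counts.shape != (self.state_space.n_states, self.alphabet.size):
            raise InvalidSpecError(
                f"count table shape {self.counts.shape} does not match "
                f"({self.state_space.n_states}, {self.alphabet.size})"
            )

    @property
    def marginals(self) -> np.ndarray:
        """N_n(s) = sum_a N_n(s, a)."""
        return self.counts.sum(axis=1)

    @property
    def n_transitions(self) -> int:
        """Total windows counted: n - o (n - G with gap)."""
        return self.n - self.spec.window

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of states with N_n(s) > 0."""
        return self.marginals > 0

    def validate(self) -> None:
        if int(self.counts.sum()) != self.n_transitions:
            raise NoDataError(
                f"counts sum to {int(self.counts.sum())}, expected "
                f"{self.n_transitions}"
            )
        if (self.counts < 0).any():
            raise NoDataError("negative counts")


def count_transitions(sequence, alphabet: Alphabet, spec: ModelSpec) -> CountTable:
    """Count N_n(s, a) over all windows o < t <= n (G < t <= n with gap)."""
    codes = alphabet.encode(sequence)
    n = len(codes)
    if n <= spec.window:
        raise SampleTooShortError(
            f"sequence of length {n} too short for memory window {spec.window}"
        )
    space = StateSpace(alphabet, spec)
    sidx = _state_indices(codes, alphabet, spec)
    targets = codes[spec.window :]
    flat = np.bincount(
        sidx * alphabet.size + targets, minlength=space.n_states * alphabet.size
    )
    counts = flat.reshape(space.n_states, alphabet.size)
    table = CountTable(counts, n, alphabet, spec)
    table.validate()
    return table


@dataclass(frozen=True)
class Partition:
    """Disjoint cover of the state space, parts numbered by first appearance.

    ``parts[i]`` holds the (sorted) lexical state indices of part ``i``
    (0-based internally; the serialised index list is 1-based).
    """

    parts: tuple
    n_states: int

    def __init__(self, parts: Iterable[Iterable[int]], n_states: int):
        norm = tuple(tuple(sorted(int(s) for s in p)) for p in parts)
        object.__setattr__(self, "parts", norm)
        object.__setattr__(self, "n_states", int(n_states))
        index_of = np.full(n_states, -1, dtype=np.int64)
        for i, p in enumerate(norm):
            if not p:
                raise InvalidSpecError("empty part in partition")
            for s in p:
                if not (0 <= s < n_states):
                    raise InvalidSpecError(f"state index {s} out of range")
                if index_of[s] != -1:
                    raise InvalidSpecError(f"state {s} assigned to two parts")
                index_of[s] = i
        if (index_of == -1).any():
            missing = int(np.flatnonzero(index_of == -1)[0])
            raise InvalidSpecError(f"state {missing} not covered by the partition")
        index_of.setflags(write=False)
        object.__setattr__(self, "index_of", index_of)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def indices(self) -> list[int]:
        """1-based part index per state in lexical order (the serialised list)."""
        return [int(i) + 1 for i in self.index_of]

    @property
    def sizes(self) -> list[int]:
        return [len(p) for p in self.parts]

    def canonicalize(self) -> "Partition":
        """Renumber parts by first appearance when scanning states lexically."""
        seen: dict[int, int] = {}
        for s in range(self.n_states):
            i = int(self.index_of[s])
            if i not in seen:
                seen[i] = len(seen)
        order = sorted(seen, key=seen.get)
        return Partition([self.parts[i] for i in order], self.n_states)

    def is_canonical(self) -> bool:
        first = [min(p) for p in self.parts]
        return first == sorted(first)

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        """Build from an arbitrary per-state label array; renumbers canonically."""
        groups: dict[int, list[int]] = {}
        for s, lab in enumerate(labels):
            groups.setdefault(lab, []).append(s)
        part = cls(list(groups.values()), len(labels))
        return part.canonicalize()

    @classmethod
    def singletons(cls, n_states: int) -> "Partition":
        return cls([[s] for s in range(n_states)], n_states)

    @classmethod
    def one_part(cls, n_states: int) -> "Partition":
        return cls([list(range(n_states))], n_states)

    @classmethod
    def from_state_tuples(
        cls, parts: Iterable[Iterable[tuple]], space: StateSpace
    ) -> "Partition":
        idx_parts = [
            [space.index_of_tuple(tuple(st)) for st in p] for p in parts
        ]
        return cls(idx_parts, space.n_states)


def aggregate_counts(table: CountTable, partition: Partition) -> np.ndarray:
    """Part-level counts N_n(L, a) = sum_{s in L} N_n(s, a); shape (|L|, |A|)."""
    if partition.n_states != table.state_space.n_states:
        raise InvalidSpecError(
            f"partition over {partition.n_states} states does not match the "
            f"{table.state_space.n_states}-state count table"
        )
    out = np.zeros((partition.n_parts, table.alphabet.size), dtype=np.int64)
    np.add.at(out, partition.index_of, table.counts)
    return out


def transition_probs(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalise counts into conditional laws.

    Returns ``(probs, observed)``: rows with zero marginal are flagged
    ``observed=False`` and left as NaN rather than estimated.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 1:
        counts = counts[None, :]
    marg = counts.sum(axis=1)
    if not (marg > 0).any():
        raise NoDataError("all rows have zero counts; nothing to estimate")
    observed = marg > 0
    probs = np.full_like(counts, np.nan)
    probs[observed] = counts[observed] / marg[observed, None]
    return probs, observed


def next_state_index(state: int, symbol: int, order: int, m: int) -> int:
    """Successor state of a contiguous order-o chain after emitting ``symbol``."""
    return (state % (m ** (order - 1))) * m + symbol if order > 1 else symbol


def block_transition_probs(
    state_rows: np.ndarray,
    spec: ModelSpec,
    alphabet: Alphabet,
    state: int,
    b: int,
) -> np.ndarray:
    """Distribution over the |A|^b blocks following ``state``, lexical order.

    ``P(x_1^b | s)`` is the product of one-step conditionals along the block,
    with the state advanced one symbol at a time.  Only contiguous (non-gap)
    models admit block conditionals for b > 1, because with an interstice the
    intermediate states depend on symbols outside the current state tuple.
    """
    if b < 1:
        raise InvalidSpecError("block size must be >= 1")
    if spec.gap is not None and b > 1:
        raise InvalidSpecError("block coding with b > 1 requires a contiguous model")
    m = alphabet.size
    rows = np.asarray(state_rows)
    if rows.shape != (alphabet.size ** spec.state_length, m):
        raise InvalidSpecError("state_rows shape does not match the state space")
    if np.isnan(rows[state]).any():
        raise MissingRowError(f"no conditional row for the context state {state}")
    cur = np.array([state], dtype=np.int64)
    probs = np.ones(1)
    o = spec.order
    mo1 = m ** (o - 1)
    for _ in range(b):
        # undefined rows (never-observed states) are dead-ends: blocks
        # through them get probability 0.  A block actually occurring in the
        # counted sample only traverses observed contexts, so nothing
        # codable is ever dropped, and both codec sides agree.
        step = np.nan_to_num(rows[cur])  # (k, m)
        probs = (probs[:, None] * step).reshape(-1)
        if spec.gap is None:
            cur = ((cur % mo1)[:, None] * m + np.arange(m)[None, :]).reshape(-1)
        else:  # b == 1; successor never used
            cur = np.repeat(cur, m)
    return probs


@dataclass
class PMM:
    """Partition Markov Model: one conditional law per part, plus part weights."""

    alphabet: Alphabet
    spec: ModelSpec
    partition: Partition
    cond_probs: np.ndarray  # (|L|, |A|)
    part_weights: np.ndarray | None = None

    _TOL = 1e-12

    def __post_init__(self):
        self.cond_probs = np.asarray(self.cond_probs, dtype=np.float64)
        space = StateSpace(self.alphabet, self.spec)
        if self.partition.n_states != space.n_states:
            raise InvalidSpecError("partition does not cover the state space")
        if self.cond_probs.shape != (self.partition.n_parts, self.alphabet.size):
            raise InvalidSpecError("cond_probs shape does not match (|L|, |A|)")
        rows = self.cond_probs.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-9:
            raise InvalidSpecError("conditional rows must sum to 1")
        if self.part_weights is not None:
            self.part_weights = np.asarray(self.part_weights, dtype=np.float64)
            if self.part_weights.shape != (self.partition.n_parts,):
                raise InvalidSpecError("part_weights shape does not match |L|")
            if abs(self.part_weights.sum() - 1.0) > 1e-9:
                raise InvalidSpecError("part weights must sum to 1")

    @property
    def state_rows(self) -> np.ndarray:
        """Per-state conditional rows (each state inherits its part's law)."""
        return self.cond_probs[self.partition.index_of]

    def is_minimal(self, tol: float = 1e-12) -> bool:
        """True when all parts carry pairwise distinct conditional laws."""
        k = self.partition.n_parts
        for i in range(k):
            for j in range(i + 1, k):
                if np.max(np.abs(self.cond_probs[i] - self.cond_probs[j])) <= tol:
                    return False
        return True
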