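"""Huffman codelengths, canonical codebooks and codelength descriptions.

The canonical Huffman code (CHC) is fully determined by the codeword
lengths: symbols are arranged by nonincreasing probability, the first
codeword is ``l_1`` zeros, and each subsequent codeword is the previous one
plus one in binary, zero-padded on the right whenever the length grows.
Because of that, a decoder only ever needs the length sequence, never the
tree.

Tie handling is deterministic: the two-minimum selection of the merge loop
prefers the group whose lexically smallest member comes first, and merged
groups inherit that smallest member.  When probabilities tie, the canonical
arrangement orders the tied symbols by their Huffman length and then by
lexical position, which keeps the length sequence nondecreasing.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import (
    IncrementOverflowError,
    InvalidLengthsError,
    NoSupportError,
)

__all__ = [
    "CodeLengths",
    "Codebook",
    "ConditionalCodebooks",
    "huffman_codelengths",
    "canonical_codebook",
    "conditional_codebooks",
    "codelength_description",
    "parse_codelength_description",
]


@dataclass(frozen=True)
class CodeLengths:
    """Codeword lengths in canonical symbol order (nonincreasing probability)."""

    symbols: tuple
    lengths: tuple

    def __post_init__(self):
        if len(self.symbols) != len(self.lengths):
            raise InvalidLengthsError("symbols and lengths differ in length")
        if any(l < 1 for l in self.lengths):
            raise InvalidLengthsError("codeword lengths must be positive")
        if any(
            self.lengths[i] > self.lengths[i + 1]
            for i in range(len(self.lengths) - 1)
        ):
            raise InvalidLengthsError("lengths must be nondecreasing")
        if self.kraft_sum > 1 + 1e-12:
            raise InvalidLengthsError(
                f"Kraft sum {self.kraft_sum} exceeds 1; not a prefix code"
            )

    @property
    def kraft_sum(self) -> float:
        return math.fsum(2.0 ** -l for l in self.lengths)

    @property
    def increments(self) -> tuple:
        """l_1 - 0, l_2 - l_1, ...: one increment per symbol."""
        prev = 0
        out = []
        for l in self.lengths:
            out.append(l - prev)
            prev = l
        return tuple(out)

    def expected_length(self, probs: Mapping) -> float:
        return math.fsum(probs[s] * l for s, l in zip(self.symbols, self.lengths))


def huffman_codelengths(weights: Sequence, symbols: Sequence | None = None) -> CodeLengths:
    """Optimal prefix-code lengths for the given weights (binary merges).

    Zero-weight symbols are dropped before construction; a single positive
    symbol receives length 1 (the one-codeword code "0").  Ties in the
    two-minimum selection are resolved toward the group with the lexically
    earliest member, so exact-arithmetic weights reproduce the worked
    examples' assignments.
    """
    if symbols is None:
        symbols = list(range(len(weights)))
    if len(symbols) != len(weights):
        raise NoSupportError("weights and symbols differ in length")
    support = [(i, s, w) for i, (s, w) in enumerate(zip(symbols, weights)) if w > 0]
    if not support:
        raise NoSupportError("all weights are zero")
    if len(support) == 1:
        return CodeLengths((support[0][1],), (1,))

    # heap entries: (weight, lexical rank of smallest member, node id)
    heap = [(w, i, nid) for nid, (i, _s, w) in enumerate(support)]
    heapq.heapify(heap)
    children: dict[int, tuple[int, int]] = {}
    next_id = len(support)
    while len(heap) > 1:
        w1, r1, n1 = heapq.heappop(heap)
        w2, r2, n2 = heapq.heappop(heap)
        children[next_id] = (n1, n2)
        heapq.heappush(heap, (w1 + w2, min(r1, r2), next_id))
        next_id += 1

    depths = [0] * len(support)
    stack = [(heap[0][2], 0)]
    while stack:
        node, d = stack.pop()
        kids = children.get(node)
        if kids is None:
            depths[node] = d
        else:
            stack.append((kids[0], d + 1))
            stack.append((kids[1], d + 1))

    # canonical arrangement: probability desc, then Huffman length asc, then
    # lexical position asc.  The sorted length multiset is assigned along
    # that order: with exact weights it coincides with each symbol's own
    # depth (optimal codes are monotone), and under float rounding of the
    # merged sums it repairs epsilon-level inversions without changing the
    # multiset.
    order = sorted(
        range(len(support)), key=lambda k: (depths[k], support[k][0])
    )
    order.sort(key=lambda k: support[k][2], reverse=True)
    syms = tuple(support[k][1] for k in order)
    return CodeLengths(syms, tuple(sorted(depths)))


@dataclass(frozen=True)
class Codebook:
    """Prefix code: symbol -> bit string, with its canonical length sequence."""

    codewords: dict
    code_lengths: CodeLengths
    canonical: bool = True

    def __getitem__(self, symbol) -> str:
        return self.codewords[symbol]

    def __len__(self) -> int:
        return len(self.codewords)

    def decoder_map(self) -> dict:
        return {bits: sym for sym, bits in self.codewords.items()}

    def is_prefix_free(self) -> bool:
        words = sorted(self.codewords.values())
        return not any(
            words[i + 1].startswith(words[i]) for i in range(len(words) - 1)
        )

    def expected_length(self, probs: Mapping) -> float:
        return math.fsum(
            probs[s] * len(bits) for s, bits in self.codewords.items()
        )


def canonical_codebook(code_lengths: CodeLengths) -> Codebook:
    """Canonical Huffman codewords from a nondecreasing length sequence.

    The first codeword is ``l_1`` zeros; each next one is the previous plus
    one in binary, left-shifted (right zero-padded) when the length grows.
    """
    lengths = code_lengths.lengths
    codewords: dict = {}
    code = 0
    prev_len = lengths[0]
    for k, (sym, l) in enumerate(zip(code_lengths.symbols, lengths)):
        if k > 0:
            code = (code + 1) << (l - prev_len)
            prev_len = l
        if code >= (1 << l):
            raise InvalidLengthsError("length sequence overflows the code space")
        codewords[sym] = format(code, f"0{l}b")
    return Codebook(codewords, code_lengths, canonical=True)


def codebook_from_weights(weights: Sequence, symbols: Sequence | None = None) -> Codebook:
    """Convenience: canonical codebook straight from weights."""
    return canonical_codebook(huffman_codelengths(weights, symbols))


@dataclass
class ConditionalCodebooks:
    """One canonical codebook per conditioning context.

    ``books`` maps a context key (state index, or part index) to a codebook
    over block ids ``0 .. |A|^b - 1`` (lexical block order); contexts with no
    support carry no codebook.
    """

    books: dict
    granularity: str  # "by States" | "by Parts"
    block_size: int


def conditional_codebooks(
    rows, contexts: Iterable | None = None, block_size: int = 1, granularity: str = "by States"
) -> ConditionalCodebooks:
    """Canonical codebooks built per context from probability (or count) rows.

    ``rows`` maps context -> weight vector over the b-blocks in lexical
    order (anything indexable: dict of sequences or a 2-D array).  Symbols of
    each codebook are the positions (block ids) with positive weight.
    """
    if contexts is None:
        contexts = range(len(rows))
    books = {}
    for ctx in contexts:
        books[ctx] = codebook_from_weights(list(rows[ctx]))
    if not books:
        raise NoSupportError("no contexts given")
    return ConditionalCodebooks(books, granularity, block_size)


def codelength_description(code_lengths: CodeLengths, mode: str = "paper") -> str:
    """Bit field describing a canonical code by its length increments.

    ``paper`` mode spends exactly one bit per symbol: the first bit is the
    first codelength's increment from zero and each later bit the increment
    to the next length.  It can only represent increments of 0 or 1 (which
    holds in all the worked examples); ``escape`` mode writes every
    increment in unary (k ones then a zero) and handles any code.
    """
    incs = code_lengths.increments
    if mode == "paper":
        if any(d not in (0, 1) for d in incs):
            raise IncrementOverflowError(
                f"increments {incs} not representable with one bit each; "
                "use escape mode"
            )
        return "".join(str(d) for d in incs)
    if mode == "escape":
        return "".join("1" * d + "0" for d in incs)
    raise ValueError(f"unknown codelength description mode {mode!r}")


def parse_codelength_description(
    bits: str, n_symbols: int, mode: str = "paper", offset: int = 0
) -> tuple[tuple, int]:
    """Inverse of :func:`codelength_description`.

    Returns ``(lengths, new_offset)`` where ``lengths`` is the nondecreasing
    length sequence of ``n_symbols`` codewords read starting at ``offset``.
    """
    lengths = []
    cur = 0
    pos = offset
    for _ in range(n_symbols):
        if mode == "paper":
            if pos >= len(bits):
                raise InvalidLengthsError("bit field exhausted mid-description")
            cur += int(bits[pos])
            pos += 1
        elif mode == "escape":
            d = 0
            while pos < len(bits) and bits[pos] == "1":
                d += 1
                pos += 1
            if pos >= len(bits):
                raise InvalidLengthsError("bit field exhausted mid-description")
            pos += 1  # terminating zero
            cur += d
        else:
            raise ValueError(f"unknown codelength description mode {mode!r}")
        if cur < 1:
            raise InvalidLengthsError("first codelength must be at least 1")
        lengths.append(cur)
    return tuple(lengths), pos
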