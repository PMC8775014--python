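"""Small worked reference fixtures used across the documentation and tests.

Three self-contained examples exercise every serialization path without any
external data:

* a three-letter order-1 chain with printed transition probabilities and
  the 8-symbol message ``caabacba`` (conditional coding example);
* a five-symbol distribution whose Huffman and canonical Huffman codes are
  tabulated (codebook example);
* a binary order-3 chain with a three-part state partition and its
  transition counts from a length-393 message (model-serialization
  example).

Probabilities are stored as exact fractions so tie decisions in the merge
loop match the tabulated codes digit for digit.
"""

from __future__ import annotations

from fractions import Fraction as F

import numpy as np

from .model import Alphabet, CountTable, ModelSpec, Partition, StateSpace

__all__ = [
    "ABC",
    "BINARY",
    "MESSAGE",
    "MESSAGE_SPEC",
    "conditional_probs_abc",
    "five_symbol_probs",
    "three_part_partition",
    "binary_order3_counts",
]

ABC = Alphabet("abc")
BINARY = Alphabet("01")

#: order-1 message over {a, b, c} used in the conditional-coding example
MESSAGE = "caabacba"
MESSAGE_SPEC = ModelSpec(order=1, block_size=1)


def conditional_probs_abc() -> np.ndarray:
    """Order-1 transition law over {a,b,c} (rows: from-state a, b, c)."""
    return np.array(
        [
            [F(1, 6), F(2, 6), F(3, 6)],
            [F(1, 3), F(1, 3), F(1, 3)],
            [F(2, 7), F(1, 7), F(4, 7)],
        ],
        dtype=object,
    )


def five_symbol_probs() -> dict:
    """Five-symbol distribution of the codebook example (lengths 1,2,3,4,4)."""
    return {
        "a": F(1, 11),
        "b": F(4, 11),
        "c": F(3, 11),
        "d": F(2, 11),
        "e": F(1, 11),
    }


def three_part_partition() -> Partition:
    """Three-part partition of the 8 binary order-3 states.

    L1 = {000, 011, 100, 111}, L2 = {001, 010, 101}, L3 = {110}; the index
    list over the lexically ordered states is 1 2 2 1 1 2 3 1.
    """
    space = StateSpace(BINARY, ModelSpec(order=3))
    parts = [
        [("0", "0", "0"), ("0", "1", "1"), ("1", "0", "0"), ("1", "1", "1")],
        [("0", "0", "1"), ("0", "1", "0"), ("1", "0", "1")],
        [("1", "1", "0")],
    ]
    return Partition.from_state_tuples(parts, space)


def binary_order3_counts() -> CountTable:
    """State-level transition counts of the binary order-3 chain, n = 393.

    Rows follow the lexical state order 000..111; columns are the counts of
    the state followed by 0 and by 1.
    """
    counts = np.array(
        [
            [30, 20],
            [24, 25],
            [26, 25],
            [31, 20],
            [29, 20],
            [25, 25],
            [10, 30],
            [30, 20],
        ],
        dtype=np.int64,
    )
    return CountTable(counts, n=393, alphabet=BINARY, spec=ModelSpec(order=3))
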