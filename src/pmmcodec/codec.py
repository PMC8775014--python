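"""Bit-level serialization: model header, coded data, and containers.

A compressed message has two halves: a description of the model used to
code the data, and the coded data itself.  Two serialization modes exist:

* ``by States`` — the model is the full order-o chain; the header carries
  the order and every state-level transition count at a fixed width of
  ``floor(log2 n) + 1`` bits per count.
* ``by Parts`` — the model is a Partition Markov Model; the header carries
  the order, the per-state part-index list coded with a canonical Huffman
  code built from the part sizes, the codelength description of that index
  code, and the part-level counts.

Two accounting modes exist.  ``paper`` reproduces the worked-example
tallies: only order (plus gap), partition fields and frequencies are
emitted for the model.  ``self_contained`` additionally prepends the sample
length ``n`` (32 bits), the block size ``b`` (8 bits), a 3-bit flags field
(mode, gap present, codelength-description mode) and the part count, so the
container decodes with no side information beyond the alphabet.

All fixed-width integers are big-endian.  Codewords are bit strings, never
padded.  Decoding is streaming: every codeword resolves as soon as its last
bit arrives (prefix property).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ContainerFormatError,
    IncrementOverflowError,
    InvalidSpecError,
)
from .huffman import (
    CodeLengths,
    Codebook,
    canonical_codebook,
    codelength_description,
    huffman_codelengths,
    parse_codelength_description,
)
from .model import (
    Alphabet,
    CountTable,
    ModelSpec,
    Partition,
    StateSpace,
    aggregate_counts,
    block_transition_probs,
    count_transitions,
    transition_probs,
)

__all__ = [
    "BitField",
    "CompressedContainer",
    "ParsedContainer",
    "frequency_width",
    "order_width",
    "order_field",
    "gap_fields",
    "partition_index_field",
    "frequency_field",
    "initial_symbols_field",
    "encode_data",
    "decode_data",
    "compress",
    "model_description_fields",
    "assemble_container",
    "parse_container",
    "decompress",
    "bit_accounting",
    "write_pmz",
    "read_pmz",
    "compress_to_file",
    "decompress_file",
]

N_WIDTH = 32  # self-contained sample-length field
B_WIDTH = 8  # self-contained block-size field
GAP_ORDER_WIDTH = 4  # order width when an interstice is present
GAP_WIDTH = 8  # interstice lag width

_DATA_FIELD_NAMES = frozenset({"initial_symbols", "data"})


def _to_bits(value: int, width: int) -> str:
    if value < 0 or value >= (1 << width):
        raise InvalidSpecError(f"value {value} does not fit in {width} bits")
    return format(value, f"0{width}b")


class BitReader:
    """Cursor over a 0/1 string; raises on exhaustion mid-read."""

    def __init__(self, bits: str, pos: int = 0):
        self.bits = bits
        self.pos = pos

    @property
    def remaining(self) -> int:
        return len(self.bits) - self.pos

    def read(self, k: int) -> str:
        if self.remaining < k:
            raise ContainerFormatError(
                f"bit stream exhausted: needed {k} bits, {self.remaining} left"
            )
        out = self.bits[self.pos : self.pos + k]
        self.pos += k
        return out

    def read_int(self, k: int) -> int:
        return int(self.read(k), 2)

    def read_codeword(self, decoder: dict, max_len: int):
        """Read one prefix codeword and return its symbol."""
        word = ""
        while len(word) <= max_len:
            if self.remaining == 0:
                raise ContainerFormatError("bit stream exhausted mid-codeword")
            word += self.read(1)
            sym = decoder.get(word)
            if sym is not None:
                return sym
        raise ContainerFormatError(f"unresolvable codeword prefix {word!r}")


@dataclass(frozen=True)
class BitField:
    name: str
    bits: str

    @property
    def width(self) -> int:
        return len(self.bits)


def frequency_width(n: int) -> int:
    """Fixed width for transmitted counts: floor(log2 n) + 1 bits."""
    if n < 1:
        raise InvalidSpecError(f"frequency width undefined for n={n}")
    return n.bit_length()


def order_width(n: int, alphabet_size: int) -> int:
    """Width reserved for the order: floor(log2(log_|A|(n) - 1)) + 1 bits."""
    x = math.log(n) / math.log(alphabet_size) - 1.0
    if x < 1.0:
        raise InvalidSpecError(
            f"sample length n={n} too small to encode any order over a "
            f"{alphabet_size}-symbol alphabet"
        )
    return math.floor(math.log2(x)) + 1


def order_field(o: int, n: int, alphabet_size: int, allow_widen: bool = False) -> BitField:
    """Order at the width mandated by the header protocol.

    An order violating the recommended bound ``o < floor(log_|A|(n)) - 1``
    may not fit the width; ``allow_widen`` pads the field to ``o`` instead
    (only legitimate for paper accounting, where nothing is re-parsed — a
    self-contained decoder must be able to infer the width from n alone).
    """
    w = order_width(n, alphabet_size)
    if o >= (1 << w):
        if not allow_widen:
            raise InvalidSpecError(
                f"order o={o} does not fit in {w} bits; the recommended bound is "
                f"o < floor(log_{alphabet_size}({n})) - 1"
            )
        w = o.bit_length()
    return BitField("order", _to_bits(o, w))


def gap_fields(o: int, gap: int) -> list[BitField]:
    """Gapped models reserve 4 bits for the order and 8 for the interstice lag."""
    return [
        BitField("order", _to_bits(o, GAP_ORDER_WIDTH)),
        BitField("gap", _to_bits(gap, GAP_WIDTH)),
    ]


def index_codebook(partition: Partition) -> Codebook:
    """Canonical Huffman code for part indices, weighted by part sizes |L_i|/|S|."""
    sizes = partition.sizes
    return canonical_codebook(
        huffman_codelengths(sizes, symbols=list(range(1, len(sizes) + 1)))
    )


def partition_index_field(partition: Partition) -> tuple[list[int], BitField, Codebook]:
    """Per-state part indices in lexical state order, Huffman coded.

    Returns the 1-based index list, the concatenated bit field, and the
    index codebook used.
    """
    if partition.n_parts < 1:
        raise InvalidSpecError("empty partition")
    book = index_codebook(partition)
    indices = partition.indices
    bits = "".join(book[i] for i in indices)
    return indices, BitField("partition_index", bits), book


def frequency_field(counts: np.ndarray, n: int) -> BitField:
    """All counts at fixed width, context-major then alphabet order."""
    counts = np.asarray(counts, dtype=np.int64)
    w = frequency_width(n)
    if (counts > n).any():
        raise InvalidSpecError("a transition count exceeds the sample length")
    bits = "".join(_to_bits(int(c), w) for c in counts.reshape(-1))
    return BitField("frequencies", bits)


def initial_symbols_field(symbols, alphabet: Alphabet) -> BitField:
    """First symbols written as 1-based lexical positions, fixed width."""
    w = alphabet.position_width
    bits = "".join(_to_bits(alphabet.index(s) + 1, w) for s in symbols)
    return BitField("initial_symbols", bits)


def _state_at(codes, pos: int, spec: ModelSpec, m: int) -> int:
    idx = 0
    for k in range(spec.order):
        idx = idx * m + int(codes[pos - spec.order + k])
    if spec.gap is not None:
        idx += int(codes[pos - spec.gap]) * (m**spec.order)
    return idx


class BlockCoder:
    """Lazy per-state canonical block codebooks from conditional rows.

    Both the encoder and the decoder construct the rows from the same
    transmitted integer counts, so the codebooks agree bit-for-bit.
    """

    def __init__(self, state_rows: np.ndarray, spec: ModelSpec, alphabet: Alphabet):
        self.state_rows = np.asarray(state_rows, dtype=np.float64)
        self.spec = spec
        self.alphabet = alphabet
        self._books: dict[tuple[int, int], Codebook] = {}

    def book(self, state: int, block_len: int) -> Codebook:
        key = (state, block_len)
        cached = self._books.get(key)
        if cached is None:
            weights = block_transition_probs(
                self.state_rows, self.spec, self.alphabet, state, block_len
            )
            cached = canonical_codebook(huffman_codelengths(weights))
            self._books[key] = cached
        return cached


def encode_data(codes: np.ndarray, coder: BlockCoder, spec: ModelSpec) -> BitField:
    """Code everything after the initial window in b-blocks.

    A trailing remainder of fewer than ``b`` symbols is coded symbol by
    symbol with the b=1 codebooks derived from the same rows.
    """
    m = coder.alphabet.size
    b = spec.block_size
    n = len(codes)
    pos = spec.window
    parts: list[str] = []
    while pos < n:
        blen = b if n - pos >= b else 1
        state = _state_at(codes, pos, spec, m)
        block_id = 0
        for k in range(blen):
            block_id = block_id * m + int(codes[pos + k])
        parts.append(coder.book(state, blen)[block_id])
        pos += blen
    return BitField("data", "".join(parts))


def decode_data(
    reader: BitReader,
    initial_codes,
    n: int,
    coder: BlockCoder,
    spec: ModelSpec,
) -> np.ndarray:
    """Exact inverse of :func:`encode_data` (streaming prefix decoding)."""
    m = coder.alphabet.size
    b = spec.block_size
    codes = list(int(c) for c in initial_codes)
    pos = spec.window
    while pos < n:
        blen = b if n - pos >= b else 1
        state = _state_at(codes, pos, spec, m)
        book = coder.book(state, blen)
        decoder = book.decoder_map()
        max_len = max(book.code_lengths.lengths)
        block_id = reader.read_codeword(decoder, max_len)
        digits = []
        for _ in range(blen):
            digits.append(block_id % m)
            block_id //= m
        codes.extend(reversed(digits))
        pos += blen
    return np.asarray(codes, dtype=np.int64)


@dataclass
class CompressedContainer:
    """Ordered bit fields plus totals and the compression ratio.

    ``model_bits`` counts every non-data field; ``data_bits`` counts the
    initial symbols and the coded data.  The uncompressed reference size is
    ``n * (floor(log2(|A| - 1)) + 1)`` bits.
    """

    mode: str  # "states" | "parts"
    accounting_mode: str  # "paper" | "self_contained"
    fields: list
    alphabet: Alphabet
    spec: ModelSpec
    n: int

    @property
    def bits(self) -> str:
        return "".join(f.bits for f in self.fields)

    @property
    def total_bits(self) -> int:
        return sum(f.width for f in self.fields)

    @property
    def model_bits(self) -> int:
        return sum(f.width for f in self.fields if f.name not in _DATA_FIELD_NAMES)

    @property
    def data_bits(self) -> int:
        return sum(f.width for f in self.fields if f.name in _DATA_FIELD_NAMES)

    @property
    def uncompressed_bits(self) -> int:
        return self.n * self.alphabet.symbol_width

    @property
    def compression_ratio(self) -> float:
        return self.uncompressed_bits / self.total_bits

    def field_width(self, name: str) -> int:
        return sum(f.width for f in self.fields if f.name == name)

    def get_field(self, name: str) -> BitField:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def breakdown(self) -> dict:
        out: dict[str, int] = {}
        for f in self.fields:
            out[f.name] = out.get(f.name, 0) + f.width
        return out

    def dump(self) -> str:
        lines = [f"mode={self.mode} accounting={self.accounting_mode} n={self.n}"]
        for f in self.fields:
            lines.append(f"{f.name:<16} {f.width:>8}  {f.bits}")
        lines.append(
            f"model_bits={self.model_bits} data_bits={self.data_bits} "
            f"total_bits={self.total_bits} Rc={self.compression_ratio:.4f}"
        )
        return "\n".join(lines)


def _coding_rows(
    table: CountTable, mode: str, partition: Partition | None
) -> tuple[np.ndarray, Partition | None, np.ndarray | None]:
    """Per-state conditional rows used for coding, under either mode."""
    if mode == "states":
        probs, _obs = transition_probs(table.counts)
        return probs, None, None
    if mode == "parts":
        if partition is None:
            from .estimation import estimate_partition

            partition = estimate_partition(table)
        part_counts = aggregate_counts(table, partition)
        probs, obs = transition_probs(part_counts)
        if not np.asarray(obs).all():
            probs[~np.asarray(obs)] = np.nan
        return probs[partition.index_of], partition, part_counts
    raise InvalidSpecError(f"unknown mode {mode!r}")


def compress(
    sequence,
    alphabet: Alphabet,
    spec: ModelSpec,
    mode: str = "parts",
    accounting: str = "self_contained",
    partition: Partition | None = None,
) -> CompressedContainer:
    """Fit (or accept) a model and assemble the full container for a sequence."""
    table = count_transitions(sequence, alphabet, spec)
    return assemble_container(
        sequence, table, mode=mode, accounting=accounting, partition=partition
    )


def model_description_fields(
    table: CountTable,
    mode: str = "parts",
    accounting: str = "paper",
    partition: Partition | None = None,
) -> list[BitField]:
    """The model half of the container, as an ordered field list.

    Paper accounting emits order (or order+gap), then for by-Parts the coded
    part-index list, the codelength description of the index code and the
    part-level frequencies — for by-States just the state-level frequencies.
    Self-contained accounting prepends n, block size, flags and the part
    count, and moves the codelength description ahead of the index list
    (the decoder needs the index codebook before it can read an index).
    """
    if accounting not in ("paper", "self_contained"):
        raise InvalidSpecError(f"unknown accounting mode {accounting!r}")
    alphabet, spec, n = table.alphabet, table.spec, table.n
    m = alphabet.size

    _rows, partition, part_counts = _coding_rows(table, mode, partition)
    desc_escape = False
    if mode == "parts":
        assert partition is not None and part_counts is not None
        _indices, idx_field, book = partition_index_field(partition)
        try:
            desc_bits = codelength_description(book.code_lengths, mode="paper")
        except IncrementOverflowError:
            desc_bits = codelength_description(book.code_lengths, mode="escape")
            desc_escape = True
        desc_field = BitField("codelength_desc", desc_bits)
        freq = frequency_field(part_counts, n)
        if accounting == "self_contained":
            part_fields = [desc_field, idx_field, freq]
        else:
            part_fields = [idx_field, desc_field, freq]
    else:
        part_fields = [frequency_field(table.counts, n)]

    fields: list[BitField] = []
    if accounting == "self_contained":
        fields.append(BitField("length_n", _to_bits(n, N_WIDTH)))
        fields.append(BitField("block_size", _to_bits(spec.block_size, B_WIDTH)))
        flags = (
            ("1" if mode == "parts" else "0")
            + ("1" if spec.gap is not None else "0")
            + ("1" if desc_escape else "0")
        )
        fields.append(BitField("flags", flags))
    if spec.gap is not None:
        fields.extend(gap_fields(spec.order, spec.gap))
    else:
        fields.append(order_field(spec.order, n, m, allow_widen=accounting == "paper"))
    if accounting == "self_contained" and mode == "parts":
        assert partition is not None
        pw = (table.state_space.n_states).bit_length()
        fields.append(BitField("part_count", _to_bits(partition.n_parts, pw)))
    fields.extend(part_fields)
    return fields


def assemble_container(
    sequence,
    table: CountTable,
    mode: str = "parts",
    accounting: str = "self_contained",
    partition: Partition | None = None,
) -> CompressedContainer:
    """Serialise a fitted model and the coded data into an ordered field list."""
    alphabet, spec, n = table.alphabet, table.spec, table.n
    codes = alphabet.encode(sequence)
    if len(codes) != n:
        raise InvalidSpecError("sequence length does not match the count table")

    state_rows, partition, _part_counts = _coding_rows(table, mode, partition)
    fields = model_description_fields(table, mode, accounting, partition)

    coder = BlockCoder(state_rows, spec, alphabet)
    fields.append(initial_symbols_field(sequence[: spec.window], alphabet))
    fields.append(encode_data(codes, coder, spec))

    return CompressedContainer(mode, accounting, fields, alphabet, spec, n)


@dataclass
class ParsedContainer:
    """Model information recovered while decoding a self-contained container."""

    mode: str
    spec: ModelSpec
    n: int
    partition: Partition | None
    counts: np.ndarray  # state-level or part-level, as transmitted
    sequence: object


def parse_container(bits: str, alphabet: Alphabet) -> ParsedContainer:
    """Full inverse of a self-contained :func:`assemble_container`."""
    m = alphabet.size
    reader = BitReader(bits)
    n = reader.read_int(N_WIDTH)
    if n < 1:
        raise ContainerFormatError("declared sample length < 1")
    b = reader.read_int(B_WIDTH)
    if b < 1:
        raise ContainerFormatError("declared block size < 1")
    flags = reader.read(3)
    mode = "parts" if flags[0] == "1" else "states"
    gapped = flags[1] == "1"
    desc_mode = "escape" if flags[2] == "1" else "paper"
    if gapped:
        o = reader.read_int(GAP_ORDER_WIDTH)
        gap = reader.read_int(GAP_WIDTH)
        spec = ModelSpec(order=o, gap=gap, block_size=b)
    else:
        o = reader.read_int(order_width(n, m))
        if o < 1:
            raise ContainerFormatError("declared order < 1")
        spec = ModelSpec(order=o, block_size=b)
    if n <= spec.window:
        raise ContainerFormatError("sample length inside the memory window")
    space = StateSpace(alphabet, spec)
    S = space.n_states
    w = frequency_width(n)

    partition: Partition | None = None
    if mode == "parts":
        n_parts = reader.read_int(S.bit_length())
        if not (1 <= n_parts <= S):
            raise ContainerFormatError(f"part count {n_parts} out of range")
        lengths, reader.pos = parse_codelength_description(
            bits, n_parts, mode=desc_mode, offset=reader.pos
        )
        book = canonical_codebook(CodeLengths(tuple(range(n_parts)), lengths))
        decoder = book.decoder_map()
        max_len = max(lengths)
        ranks = [reader.read_codeword(decoder, max_len) for _ in range(S)]
        # parts are numbered by first appearance over the lexical state scan,
        # so relabelling the decoded ranks the same way recovers the exact map
        partition = Partition.from_labels(ranks)
        if partition.n_parts != n_parts:
            raise ContainerFormatError(
                "partition index list uses fewer parts than declared"
            )
        counts = np.array(
            [[reader.read_int(w) for _ in range(m)] for _ in range(n_parts)],
            dtype=np.int64,
        )
        probs, obs = transition_probs(counts)
        if not np.asarray(obs).all():
            probs[~np.asarray(obs)] = np.nan
        state_rows = probs[partition.index_of]
    else:
        counts = np.array(
            [[reader.read_int(w) for _ in range(m)] for _ in range(S)],
            dtype=np.int64,
        )
        probs, _obs = transition_probs(counts)
        state_rows = probs
    if int(counts.sum()) != n - spec.window:
        raise ContainerFormatError(
            f"transmitted counts sum to {int(counts.sum())}, "
            f"expected {n - spec.window}"
        )

    pw = alphabet.position_width
    initial = []
    for _ in range(spec.window):
        p = reader.read_int(pw)
        if not (1 <= p <= m):
            raise ContainerFormatError(f"initial symbol position {p} out of range")
        initial.append(p - 1)

    coder = BlockCoder(state_rows, spec, alphabet)
    codes = decode_data(reader, initial, n, coder, spec)
    if reader.remaining:
        raise ContainerFormatError(f"{reader.remaining} trailing bits after the data")
    return ParsedContainer(mode, spec, n, partition, counts, alphabet.decode(codes))


def decompress(container_or_bits, alphabet: Alphabet):
    """Recover the original sequence from a self-contained container."""
    if isinstance(container_or_bits, CompressedContainer):
        if container_or_bits.accounting_mode != "self_contained":
            raise ContainerFormatError(
                "only self-contained containers carry enough header to decode"
            )
        bits = container_or_bits.bits
    else:
        bits = container_or_bits
    return parse_container(bits, alphabet).sequence


def bit_accounting(container: CompressedContainer) -> dict:
    """Per-field breakdown, totals and the compression ratio R_c."""
    breakdown = container.breakdown()
    n_freqs = container.field_width("frequencies") // frequency_width(container.n)
    return {
        "mode": container.mode,
        "accounting": container.accounting_mode,
        "n": container.n,
        "fields": breakdown,
        "n_frequencies": n_freqs,
        "model_bits": container.model_bits,
        "data_bits": container.data_bits,
        "total_bits": container.total_bits,
        "uncompressed_bits": container.uncompressed_bits,
        "compression_ratio": container.compression_ratio,
    }


_MAGIC = b"PMZ1"


def write_pmz(container: CompressedContainer, path) -> None:
    """Write a container to disk: magic, version, flag byte, alphabet, payload.

    The flag byte carries the mode (bit 7), accounting (bit 6) and the
    number of zero pad bits appended to reach a byte boundary (bits 0-2).
    """
    bits = container.bits
    pad = (-len(bits)) % 8
    flag = (
        (0x80 if container.mode == "parts" else 0)
        | (0x40 if container.accounting_mode == "self_contained" else 0)
        | pad
    )
    payload = int(bits + "0" * pad, 2).to_bytes((len(bits) + pad) // 8, "big") if bits else b""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(bytes([1, flag, container.alphabet.size]))
        for sym in container.alphabet.symbols:
            raw = str(sym).encode("utf-8")
            fh.write(bytes([len(raw)]))
            fh.write(raw)
        fh.write(payload)


def read_pmz(path) -> tuple[str, Alphabet, str, str]:
    """Read a .pmz file; returns (bits, alphabet, mode, accounting)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[:4] != _MAGIC or len(raw) < 7:
        raise ContainerFormatError("not a pmz container (bad magic)")
    version, flag, asize = raw[4], raw[5], raw[6]
    if version != 1:
        raise ContainerFormatError(f"unsupported container version {version}")
    pos = 7
    symbols = []
    for _ in range(asize):
        ln = raw[pos]
        symbols.append(raw[pos + 1 : pos + 1 + ln].decode("utf-8"))
        pos += 1 + ln
    alphabet = Alphabet(symbols)
    payload = raw[pos:]
    pad = flag & 0x07
    nbits = len(payload) * 8 - pad
    bits = bin(int.from_bytes(payload, "big"))[2:].zfill(len(payload) * 8)[:nbits] if payload else ""
    mode = "parts" if flag & 0x80 else "states"
    accounting = "self_contained" if flag & 0x40 else "paper"
    return bits, alphabet, mode, accounting


def compress_to_file(
    sequence, alphabet: Alphabet, spec: ModelSpec, path, mode: str = "parts"
) -> CompressedContainer:
    container = compress(sequence, alphabet, spec, mode=mode, accounting="self_contained")
    write_pmz(container, path)
    return container


def decompress_file(path):
    bits, alphabet, _mode, accounting = read_pmz(path)
    if accounting != "self_contained":
        raise ContainerFormatError("paper-accounting containers are not decodable")
    return parse_container(bits, alphabet).sequence
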