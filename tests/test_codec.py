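import numpy as np
import pytest

from pmmcodec import examples as ex
from pmmcodec.codec import (
    BitReader,
    BlockCoder,
    assemble_container,
    bit_accounting,
    compress,
    decode_data,
    decompress,
    encode_data,
    frequency_field,
    frequency_width,
    initial_symbols_field,
    model_description_fields,
    order_field,
    parse_container,
    partition_index_field,
    read_pmz,
    write_pmz,
)
from pmmcodec.errors import ContainerFormatError, InvalidSpecError, PmmError
from pmmcodec.model import (
    Alphabet,
    DNA,
    ModelSpec,
    Partition,
    aggregate_counts,
    count_transitions,
)
from conftest import make_sample

EQ16 = (
    "000011110000010100"
    "000011000000011001"
    "000011010000011001"
    "000011111000010100"
    "000011101000010100"
    "000011001000011001"
    "000001010000011110"
    "000011110000010100"
)
EQ17 = "001111000001010000001001011001001011000001010000011110"


class TestHeaderFields:
    @pytest.mark.parametrize("n,w", [(393, 9), (1, 1), (29903, 15)])
    def test_frequency_width(self, n, w):
        assert frequency_width(n) == w

    def test_order_field_width_and_bits(self):
        f = order_field(3, 393, 2)
        assert (f.bits, f.width) == ("011", 3)

    def test_order_field_minimal(self):
        assert order_field(1, 4, 2).bits == "1"

    def test_order_field_dna(self):
        f = order_field(3, 29903, 4)
        assert int(f.bits, 2) == 3

    def test_order_overflow_without_widening(self):
        with pytest.raises(InvalidSpecError, match="recommended bound"):
            order_field(4, 1000, 4)
        assert int(order_field(4, 1000, 4, allow_widen=True).bits, 2) == 4

    @pytest.mark.parametrize(
        "sym,alpha,bits", [("c", "abc", "11"), ("a", "abc", "01"), ("t", "acgt", "100")]
    )
    def test_initial_symbol_positions(self, sym, alpha, bits):
        assert initial_symbols_field(sym, Alphabet(alpha)).bits == bits


class TestPartitionIndexField:
    def test_three_part_example(self, three_part_partition):
        indices, field, book = partition_index_field(three_part_partition)
        assert indices == [1, 2, 2, 1, 1, 2, 3, 1]
        assert book.codewords == {1: "0", 2: "10", 3: "11"}
        assert field.bits == "010100010110" and field.width == 12

    def test_one_part_partition(self):
        _, field, book = partition_index_field(Partition.one_part(4))
        assert book.codewords == {1: "0"}
        assert field.bits == "0000"

    def test_roundtrip_recovers_index_map(self, rng):
        labels = rng.integers(0, 4, size=16)
        labels[:4] = [0, 1, 2, 3]
        part = Partition.from_labels(labels)
        _, field, book = partition_index_field(part)
        reader = BitReader(field.bits)
        decoder = book.decoder_map()
        got = [reader.read_codeword(decoder, 16) for _ in range(16)]
        assert got == part.indices


class TestFrequencyField:
    def test_state_level_matches_printed_string(self, binary_counts):
        f = frequency_field(binary_counts.counts, 393)
        assert f.bits == EQ16 and f.width == 144

    def test_part_level_matches_printed_string(self, binary_counts, three_part_partition):
        agg = aggregate_counts(binary_counts, three_part_partition)
        f = frequency_field(agg, 393)
        assert f.bits == EQ17 and f.width == 54

    def test_zero_count_is_all_zero_word(self):
        assert frequency_field(np.array([[0]]), 7).bits == "000"


class TestWorkedMessageCodec:
    def test_encode_printed_message(self, cond_probs_abc):
        coder = BlockCoder(cond_probs_abc, ex.MESSAGE_SPEC, ex.ABC)
        codes = ex.ABC.encode(ex.MESSAGE)
        init = initial_symbols_field(ex.MESSAGE[:1], ex.ABC)
        data = encode_data(codes, coder, ex.MESSAGE_SPEC)
        assert init.bits + data.bits == "111011101001110"

    def test_decode_printed_message(self, cond_probs_abc):
        coder = BlockCoder(cond_probs_abc, ex.MESSAGE_SPEC, ex.ABC)
        data_bits = "111011101001110"[2:]  # after the 2-bit initial symbol
        codes = decode_data(BitReader(data_bits), [2], 8, coder, ex.MESSAGE_SPEC)
        assert ex.ABC.decode(codes) == ex.MESSAGE

    def test_constant_sequence_one_bit_per_symbol(self):
        seq = "a" * 100
        c = compress(seq, Alphabet("ab"), ModelSpec(order=1, block_size=1), mode="states")
        assert c.get_field("data").width == 99
        assert decompress(c, Alphabet("ab")) == seq


class TestModelSerializationTallies:
    """The model half of the container for the binary order-3 worked example.

    The printed count table is illustrative (its transition multigraph is
    unbalanced, so no single message realises it); the model description
    depends only on the counts, which are the inputs here.
    """

    def test_by_states_model_bits(self, binary_counts):
        fields = model_description_fields(binary_counts, mode="states")
        widths = {f.name: f.width for f in fields}
        assert widths == {"order": 3, "frequencies": 144}
        assert sum(widths.values()) == 147
        assert widths["frequencies"] // frequency_width(393) == 16

    def test_by_parts_model_bits(self, binary_counts, three_part_partition):
        fields = model_description_fields(
            binary_counts, mode="parts", partition=three_part_partition
        )
        widths = {f.name: f.width for f in fields}
        assert widths["order"] == 3
        assert widths["partition_index"] == 12
        assert widths["codelength_desc"] == 3
        assert widths["frequencies"] == 54
        # the partition information alone: index list + codelength description
        assert widths["partition_index"] + widths["codelength_desc"] == 15
        assert widths["order"] + widths["partition_index"] + widths["frequencies"] == 69
        assert widths["frequencies"] // frequency_width(393) == 6

    def test_paper_field_concatenation_matches_final_string(
        self, binary_counts, three_part_partition
    ):
        fields = {
            f.name: f.bits
            for f in model_description_fields(
                binary_counts, mode="parts", partition=three_part_partition
            )
        }
        got = fields["order"] + fields["partition_index"] + fields["frequencies"]
        assert got == "011" + "010100010110" + EQ17


class TestSelfContainedRoundTrip:
    @pytest.mark.parametrize("m", [2, 3, 4])
    @pytest.mark.parametrize("o", [1, 2, 3])
    @pytest.mark.parametrize("b", [1, 2, 4])
    def test_fuzzed_roundtrips(self, m, o, b):
        seed = m * 100 + o * 10 + b
        _, _, seq = make_sample(m, o, min(3, m**o), 400, seed=seed, block_size=b)
        alphabet = Alphabet("abcd"[:m])
        spec = ModelSpec(order=o, block_size=b)
        for mode in ("states", "parts"):
            c = compress(seq, alphabet, spec, mode=mode)
            assert decompress(c, alphabet) == seq

    def test_parse_recovers_model(self, small_sample):
        scenario, _, seq, spec = small_sample
        c = compress(seq, scenario.alphabet, spec, mode="parts")
        parsed = parse_container(c.bits, scenario.alphabet)
        assert parsed.sequence == seq
        assert parsed.spec == spec
        table = count_transitions(seq, scenario.alphabet, spec)
        from pmmcodec.estimation import estimate_partition

        assert parsed.partition.parts == estimate_partition(table).parts

    def test_gapped_dna_roundtrip(self):
        gen = np.random.default_rng(8)
        # synthetic DNA with a weak lag-9 dependency
        base = gen.choice(list("acgt"), size=1500).tolist()
        for t in range(9, 1500):
            if gen.random() < 0.35:
                base[t] = base[t - 9]
        seq = "".join(base)
        spec = ModelSpec(order=3, gap=9, block_size=1)
        for mode in ("states", "parts"):
            c = compress(seq, DNA, spec, mode=mode)
            assert decompress(c, DNA) == seq

    def test_corrupted_frequency_word_fails_loudly(self, small_sample):
        scenario, _, seq, spec = small_sample
        c = compress(seq, scenario.alphabet, spec, mode="parts")
        bits = list(c.bits)
        # flip a bit inside the frequency field: the count sum check must trip
        names = [f.name for f in c.fields]
        offset = sum(f.width for f in c.fields[: names.index("frequencies")])
        bits[offset + 5] = "1" if bits[offset + 5] == "0" else "0"
        with pytest.raises(PmmError):
            parse_container("".join(bits), scenario.alphabet)

    def test_truncated_stream_fails_loudly(self, small_sample):
        scenario, _, seq, spec = small_sample
        c = compress(seq, scenario.alphabet, spec, mode="parts")
        with pytest.raises(ContainerFormatError):
            parse_container(c.bits[:-40], scenario.alphabet)

    def test_trailing_garbage_detected(self, small_sample):
        scenario, _, seq, spec = small_sample
        c = compress(seq, scenario.alphabet, spec, mode="states")
        with pytest.raises(ContainerFormatError, match="trailing"):
            parse_container(c.bits + "0000000000", scenario.alphabet)


class TestPmzFile:
    def test_file_roundtrip(self, tmp_path, small_sample):
        scenario, _, seq, spec = small_sample
        c = compress(seq, scenario.alphabet, spec, mode="parts")
        path = tmp_path / "sample.pmz"
        write_pmz(c, path)
        bits, alphabet, mode, accounting = read_pmz(path)
        assert bits == c.bits
        assert alphabet.symbols == scenario.alphabet.symbols
        assert (mode, accounting) == ("parts", "self_contained")
        assert parse_container(bits, alphabet).sequence == seq

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "junk.pmz"
        p.write_bytes(b"NOPE" + bytes(10))
        with pytest.raises(ContainerFormatError):
            read_pmz(p)


class TestAccounting:
    def test_parts_beats_states_on_structured_model(self):
        _, _, seq = make_sample(4, 3, 4, 10_000, seed=77, separation=0.2)
        alphabet = Alphabet("abcd")
        spec = ModelSpec(order=3, block_size=4)
        table = count_transitions(seq, alphabet, spec)
        by_states = assemble_container(seq, table, mode="states", accounting="paper")
        by_parts = assemble_container(seq, table, mode="parts", accounting="paper")
        assert by_parts.total_bits < by_states.total_bits
        assert by_parts.model_bits < by_states.model_bits

    def test_ratio_is_one_when_sizes_match(self, small_sample):
        scenario, _, seq, spec = small_sample
        c = compress(seq, scenario.alphabet, spec, mode="parts")
        assert c.compression_ratio == pytest.approx(c.uncompressed_bits / c.total_bits)
        report = bit_accounting(c)
        assert report["model_bits"] + report["data_bits"] == report["total_bits"]

    def test_data_bits_per_symbol_within_entropy_band(self):
        _, _, seq = make_sample(3, 2, 3, 10_000, seed=5, separation=0.4)
        alphabet = Alphabet("abc")
        spec = ModelSpec(order=2, block_size=4)
        table = count_transitions(seq, alphabet, spec)
        from pmmcodec.estimation import entropy_plugin, estimate_partition

        part = estimate_partition(table)
        c = assemble_container(seq, table, mode="parts", accounting="paper", partition=part)
        bps = c.get_field("data").width / (table.n - spec.order)
        h = entropy_plugin(table, part).value
        assert h <= bps <= h + 1 / spec.block_size + 0.05
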