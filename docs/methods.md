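# Methods

## Model

Sequences are realisations of a stationary order-`o` Markov chain `(X_t)` on
a finite ordered alphabet `A` (`m = |A|`).  The state space is `S = A^o`;
in the gapped variant a state additionally carries the symbol at lag
`G > o`, i.e. states live in `A × A^o` and `|S| = m^(o+1)`.  The gapped
window is (lag `G`, then the contiguous lags `o..1`); states are serialised
in lexical order of that tuple under the alphabet's ordering, which is fixed
once and reused everywhere (counting, partition indices, frequency fields).

A **Partition Markov Model** groups states into parts with identical
conditional laws: `P(a|s) = P(a|L)` for every `s ∈ L`.  A PMM is *minimal*
when distinct parts carry distinct laws; the simulator only generates
minimal models.

### Counting and estimation

`N(s,a)` counts windows `o < t ≤ n` with state `s` followed by symbol `a`
(`G < t ≤ n` with a gap); totals satisfy `Σ_s N(s) = n − o` (`n − G`).
Counting is contiguous within one sequence, no wrap-around.  Part-level
counts are sums over members, and `N(L,a)/N(L)` estimates `P(a|L)`.

The partition is selected by maximising

```
BIC(L) = Σ_{L,a} N(L,a) ln(N(L,a)/N(L)) − (m−1)|L|/2 · ln n
```

with `0·ln 0 = 0` and `|L|` counting only parts with positive counts.  The
optimiser is greedy pairwise agglomeration from singleton parts of the
observed states: at each step the merge with the largest strictly positive
BIC gain is applied (merging costs likelihood but saves `(m−1)/2·ln n` of
penalty); ties go to the smallest part indices, making the procedure fully
deterministic.  An exhaustive search over set partitions is provided as a
reference implementation for up to 8 observed states and agrees with the
greedy result on randomised small tables in the test suite.  Worst-case cost
is `O(|S|^2·m)` for the initial gain matrix plus `O(|S|·m)` per merge —
negligible up to the 256-state models used here.

States never observed in the sample are excluded from the likelihood and
appended to part 1 (configurable to a separate trailing part), so the
serialised state→part map is total.  Their rows are never used for coding:
a state must occur as a context to be needed, and occurring contexts always
have counts.

### Entropy and the codeword-rate floor

For a stationary PMM the entropy rate is
`H_D = − Σ_L P(L) Σ_a P(a|L) log_D P(a|L)` (the part-level regrouping of the
state-level conditional entropy).  From a sample, the plug-in estimate is
`Ĥ_D = − ln ML(L̂, x_1^n) / (n ln D)`, identical to the count-weighted sum
of the parts' empirical entropies.  The denominator is `n` as defined,
although only `n − o` transitions contribute; an `n_minus_o` variant is
available behind a flag (the difference is `O(o/n)`).  Since the expected
length per symbol of an optimal prefix block code converges to the entropy
rate as the block grows, `Ĥ_D` is reported as the estimated minimum expected
codeword length per symbol; `min_codeword_rate` is an explicit alias.

## Coding

### Huffman construction

`huffman_codelengths` implements binary Huffman merging with deterministic
tie-breaking: among equal weights the group whose lexically smallest member
comes first wins, and merged groups inherit that member.  Zero-weight
symbols are excluded (the decoder reconstructs the identical support from
the transmitted integer frequencies); a single-symbol support gets the
one-bit code "0".

The canonical form orders symbols by (probability desc, Huffman length asc,
lexical position asc) and assigns the sorted length multiset along that
order.  With exact weights this reproduces each symbol's own depth; with
float weights it additionally repairs epsilon-level inversions that rounding
of merged sums can introduce, without changing the multiset (and therefore
without losing optimality).  Codewords then follow the canonical rule:
`l_1` zeros, each next codeword the previous plus one in binary, zero-padded
on the right when the length increases.  Codewords are MSB-first bit
strings, never padded.

Block codes condition on the state preceding each `b`-block, with block law
`P(x_1^b|s) = Π_i P(x_i | s_i)` (the state advanced one symbol at a time).
With a gap the intermediate states depend on symbols outside the current
state tuple, so block coding is restricted to `b = 1` in gapped mode.
Undefined rows reachable inside a block (never-observed states) are treated
as dead-ends — such blocks get probability zero and no codeword; this is
exactly mirrored at the decoder, and no occurring block is ever affected.
Consequently, for contexts whose continuations include unobserved states the
block weights sum to slightly less than one; codebooks are built from the
unnormalised weights, which Huffman handles unchanged.

### Serialization protocol

All fixed-width integers are big-endian.  Frequencies are written at
`⌊log₂ n⌋ + 1` bits each (any count is ≤ n), context-major then alphabet
order.  The order field takes `⌊log₂(log_m n − 1)⌋ + 1` bits; gapped models
instead reserve 4 bits for `o` and 8 for `G`.  Initial symbols (the first
`o`, or `G` with a gap) are written as 1-based lexical positions at
`⌊log₂ m⌋ + 1` bits each.

The by-Parts header codes the per-state part-index list with a canonical
Huffman code built from the part sizes `|L_i|/|S|`, plus a *codelength
description* of that index code: one bit per part giving the increment of
each codelength over the previous one (first increment from zero).  The
one-bit scheme cannot express an increment ≥ 2 (e.g. four equal parts with
lengths 2,2,2,2), in which case an escape variant writes each increment in
unary; the choice is carried in a flag.

Two accounting modes:

* **paper** — only order (+gap), partition fields and frequencies for the
  model; reproduces the worked-example tallies (147 bits by States; 69 bits
  for order + index list + part frequencies by Parts, with the 3-bit
  codelength description tallied separately as part of the 15-bit partition
  information).
* **self_contained** — additionally prepends the sample length `n`
  (32 bits), block size `b` (8 bits), a 3-bit flags field (mode, gap
  present, description variant) and the part count `|L|` at
  `⌊log₂|S|⌋ + 1` bits, and moves the codelength description ahead of the
  index list (the decoder needs the index codebook before it can read an
  index).  These containers decode with no side information beyond the
  alphabet.

Decodability of the index list deserves a note: only codeword *lengths* are
transmitted, not part labels.  The decoder reads the codeword sequence with
the anonymous canonical codebook and renumbers symbols by first appearance
over the lexical state scan; because the encoder numbers parts by first
appearance too, the recovered map is exact, and the part-level frequency
block (ordered by part index) lines up.

Both codec sides rebuild the data codebooks from the same transmitted
integer counts, so their (float) conditional rows, tie decisions and
codebooks agree bit for bit.  Decoding is streaming: prefix codes resolve
each codeword as its last bit arrives.  A trailing remainder of `r < b`
symbols is coded symbol-by-symbol with `b = 1` codebooks derived from the
same counts; the decoder infers `r` from `n`.  Parsing is strict: count
sums, part counts, symbol positions and stream length are validated, and
corruption surfaces as a deterministic error, never as wrong output.

The compression ratio is `Rc = n·(⌊log₂(m−1)⌋ + 1) / total_bits`
(uncompressed cost of 1 bit/symbol for binary, 2 for 3- and 4-letter
alphabets).

Degenerate corners: an order that does not fit the inferable order-field
width is an error in self-contained mode (the decoder must derive the width
from `n` and `m` alone) but is written at `bit_length(o)` under paper
accounting so oversized benchmark shapes can still be measured; a sample of
length `n ≤ o` cannot be counted and is rejected — the container format has
no header-only special case.

## Synthetic data

`random_pmm` assigns states to `|L|` balanced parts by a seeded shuffle and
draws one conditional law per part from a symmetric Dirichlet
(concentration 1.0 by default, i.e. uniform on the simplex), redrawing until
all pairwise total-variation distances reach the requested separation
(default 0: only distinctness, hence minimality, is enforced — mandatory for
large `|L|`, where sizeable separation is geometrically infeasible).
Sampling starts from a uniformly drawn state and discards a burn-in of
`10·|S|` symbols (configurable) to approximate the stationarity the entropy
theory assumes.  Part weights attached to generated models are the
state-uniform proxy `|L_i|/|S|`, used only for closed-form entropies of
constructed models, never for sampling.

The benchmark grid reproduces the eight published scenario *shapes*
(order, part count, alphabet size: 64 and 256 singleton-part models, 2-part
models on 27 states, 4-part models on 64 and 256 states, and 6/3-part models
on 8 binary states).  The generating transition probabilities behind the
published numbers are not available, so the runner regenerates random models
of the same shapes: orderings and regime changes (which strategy wins, where
compression fails outright) are reproducible, exact cell values are not and
are not targeted.  Both conventions for averaging the compression ratio
(mean of per-replicate ratios, ratio of mean sizes) are reported since the
choice is not documented.

What the generator does *not* emulate about real genomic data: long-range
and non-stationary structure, repeats, heterogeneous composition along the
sequence, and ambiguity codes.  Green tests therefore demonstrate
correctness of the machinery and the statistical behaviour under the model's
own assumptions, not compression performance on arbitrary real sequences.

## Problem sizes used in the test and acceptance runs

Partition recovery uses 3-letter order-2 models (9 states) with 3 parts,
pairwise row separation ≥ 0.4 in total variation, samples of `n = 10^4`,
100 seeds; the benchmark contrasts use all eight shapes at `n = 5000` with
20 replicates each (plus the 256-state shape at `n = 1000` for the
failure-to-compress regime).  Huffman optimality is verified against an
exhaustive search over monotone Kraft-feasible length vectors for up to six
symbols, 200 random distributions.

## Known limitations

* Gapped models code data with `b = 1` only (see above); multi-interstice
  and variable-length (context-tree) memories are out of scope.
* The greedy agglomeration is a heuristic: it matches the exhaustive BIC
  optimum on the small tables where that is checkable, but carries no global
  guarantee in tie-heavy cases.
* The published worked-example count table is itself illustrative — its
  transition multigraph is unbalanced, so no single message realises it;
  serialization tallies are computed from the counts, which is all the
  protocol needs.
* Sequences are processed in memory; this is a modelling/benchmark codec,
  not a streaming archiver.
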