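"""Synthetic Partition Markov Models and the by-States vs by-Parts benchmark.

The generator draws one conditional law per part from a Dirichlet
distribution and assigns states to parts in balanced blocks (seeded
shuffle).  A minimum pairwise total-variation separation between part rows
can be requested; rows are redrawn until it holds.  Samples start from a
uniformly drawn state and a burn-in stretch is discarded so the retained
stretch is approximately stationary.

``run_comparison`` mirrors the benchmark design of the method: for a grid
of scenario shapes (alphabet size, order, number of parts) and sample
sizes, it fits both the full chain (``by States``) and the BIC-estimated
PMM (``by Parts``), compresses with block codes, and reports per-replicate
model bits, data bits, total bits and the compression ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import assemble_container
from .errors import InvalidSpecError
from .estimation import entropy_plugin, estimate_partition
from .model import (
    Alphabet,
    ModelSpec,
    PMM,
    Partition,
    StateSpace,
    count_transitions,
)

__all__ = [
    "ScenarioSpec",
    "reference_scenarios",
    "random_pmm",
    "sample_sequence",
    "run_comparison",
    "summarize_comparison",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class ScenarioSpec:
    """Shape and size of one simulation setting."""

    label: str
    alphabet_size: int
    order: int
    n_parts: int
    sample_sizes: tuple = (1000, 5000, 10000)
    n_replicates: int = 100
    separation: float = 0.0  # minimum pairwise total variation between part rows
    concentration: float = 1.0  # Dirichlet concentration for row draws
    block_size: int = 4

    def __post_init__(self):
        if not (0.0 <= self.separation < 1.0):
            raise InvalidSpecError("separation must lie in [0, 1)")
        if self.n_replicates < 1:
            raise InvalidSpecError("need at least one replicate")
        if self.n_parts > self.alphabet_size**self.order:
            raise InvalidSpecError("more parts than states")

    @property
    def alphabet(self) -> Alphabet:
        return Alphabet(_LETTERS[: self.alphabet_size])

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(order=self.order, block_size=self.block_size)


def reference_scenarios(
    sample_sizes: tuple = (1000, 5000, 10000), n_replicates: int = 100
) -> list[ScenarioSpec]:
    """The eight benchmark shapes (order, #parts, alphabet size) of the study design."""
    shapes = [
        ("1", 3, 64, 4),
        ("2", 4, 256, 4),
        ("3", 3, 2, 3),
        ("4", 3, 2, 3),
        ("5", 3, 4, 4),
        ("6", 4, 4, 4),
        ("7", 3, 6, 2),
        ("8", 3, 3, 2),
    ]
    return [
        ScenarioSpec(
            label=lab,
            order=o,
            n_parts=k,
            alphabet_size=a,
            sample_sizes=tuple(sample_sizes),
            n_replicates=n_replicates,
        )
        for lab, o, k, a in shapes
    ]


def _pairwise_tv(rows: np.ndarray) -> float:
    k = rows.shape[0]
    if k < 2:
        return 1.0
    tv = np.abs(rows[:, None, :] - rows[None, :, :]).sum(axis=2) / 2.0
    iu = np.triu_indices(k, k=1)
    return float(tv[iu].min())


def random_pmm(
    scenario: ScenarioSpec, rng: np.random.Generator, max_retries: int = 1000
) -> PMM:
    """Draw a minimal PMM with the scenario's shape.

    States are split into ``n_parts`` balanced parts after a seeded shuffle;
    each part's row is Dirichlet-distributed and the whole set is redrawn
    until every pair of rows is at least ``separation`` apart in total
    variation (distinct rows are always enforced, so the model is minimal).
    """
    alphabet = scenario.alphabet
    spec = scenario.spec
    space = StateSpace(alphabet, spec)
    S = space.n_states
    k = scenario.n_parts

    perm = rng.permutation(S)
    bounds = np.linspace(0, S, k + 1).astype(int)
    parts = [perm[bounds[i] : bounds[i + 1]].tolist() for i in range(k)]
    partition = Partition(parts, S).canonicalize()

    alpha = np.full(alphabet.size, scenario.concentration)
    for _ in range(max_retries):
        rows = rng.dirichlet(alpha, size=k)
        if _pairwise_tv(rows) >= max(scenario.separation, 1e-9):
            break
    else:
        raise InvalidSpecError(
            f"could not draw {k} rows with pairwise separation "
            f">= {scenario.separation} in {max_retries} attempts"
        )
    weights = np.array(partition.sizes, dtype=float) / S
    return PMM(alphabet, spec, partition, rows, part_weights=weights)


def sample_sequence(
    pmm: PMM, n: int, rng: np.random.Generator, burn_in: int | None = None
) -> str:
    """Sample a length-n realisation of the PMM.

    The initial state is uniform over the state space and ``burn_in``
    symbols (default ``10 * |S|``) are generated and discarded before the
    retained stretch, to approximate stationarity.
    """
    spec = pmm.spec
    alphabet = pmm.alphabet
    m = alphabet.size
    W = spec.window
    if n <= W:
        raise InvalidSpecError(f"sample length {n} must exceed the window {W}")
    if burn_in is None:
        burn_in = 10 * (m**spec.state_length)
    total = W + burn_in + n
    codes = np.empty(total, dtype=np.int64)
    codes[:W] = rng.integers(0, m, size=W)
    rows = pmm.state_rows
    cum = np.cumsum(rows, axis=1)
    o = spec.order
    state = 0
    for k in range(o):
        state = state * m + int(codes[W - o + k])
    mo1 = m ** (o - 1)
    u = rng.random(total - W)
    gap = spec.gap
    for t in range(W, total):
        s = state if gap is None else int(codes[t - gap]) * (m**o) + state
        sym = int(np.searchsorted(cum[s], u[t - W], side="right"))
        sym = min(sym, m - 1)  # guard against cum[-1] < 1 by rounding
        codes[t] = sym
        state = (state % mo1) * m + sym
    return alphabet.decode(codes[total - n :])


def _one_replicate(
    scenario: ScenarioSpec, n: int, rep: int, rng: np.random.Generator
) -> list[dict]:
    pmm = random_pmm(scenario, rng)
    seq = sample_sequence(pmm, n, rng)
    table = count_transitions(seq, scenario.alphabet, scenario.spec)
    rows = []
    order_ok = scenario.spec.order < int(
        np.floor(np.log(n) / np.log(scenario.alphabet_size)) - 1
    )
    for mode in ("states", "parts"):
        partition = estimate_partition(table) if mode == "parts" else None
        container = assemble_container(
            seq, table, mode=mode, accounting="paper", partition=partition
        )
        ent_partition = (
            partition
            if partition is not None
            else Partition.singletons(table.state_space.n_states)
        )
        rows.append(
            {
                "scenario": scenario.label,
                "order": scenario.order,
                "true_parts": scenario.n_parts,
                "alphabet_size": scenario.alphabet_size,
                "n": n,
                "replicate": rep,
                "method": "by States" if mode == "states" else "by Parts",
                "est_parts": partition.n_parts if partition is not None else None,
                "model_bits": container.model_bits,
                "data_bits": container.data_bits,
                "total_bits": container.total_bits,
                "uncompressed_bits": container.uncompressed_bits,
                "compression_ratio": container.compression_ratio,
                "entropy_plugin": entropy_plugin(table, ent_partition).value,
                "order_warning": not order_ok,
            }
        )
    return rows


def run_comparison(
    scenario: ScenarioSpec, seed: int = 0, progress: bool = False
) -> pd.DataFrame:
    """Per-replicate benchmark of both strategies under one scenario.

    Every replicate regenerates a fresh random model and sample (seeded);
    both strategies compress the same sample with paper accounting.  A
    scenario whose order violates the recommended bound
    ``o < floor(log_|A|(n)) - 1`` is still run, with ``order_warning`` set.
    """
    rows: list[dict] = []
    ss = np.random.SeedSequence([seed] + [ord(c) for c in scenario.label])
    children = ss.spawn(len(scenario.sample_sizes) * scenario.n_replicates)
    k = 0
    for n in scenario.sample_sizes:
        for rep in range(scenario.n_replicates):
            rng = np.random.default_rng(children[k])
            k += 1
            rows.extend(_one_replicate(scenario, n, rep, rng))
    return pd.DataFrame(rows)


def summarize_comparison(df: pd.DataFrame) -> pd.DataFrame:
    """Mean bits per (scenario, n, method); R_c both as mean of per-replicate
    ratios and as the ratio of mean sizes (the study leaves this ambiguous)."""
    grouped = df.groupby(["scenario", "n", "method"], sort=False)
    out = grouped.agg(
        model_bits=("model_bits", "mean"),
        data_bits=("data_bits", "mean"),
        total_bits=("total_bits", "mean"),
        rc_mean_of_ratios=("compression_ratio", "mean"),
        uncompressed_bits=("uncompressed_bits", "mean"),
        replicates=("replicate", "count"),
    ).reset_index()
    out["rc_ratio_of_means"] = out["uncompressed_bits"] / out["total_bits"]
    return out
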