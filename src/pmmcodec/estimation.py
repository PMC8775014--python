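"""BIC model selection for Partition Markov Models and entropy estimation.

The selection criterion for a candidate partition ``L`` of the state space is

    BIC(L, x_1^n) = ln ML(L, x_1^n) - (|A| - 1) |L| / 2 * ln(n),

where ``ln ML`` is the pseudo log-likelihood ``sum_{L,a} N(L,a) ln(N(L,a)/N(L))``
over parts with positive counts.  Maximising the BIC over partitions is done
by greedy pairwise agglomeration starting from singleton parts: the merge
with the largest strictly positive BIC gain is applied until no merge helps.
Merging never changes the likelihood of parts with identical empirical rows,
while each merge lowers the penalty by ``(|A|-1)/2 ln n``, so statistically
indistinguishable states end up sharing a part.

The fitted partition doubles as an entropy estimator: the plug-in entropy
``-ln ML(L^, x_1^n) / (n ln D)`` estimates the entropy rate of the process in
base ``D``, which is also the asymptotic minimum expected codeword length per
symbol of any prefix block code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import InvalidSpecError, NoDataError
from .model import CountTable, PMM, Partition, aggregate_counts, transition_probs

__all__ = [
    "BICValue",
    "EntropyEstimate",
    "log_pseudo_likelihood",
    "bic",
    "estimate_partition",
    "exhaustive_partition",
    "entropy_plugin",
    "entropy_closed_form",
    "min_codeword_rate",
    "fit_pmm",
]


@dataclass(frozen=True)
class BICValue:
    log_pseudo_likelihood: float
    penalty: float

    @property
    def bic(self) -> float:
        return self.log_pseudo_likelihood - self.penalty


@dataclass(frozen=True)
class EntropyEstimate:
    value: float
    base: int
    source: str  # "plug-in" | "closed-form"


def log_pseudo_likelihood(part_counts: np.ndarray) -> float:
    """sum_{L,a} N(L,a) ln(N(L,a)/N(L)), with 0 ln 0 = 0 and empty parts skipped."""
    counts = np.asarray(part_counts, dtype=np.float64)
    if counts.ndim == 1:
        counts = counts[None, :]
    totals = counts.sum(axis=1)
    keep = totals > 0
    counts = counts[keep]
    totals = totals[keep]
    return float(xlogy(counts, counts).sum() - xlogy(totals, totals).sum())


def _penalty(n_parts: int, alphabet_size: int, n: int) -> float:
    return (alphabet_size - 1) * n_parts / 2.0 * math.log(n)


def bic(partition: Partition, table: CountTable) -> BICValue:
    """BIC of a partition; |L| counts only parts with positive counts."""
    if table.n <= 1:
        raise NoDataError("BIC requires a sample of length n > 1")
    part_counts = aggregate_counts(table, partition)
    effective = int((part_counts.sum(axis=1) > 0).sum())
    return BICValue(
        log_pseudo_likelihood(part_counts),
        _penalty(effective, table.alphabet.size, table.n),
    )


def estimate_partition(table: CountTable, unobserved: str = "first") -> Partition:
    """Greedy BIC-maximising agglomeration of states into parts.

    Starts from one singleton part per observed state; repeatedly merges the
    pair of parts with the largest strictly positive BIC gain (ties broken
    toward the smallest part indices) until no merge improves the BIC.

    Never-observed states contribute nothing to the likelihood; they are
    appended to the first part (``unobserved="first"``, the default, so the
    serialised index map is total) or kept as one trailing part
    (``unobserved="own_part"``).
    """
    obs = np.flatnonzero(table.observed)
    if obs.size == 0:
        raise NoDataError("no observed states in the count table")
    n = table.n
    m = table.alphabet.size
    pen_unit = _penalty(1, m, n)

    counts = table.counts[obs].astype(np.float64)  # (P, m)
    members: list[list[int]] = [[int(s)] for s in obs]
    P = len(members)
    alive = np.ones(P, dtype=bool)

    def row_ll(rows: np.ndarray) -> np.ndarray:
        tot = rows.sum(axis=-1)
        return xlogy(rows, rows).sum(axis=-1) - xlogy(tot, tot)

    ll = row_ll(counts)  # per-part pseudo log-likelihood

    def gains_against(i: int) -> np.ndarray:
        g = row_ll(counts[i][None, :] + counts) - ll[i] - ll + pen_unit
        g[~alive] = -np.inf
        g[i] = -np.inf
        return g

    # gain[i, j] = ll(i merged with j) - ll(i) - ll(j) + pen_unit; only the
    # merged part's row changes per step, so the matrix is updated in place.
    gain = np.full((P, P), -np.inf)
    for i in range(P):
        gain[i, i + 1 :] = gains_against(i)[i + 1 :]

    for _ in range(P - 1):
        flat = int(np.argmax(gain))  # first maximum = smallest (i, j) pair
        i, j = divmod(flat, P)
        if gain[i, j] <= 0:
            break
        counts[i] += counts[j]
        ll[i] = row_ll(counts[i][None, :])[0]
        members[i].extend(members[j])
        alive[j] = False
        gain[j, :] = -np.inf
        gain[:, j] = -np.inf
        g = gains_against(i)
        gain[i, i + 1 :] = g[i + 1 :]
        gain[: i, i] = g[:i]

    parts = [sorted(members[i]) for i in np.flatnonzero(alive)]
    hidden = [int(s) for s in np.flatnonzero(~table.observed)]
    if hidden:
        if unobserved == "first":
            # attach to the part that will carry index 1 (earliest first state)
            first = min(range(len(parts)), key=lambda k: parts[k][0])
            parts[first] = sorted(parts[first] + hidden)
        elif unobserved == "own_part":
            parts.append(hidden)
        else:
            raise InvalidSpecError(f"unknown unobserved policy {unobserved!r}")
    return Partition(parts, table.state_space.n_states).canonicalize()


def _set_partitions(items: list):
    """All set partitions of ``items`` (restricted growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for k in range(len(sub)):
            yield sub[:k] + [[first] + sub[k]] + sub[k + 1 :]
        yield [[first]] + sub


def exhaustive_partition(table: CountTable) -> tuple[Partition, BICValue]:
    """Brute-force BIC maximiser over all set partitions of the observed states.

    Reference implementation for tiny state spaces (Bell numbers grow fast;
    refuse beyond 8 observed states).  Unobserved states join the first part.
    """
    obs = [int(s) for s in np.flatnonzero(table.observed)]
    if not obs:
        raise NoDataError("no observed states")
    if len(obs) > 8:
        raise InvalidSpecError("exhaustive search limited to <= 8 observed states")
    hidden = [int(s) for s in np.flatnonzero(~table.observed)]
    best: tuple[float, Partition] | None = None
    for grouping in _set_partitions(obs):
        parts = [list(g) for g in grouping]
        if hidden:
            k = min(range(len(parts)), key=lambda i: min(parts[i]))
            parts[k] = parts[k] + hidden
        cand = Partition(parts, table.state_space.n_states).canonicalize()
        val = bic(cand, table)
        if best is None or val.bic > best[0] + 1e-12:
            best = (val.bic, cand)
    assert best is not None
    return best[1], bic(best[1], table)


def entropy_plugin(
    table: CountTable,
    partition: Partition,
    base: int = 2,
    denominator: str = "n",
) -> EntropyEstimate:
    """Plug-in entropy-rate estimate -ln ML(L^, x_1^n) / (n ln D).

    Identical to the weighted form ``sum_L N(L)/n * H_L`` with empirical
    conditional entropies ``H_L``.  ``denominator="n_minus_o"`` divides by the
    number of counted transitions instead of the sample length.
    """
    if base < 2:
        raise InvalidSpecError("entropy base D must be >= 2")
    if denominator == "n":
        denom = table.n
    elif denominator == "n_minus_o":
        denom = table.n_transitions
    else:
        raise InvalidSpecError(f"unknown denominator {denominator!r}")
    ll = log_pseudo_likelihood(aggregate_counts(table, partition))
    return EntropyEstimate(-ll / (denom * math.log(base)), base, "plug-in")


def entropy_closed_form(pmm: PMM, base: int = 2) -> EntropyEstimate:
    """Entropy rate of a stationary PMM: -sum_L P(L) sum_a P(a|L) log_D P(a|L)."""
    if base < 2:
        raise InvalidSpecError("entropy base D must be >= 2")
    if pmm.part_weights is None:
        raise InvalidSpecError("closed-form entropy requires part weights")
    p = pmm.cond_probs
    h_parts = -(xlogy(p, p).sum(axis=1)) / math.log(base)
    return EntropyEstimate(
        float(np.dot(pmm.part_weights, h_parts)), base, "closed-form"
    )


def min_codeword_rate(
    table: CountTable, partition: Partition, base: int = 2, denominator: str = "n"
) -> float:
    """Estimated minimum expected codeword length per symbol (base-D digits).

    The asymptotic floor for any prefix block code equals the entropy rate,
    so this is the plug-in entropy estimate reported per symbol.
    """
    return entropy_plugin(table, partition, base, denominator).value


def fit_pmm(table: CountTable, unobserved: str = "first") -> PMM:
    """Estimate the partition by BIC and attach empirical rows and weights."""
    partition = estimate_partition(table, unobserved=unobserved)
    part_counts = aggregate_counts(table, partition)
    probs, observed = transition_probs(part_counts)
    if not observed.all():
        # parts of only-unobserved states get a uniform placeholder row
        probs[~observed] = 1.0 / table.alphabet.size
    weights = part_counts.sum(axis=1) / table.n_transitions
    return PMM(table.alphabet, table.spec, partition, probs, weights)
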