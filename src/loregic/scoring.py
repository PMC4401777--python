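"""Matching regulatory triplets to logic gates by succession-rule scoring.

For a triplet (RF1, RF2, T) with binarized expression vectors x, y, z over m
samples, the samples are partitioned by input combination v_i in
{(0,0), (0,1), (1,0), (1,1)}.  With m_i samples at combination v_i, of which
n_i^g have a target value matching gate g's output f^g(v_i), the gate's
succession probability at v_i is the Laplace-smoothed fraction

    s_i^g = (1 + n_i^g) / (2 + m_i)

and the consistency score is the product C^g = s_1^g s_2^g s_3^g s_4^g.
The smoothing penalizes gates distinguished on few observations; with no
data at all every gate scores (1/2)^4 = 1/16, the probability of a random
guess among the 16 gates.  The gate with the strictly highest score is the
match; any tie at the maximum makes the triplet *gate-inconsistent*.

Scores are exact rationals: all 16 gates share the denominator
prod_i (2 + m_i), so best-gate selection and tie detection compare the
integer numerators prod_i (1 + n_i^g) and never depend on float rounding.

A permutation score guards against spurious matches: the target is replaced
by a randomly drawn gene M times and the score is the fraction of
replacements that are again gate-consistent with the same gate.  Matches
with a permutation score at or above the threshold (default 0.1) fail the
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gates import Gate, enumerate_gates
from .network import Triplet

__all__ = [
    "TripletCounts",
    "GateMatch",
    "INCONSISTENT",
    "tabulate_counts",
    "consistency_score",
    "score_all_gates",
    "match_gate",
    "match_counts",
    "permutation_score",
]

#: Sentinel label used in output tables for gate-inconsistent triplets.
INCONSISTENT = "inconsistent"

_GATES = enumerate_gates()
# gate outputs as a 16 x 4 bit array, row order = gate id
_GATE_OUT = np.array([g.outputs for g in _GATES], dtype=np.int64)


@dataclass(frozen=True)
class TripletCounts:
    """Per-input-combination sample tallies for one triplet.

    ``m_i[i]`` counts samples with inputs equal to v_{i+1}; ``n1_i[i]``
    counts those among them whose target value is 1.  ``m`` is the total
    number of samples retained (missing-value samples are dropped upstream).
    """

    m_i: tuple[int, int, int, int]
    n1_i: tuple[int, int, int, int]

    def __post_init__(self):
        if sum(self.m_i) < 0 or any(
            not (0 <= n <= m) for n, m in zip(self.n1_i, self.m_i)
        ):
            raise ValueError(f"inconsistent counts: m_i={self.m_i}, n1_i={self.n1_i}")

    @property
    def m(self) -> int:
        return int(sum(self.m_i))

    def n_for_gate(self, g: Gate) -> tuple[int, ...]:
        """n_i^g: samples at v_i whose target matches the gate output."""
        return tuple(
            n1 if out == 1 else m - n1
            for m, n1, out in zip(self.m_i, self.n1_i, g.outputs)
        )


def _clean_vectors(x, y, z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if not (x.size == y.size == z.size):
        raise ValueError(
            f"vector length mismatch: {x.size}, {y.size}, {z.size}"
        )
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[keep], y[keep], z[keep]
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"{name} contains non-binary values")
    return x.astype(np.int64), y.astype(np.int64), z.astype(np.int64)


def tabulate_counts(x, y, z) -> TripletCounts:
    """Tally (m_i, n1_i) from three equal-length binary vectors.

    Samples with a missing value in any of the three vectors are dropped
    first; the remaining count is ``m``.
    """
    xi, yi, zi = _clean_vectors(x, y, z)
    combo = (xi << 1) | yi
    m_i = np.bincount(combo, minlength=4)
    n1_i = np.bincount(combo, weights=zi, minlength=4).astype(np.int64)
    return TripletCounts(tuple(int(v) for v in m_i), tuple(int(v) for v in n1_i))


def consistency_score(counts: TripletCounts, g: Gate) -> Fraction:
    """Exact consistency score C^g = prod_i (1 + n_i^g) / (2 + m_i)."""
    num = 1
    den = 1
    for m, n in zip(counts.m_i, counts.n_for_gate(g)):
        num *= 1 + n
        den *= 2 + m
    return Fraction(num, den)


def _numerators(counts: TripletCounts) -> list[int]:
    """Score numerators for all 16 gates over the common denominator."""
    m, n1 = counts.m_i, counts.n1_i
    factors = [(1 + n1[i], 1 + m[i] - n1[i]) for i in range(4)]  # (out=1, out=0)
    nums = []
    for g in _GATES:
        p = 1
        for i, out in enumerate(g.outputs):
            p *= factors[i][0] if out else factors[i][1]
        nums.append(p)
    return nums


def score_all_gates(counts: TripletCounts) -> tuple[Fraction, ...]:
    """Exact consistency scores for all 16 gates, in gate-id order."""
    den = 1
    for m in counts.m_i:
        den *= 2 + m
    return tuple(Fraction(num, den) for num in _numerators(counts))


@dataclass
class GateMatch:
    """Result of matching one triplet against all 16 gates."""

    counts: TripletCounts
    best_gate: Optional[Gate]  # None when gate-inconsistent
    score: Fraction  # score of the (possibly tied) maximum
    per_gate_scores: tuple[Fraction, ...]
    triplet: Optional[Triplet] = None
    permutation_p: Optional[float] = None
    passed_filter: Optional[bool] = None

    @property
    def consistent(self) -> bool:
        return self.best_gate is not None

    @property
    def gate_label(self) -> str:
        return self.best_gate.expr if self.best_gate else INCONSISTENT


def match_counts(
    counts: TripletCounts,
    triplet: Optional[Triplet] = None,
    min_score: Optional[Fraction] = None,
) -> GateMatch:
    """Select the best gate from tallied counts (tie -> inconsistent).

    ``min_score``, when given, additionally marks matches whose maximal
    score falls below it as inconsistent (the optional "all gates score
    low" branch; off by default).
    """
    nums = _numerators(counts)
    den = 1
    for m in counts.m_i:
        den *= 2 + m
    best = max(nums)
    top = [i for i, v in enumerate(nums) if v == best]
    score = Fraction(best, den)
    gate: Optional[Gate] = _GATES[top[0]] if len(top) == 1 else None
    if gate is not None and min_score is not None and score < min_score:
        gate = None
    return GateMatch(
        counts=counts,
        best_gate=gate,
        score=score,
        per_gate_scores=tuple(Fraction(v, den) for v in nums),
        triplet=triplet,
    )


def match_gate(
    x,
    y,
    z,
    triplet: Optional[Triplet] = None,
    min_score: Optional[Fraction] = None,
) -> GateMatch:
    """Tabulate three binary vectors and select the best-matching gate."""
    return match_counts(tabulate_counts(x, y, z), triplet=triplet, min_score=min_score)


def _best_gate_id_fast(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> int:
    """Gate id of the unique best match, or -1 for inconsistent.

    Majority-vote shortcut used in the permutation inner loop: the maximal
    gate takes, at each input combination, the majority target output; a
    tie in any combination ties the maximum (the product factorizes over
    combinations).  Equivalent to the exact numerator comparison.
    """
    combo = (x << 1) | y
    m_i = np.bincount(combo, minlength=4)
    n1_i = np.bincount(combo, weights=z, minlength=4).astype(np.int64)
    ones = 2 * n1_i
    if (ones == m_i).any():
        return -1
    bits = ones > m_i
    return int((bits[0] << 3) | (bits[1] << 2) | (bits[2] << 1) | bits[3])


def permutation_score(
    triplet: Triplet,
    gate: Gate,
    binmat: pd.DataFrame,
    M: int = 1000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    threshold: float = 0.1,
) -> float:
    """Fraction of target-replacement triplets re-matching the same gate.

    The target is replaced by a gene drawn (with replacement) from all genes
    in the binarized matrix except RF1, RF2 and the original target, M times;
    a replacement counts when its own match is gate-consistent *and* matches
    ``gate``.  A high score means random genes reproduce the call, flagging
    it as spurious; calls with score >= ``threshold`` should be discarded.
    Deterministic for a fixed seed.
    """
    if M <= 0:
        raise ValueError(f"M must be positive, got {M}")
    pool = binmat.index.difference([triplet.rf1, triplet.rf2, triplet.target])
    if len(pool) == 0:
        raise ValueError("empty replacement pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = binmat.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(binmat.index)}
    x = values[row_of[triplet.rf1]]
    y = values[row_of[triplet.rf2]]
    pool_rows = np.array([row_of[g] for g in pool])
    picks = rng.choice(pool_rows, size=M, replace=True)
    hits = 0
    for row in picks:
        z = values[row]
        keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
        xi = x[keep].astype(np.int64)
        yi = y[keep].astype(np.int64)
        zi = z[keep].astype(np.int64)
        if _best_gate_id_fast(xi, yi, zi) == gate.id:
            hits += 1
    return hits / M
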