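"""Gate-frequency summaries and hypergeometric gate enrichment.

Given a subset of triplets (for instance, all triplets whose RF1 is a
particular factor, or all feed-forward loops) the enrichment of a gate g in
that subset is scored against the full triplet collection by the
hypergeometric tail

    p(k_g, k, K_g, N) = sum_{i = k_g + 1}^{k} C(K_g, i) C(N - K_g, k - i) / C(N, k)

where k is the subset size, k_g the subset triplets consistent with g, K_g
the total triplets consistent with g, and N the total number of triplets.
The default tail is *strict* (probability of strictly exceeding the observed
count, the form above); the conventional inclusive one-sided test adds the
i = k_g term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gates import enumerate_gates
from .scoring import GateMatch

__all__ = ["EnrichmentInput", "hypergeom_enrichment", "summarize_gate_distribution"]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one gate-in-subset enrichment test."""

    k_g: int  # subset triplets consistent with the gate
    k: int    # subset size
    K_g: int  # all triplets consistent with the gate
    N: int    # all triplets

    def __post_init__(self):
        if not (0 <= self.k_g <= min(self.k, self.K_g) and self.k <= self.N
                and self.K_g <= self.N):
            raise ValueError(
                f"invalid enrichment counts: k_g={self.k_g}, k={self.k}, "
                f"K_g={self.K_g}, N={self.N}"
            )


def hypergeom_enrichment(e: EnrichmentInput, tail: str = "strict") -> float:
    """Hypergeometric enrichment p-value for a gate within a triplet subset.

    ``tail="strict"`` is the probability of drawing strictly more than k_g
    gate-consistent triplets in a random size-k subset; ``"inclusive"`` adds
    the probability mass at exactly k_g.
    """
    rv = hypergeom(M=e.N, n=e.K_g, N=e.k)
    if tail == "strict":
        return float(rv.sf(e.k_g))
    if tail == "inclusive":
        return float(rv.sf(e.k_g - 1))
    raise ValueError(f"tail must be 'strict' or 'inclusive', got {tail!r}")


def summarize_gate_distribution(
    matches: Sequence[GateMatch],
    subset_filter: Optional[Callable[[GateMatch], bool]] = None,
    tail: str = "strict",
) -> pd.DataFrame:
    """Per-gate counts in a subset with enrichment against the full set.

    ``matches`` is the background collection (all scored triplets);
    ``subset_filter`` selects the subset (default: everything).  Returns one
    row per gate with columns gate, count (k_g), k, K_g, N, p_value and
    minus_log10_p.  Inconsistent triplets contribute to k and N but to no
    gate's count.
    """
    matches = list(matches)
    subset = [m for m in matches if subset_filter is None or subset_filter(m)]
    N, k = len(matches), len(subset)
    rows = []
    for gate in enumerate_gates():
        K_g = sum(1 for m in matches if m.best_gate is gate)
        k_g = sum(1 for m in subset if m.best_gate is gate)
        if N == 0:
            continue
        p = hypergeom_enrichment(EnrichmentInput(k_g, k, K_g, N), tail=tail)
        rows.append(
            {
                "gate": gate.expr,
                "count": k_g,
                "k": k,
                "K_g": K_g,
                "N": N,
                "p_value": p,
                "minus_log10_p": -np.log10(p) if p > 0 else np.inf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gate", "count", "k", "K_g", "N", "p_value", "minus_log10_p"],
    )
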