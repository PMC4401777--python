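"""Synthetic fixtures with planted gate logic.

Every stage of the pipeline is testable without external data: the
generator plants a known gate for each target — the target's binary state
is the gate function of its two regulators' Bernoulli states, corrupted by
symmetric bit-flip noise — and writes the same edge-list / expression-matrix
formats the pipeline reads, together with a ground-truth table.

Defaults mirror the regime the method is characterized under: 60 samples,
regulator on-probability 0.5, 5% bit-flip noise; continuous mode maps bits
to Gaussians whose means are four standard deviations apart so two-means
binarization recovers the bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gates import Gate, enumerate_gates
from .network import Triplet

__all__ = ["SimConfig", "simulate_triplet", "simulate_dataset", "write_dataset"]

# continuous emission: bit b -> Normal(MU[b], SIGMA); separation 4*SIGMA
MU_OFF, MU_ON, SIGMA = 2.0, 6.0, 1.0


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one planted-gate triplet simulation."""

    gate: Gate
    n_samples: int = 60
    input_p: float = 0.5
    noise: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.input_p <= 1):
            raise ValueError(f"input_p must be in [0, 1], got {self.input_p}")
        if not (0 <= self.noise <= 0.5):
            raise ValueError(f"noise must be in [0, 0.5], got {self.noise}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_triplet(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Draw (x, y, z): Bernoulli inputs, gated output with bit-flip noise."""
    rng = rng if rng is not None else _rng(cfg.seed)
    x = (rng.random(cfg.n_samples) < cfg.input_p).astype(np.int64)
    y = (rng.random(cfg.n_samples) < cfg.input_p).astype(np.int64)
    outputs = np.array(cfg.gate.outputs, dtype=np.int64)
    z = outputs[(x << 1) | y]
    flips = rng.random(cfg.n_samples) < cfg.noise
    z = np.where(flips, 1 - z, z)
    return x, y, z


def simulate_dataset(
    n_rf: int,
    n_targets: int,
    targets_per_pair: Optional[int] = None,
    gate_assignment: Union[dict, Sequence[Gate], str] = "random",
    continuous: bool = False,
    seed: Optional[int] = None,
    n_samples: int = 60,
    input_p: float = 0.5,
    noise: float = 0.05,
    n_noise_genes: int = 0,
):
    """Generate a planted-gate dataset: network, expression, ground truth.

    Regulator pairs are taken round-robin from all C(n_rf, 2) unordered
    pairs (``targets_per_pair`` caps how many targets a pair receives);
    each target's planted gate comes from ``gate_assignment`` — a mapping
    target -> Gate, a sequence cycled over targets, or ``"random"`` (uniform
    over the 16 gates).  ``n_noise_genes`` appends independent
    Bernoulli(input_p) genes with no regulators, useful as a permutation
    pool.  Continuous mode emits Gaussian values per bit instead of 0/1.

    Returns ``(edges, expression, truth)``: an edge-list DataFrame
    (regulator, target), a genes x samples DataFrame, and a ground-truth
    DataFrame (target, rf1, rf2, planted_gate).
    """
    if n_rf < 2 or n_targets < 1:
        raise ValueError("need n_rf >= 2 and n_targets >= 1")
    rng = _rng(seed)
    gates = enumerate_gates()
    rfs = [f"RF{i:03d}" for i in range(1, n_rf + 1)]
    pairs = list(combinations(rfs, 2))
    if targets_per_pair is not None and n_targets > targets_per_pair * len(pairs):
        raise ValueError("n_targets exceeds targets_per_pair * number of pairs")

    # per-RF activity series
    series: dict[str, np.ndarray] = {
        rf: (rng.random(n_samples) < input_p).astype(np.int64) for rf in rfs
    }

    edges, truth_rows = [], []
    for t_idx in range(n_targets):
        pair = pairs[t_idx % len(pairs)]
        target = f"T{t_idx + 1:04d}"
        if isinstance(gate_assignment, str) and gate_assignment == "random":
            gate = gates[rng.integers(16)]
        elif isinstance(gate_assignment, dict):
            gate = gate_assignment[target]
        else:
            gate = gate_assignment[t_idx % len(gate_assignment)]
        x, y = series[pair[0]], series[pair[1]]
        z = np.array(gate.outputs, dtype=np.int64)[(x << 1) | y]
        flips = rng.random(n_samples) < noise
        series[target] = np.where(flips, 1 - z, z)
        edges.append((pair[0], target))
        edges.append((pair[1], target))
        truth_rows.append(
            {"target": target, "rf1": pair[0], "rf2": pair[1],
             "planted_gate": gate.expr}
        )
    for i in range(n_noise_genes):
        series[f"N{i + 1:04d}"] = (rng.random(n_samples) < input_p).astype(np.int64)

    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    matrix = pd.DataFrame(
        np.vstack(list(series.values())), index=list(series.keys()),
        columns=sample_ids, dtype=float,
    )
    if continuous:
        bits = matrix.to_numpy()
        values = np.where(bits == 1, MU_ON, MU_OFF) + rng.normal(
            0.0, SIGMA, size=bits.shape
        )
        matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)

    edges_df = pd.DataFrame(edges, columns=["regulator", "target"])
    truth_df = pd.DataFrame(truth_rows, columns=["target", "rf1", "rf2", "planted_gate"])
    return edges_df, matrix, truth_df


def write_dataset(out_dir, edges: pd.DataFrame, matrix: pd.DataFrame,
                  truth: pd.DataFrame) -> dict[str, Path]:
    """Write edges.tsv / expression.tsv / truth.tsv in pipeline formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "expression": out / "expression.tsv",
        "truth": out / "truth.tsv",
    }
    edges.to_csv(paths["edges"], sep="\t", header=False, index=False)
    matrix.to_csv(paths["expression"], sep="\t", index_label="gene")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
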