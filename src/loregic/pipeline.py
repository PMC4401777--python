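"""End-to-end driver: network + expression in, scored triplet tables out.

Stages: load the edge list and expression matrix; preprocess and binarize
(or validate user-supplied binary data); enumerate co-regulating triplets;
match each against the 16 gates with consistency scores; optionally run the
permutation spuriousness filter; annotate feed-forward loops; summarize the
per-gate distribution with hypergeometric enrichment.  Every stage logs its
counts and the whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import network as network_mod
from . import scoring as scoring_mod
from .network import RegulatoryNetwork, Triplet
from .scoring import INCONSISTENT, GateMatch

__all__ = ["RunConfig", "RunResult", "run_loregic", "score_network"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (mirrors the CLI flags)."""

    network: str
    expression: str
    out_dir: str = "loregic_out"
    binary: bool = False                     # expression already 0/1
    preprocess: str = "none"                 # none | log1p_standardize | center_per_sample
    rf_class: Optional[str] = None
    rf1_class: Optional[str] = None
    rf2_class: Optional[str] = None
    role_order: str = "lex"
    permutations: int = 1000                 # 0 disables the filter
    perm_threshold: float = 0.1
    min_score: Optional[float] = None
    seed: int = 0
    score_precision: int = 6
    network_header: bool = False


@dataclass
class RunResult:
    """Tables and counters produced by one run."""

    triplet_table: pd.DataFrame
    gate_distribution: pd.DataFrame
    matches: list[GateMatch]
    stage_counts: dict[str, int] = field(default_factory=dict)


def score_network(
    net: RegulatoryNetwork,
    binmat: pd.DataFrame,
    triplets: Optional[list[Triplet]] = None,
    permutations: int = 0,
    perm_threshold: float = 0.1,
    min_score: Optional[float] = None,
    seed: Optional[int] = None,
    excluded_genes: Optional[set[str]] = None,
) -> list[GateMatch]:
    """Match every scorable triplet of a network against the 16 gates.

    Triplets touching genes absent from the matrix or flagged uninformative
    are skipped (logged).  With ``permutations > 0`` each consistent match
    gets a permutation score and a pass/fail flag at ``perm_threshold``.
    """
    if triplets is None:
        triplets = network_mod.enumerate_triplets(net)
    excluded = excluded_genes or set()
    present = set(binmat.index)
    rng = np.random.default_rng(seed)
    min_score_frac = Fraction(min_score).limit_denominator(10**9) if min_score else None

    values = binmat.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(binmat.index)}
    matches: list[GateMatch] = []
    skipped = 0
    for t in triplets:
        genes = (t.rf1, t.rf2, t.target)
        if any(g not in present or g in excluded for g in genes):
            skipped += 1
            continue
        m = scoring_mod.match_gate(
            values[row_of[t.rf1]],
            values[row_of[t.rf2]],
            values[row_of[t.target]],
            triplet=t,
            min_score=min_score_frac,
        )
        if m.consistent and permutations > 0:
            m.permutation_p = scoring_mod.permutation_score(
                t, m.best_gate, binmat, M=permutations, seed=rng
            )
            m.passed_filter = m.permutation_p < perm_threshold
        matches.append(m)
    if skipped:
        logger.info("skipped %d triplets with missing/uninformative genes", skipped)
    return matches


def matches_to_table(
    matches: list[GateMatch],
    net: Optional[RegulatoryNetwork] = None,
    precision: int = 6,
) -> pd.DataFrame:
    """Render matches as the standard output table.

    Columns: RF1, RF2, target, matched_logic_gate, consistency_score,
    permutation_score, is_ffl.
    """
    rows = []
    for m in matches:
        t = m.triplet
        rows.append(
            {
                "RF1": t.rf1 if t else "",
                "RF2": t.rf2 if t else "",
                "target": t.target if t else "",
                "matched_logic_gate": m.gate_label,
                "consistency_score": round(float(m.score), precision),
                "permutation_score": (
                    round(m.permutation_p, precision)
                    if m.permutation_p is not None else ""
                ),
                "is_ffl": (
                    network_mod.is_ffl(t, net) if (t and net is not None) else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["RF1", "RF2", "target", "matched_logic_gate",
                 "consistency_score", "permutation_score", "is_ffl"],
    )


def run_loregic(cfg: RunConfig) -> RunResult:
    """Run the full pipeline and write its output tables.

    Writes ``triplets.tsv`` (one row per scorable triplet),
    ``gate_distribution.tsv`` (per-gate counts of filter-passing consistent
    triplets with enrichment) and ``run_log.txt`` under ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    net = network_mod.load_network(
        cfg.network, class_map=cfg.rf_class, header=cfg.network_header
    )
    counts["edges"] = len(net)

    matrix = expression_mod.load_expression(cfg.expression)
    if cfg.binary:
        binmat = expression_mod.validate_binary(matrix)
        uninformative: list[str] = []
    else:
        matrix = expression_mod.preprocess(matrix, cfg.preprocess)
        binmat, uninformative = expression_mod.binarize_two_cluster(matrix)
    counts["genes"] = binmat.shape[0]
    counts["samples"] = binmat.shape[1]
    counts["uninformative_genes"] = len(uninformative)

    triplets = network_mod.enumerate_triplets(
        net,
        rf1_class=cfg.rf1_class,
        rf2_class=cfg.rf2_class,
        role_order=cfg.role_order,
        seed=cfg.seed,
    )
    counts["triplets"] = len(triplets)
    if not triplets:
        logger.warning("no triplets enumerated; writing empty tables")

    matches = score_network(
        net,
        binmat,
        triplets=triplets,
        permutations=cfg.permutations,
        perm_threshold=cfg.perm_threshold,
        min_score=cfg.min_score,
        seed=cfg.seed,
        excluded_genes=set(uninformative),
    )
    counts["scored"] = len(matches)
    counts["consistent"] = sum(1 for m in matches if m.consistent)
    counts["filter_passed"] = sum(1 for m in matches if m.passed_filter)

    table = matches_to_table(matches, net=net, precision=cfg.score_precision)
    table.to_csv(out_dir / "triplets.tsv", sep="\t", index=False)

    # distribution over filter-passing matches, enrichment vs all scored
    kept_ids = {
        id(m) for m in matches
        if m.consistent and (cfg.permutations == 0 or m.passed_filter)
    }
    dist = enrichment_mod.summarize_gate_distribution(
        matches, subset_filter=lambda m: id(m) in kept_ids
    )
    dist.to_csv(out_dir / "gate_distribution.tsv", sep="\t", index=False)

    log_path = out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        for key, value in counts.items():
            fh.write(f"{key}\t{value}\n")
    for key, value in counts.items():
        logger.info("%s: %d", key, value)

    return RunResult(
        triplet_table=table,
        gate_distribution=dist,
        matches=matches,
        stage_counts=counts,
    )
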