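"""Promoter PWM scanning and indirect-binding classification.

A TF can cooperate in a gate-consistent triplet without binding the target's
promoter directly, acting instead through protein-protein interaction with a
bound partner.  This module flags such candidates: the promoter window
upstream of each target's transcription start site is scanned with each
regulator's position weight matrix (PWM), and a gate-consistent triplet in
which exactly one TF has zero motif hits is classified as having an
indirectly bound TF.

A window of length L scores sum of the per-position weight of the observed
base; with S_min / S_max the minimal / maximal achievable window scores, a
hit requires (score - S_min) / (S_max - S_min) >= min_score_frac (default
0.8, the "80% PWM similarity" convention).  Both strands are scanned by
default and windows containing N never hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import GateMatch

__all__ = [
    "PWM",
    "read_pwms",
    "load_gene_coords",
    "extract_promoters",
    "scan_pwm",
    "classify_binding",
    "classify_triplets",
]

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4 x L weights over A, C, G, T (row order)."""

    name: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be 4 x L, L >= 1")
        if not np.isfinite(m).all():
            raise ValueError(f"PWM {self.name!r}: non-finite weights")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=0))


def read_pwms(path) -> dict[str, PWM]:
    """Parse a JASPAR-like PWM file into {name: PWM}.

    Blocks start with a ``>name`` header followed by four whitespace-
    delimited rows in A, C, G, T order; rows may carry a leading base letter
    and surrounding brackets (``A [ 4 19 0 ]``).
    """
    pwms: dict[str, PWM] = {}
    name: Optional[str] = None
    rows: list[list[float]] = []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"PWM {name!r}: expected 4 rows, got {len(rows)}")
        if len({len(r) for r in rows}) != 1:
            raise ValueError(f"PWM {name!r}: ragged rows")
        pwms[name] = PWM(name=name, matrix=np.array(rows, dtype=float))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name, rows = line[1:].split()[0], []
            continue
        if name is None:
            raise ValueError(f"{path}: matrix row before any '>name' header")
        tokens = line.replace("[", " ").replace("]", " ").split()
        if tokens and tokens[0].upper() in _BASE_INDEX and not _is_number(tokens[0]):
            expected = _ALPHABET[len(rows)]
            if tokens[0].upper() != expected:
                raise ValueError(
                    f"PWM {name!r}: row labelled {tokens[0]!r} where {expected} expected"
                )
            tokens = tokens[1:]
        rows.append([float(t) for t in tokens])
    flush()
    if not pwms:
        raise ValueError(f"{path}: no PWMs found")
    return pwms


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_gene_coords(path) -> pd.DataFrame:
    """Read BED6-style gene coordinates (chrom, start, end, gene, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand column must be '+' or '-'")
    return df


def extract_promoters(genome, coords: pd.DataFrame, window: int) -> dict[str, str]:
    """Promoter windows upstream of each gene's TSS (0-based half-open).

    ``genome`` is a FASTA path (read via pyfaidx) or a {chrom: sequence}
    mapping.  Plus-strand genes take reference slice [TSS - window, TSS)
    with TSS = start; minus-strand genes take the reverse complement of
    [TSS, TSS + window) with TSS = end.  Windows are clipped at chromosome
    bounds (with a warning); genes on missing chromosomes are skipped.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fasta = Fasta(str(genome))
        chroms = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    else:
        chroms = {k: str(v).upper() for k, v in dict(genome).items()}

    promoters: dict[str, str] = {}
    for row in coords.itertuples(index=False):
        seq = chroms.get(row.chrom)
        if seq is None:
            logger.warning("gene %s: chromosome %s absent, skipped", row.gene, row.chrom)
            continue
        if row.strand == "+":
            lo, hi = row.start - window, row.start
            clipped_lo, clipped_hi = max(lo, 0), min(hi, len(seq))
            piece = seq[clipped_lo:clipped_hi]
        else:
            lo, hi = row.end, row.end + window
            clipped_lo, clipped_hi = max(lo, 0), min(hi, len(seq))
            piece = seq[clipped_lo:clipped_hi].translate(_COMPLEMENT)[::-1]
        if (clipped_lo, clipped_hi) != (lo, hi):
            logger.warning(
                "gene %s: promoter window clipped to chromosome bounds", row.gene
            )
        promoters[row.gene] = piece
    return promoters


def _window_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Scores of every length-L window on the given strand; NaN where an N sits."""
    L = pwm.length
    if len(seq) < L:
        return np.empty(0)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    n_win = len(seq) - L + 1
    offsets = np.arange(L)
    win_idx = idx[np.arange(n_win)[:, None] + offsets]  # n_win x L
    valid = (win_idx >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        safe = np.where(win_idx < 0, 0, win_idx)
        scores[valid] = pwm.matrix[safe, offsets].sum(axis=1)[valid]
    return scores


def scan_pwm(
    pwm: PWM,
    seq: str,
    min_score_frac: float = 0.8,
    strand: str = "both",
    threshold_mode: str = "minmax",
) -> int:
    """Count PWM hits in a sequence.

    ``threshold_mode="minmax"`` (default) calls a hit when the window score,
    min-max normalized between the worst and best achievable scores, reaches
    ``min_score_frac``; ``"absolute"`` requires score >= min_score_frac *
    S_max (only meaningful for non-negative weight matrices).
    """
    if not (0 < min_score_frac <= 1):
        raise ValueError(f"min_score_frac must be in (0, 1], got {min_score_frac}")
    if strand not in ("both", "forward"):
        raise ValueError(f"strand must be 'both' or 'forward', got {strand!r}")
    seq = seq.upper()
    s_max = pwm.matrix.max(axis=0).sum()
    s_min = pwm.matrix.min(axis=0).sum()
    if threshold_mode == "minmax":
        span = s_max - s_min
        cutoff = s_min + min_score_frac * span if span > 0 else s_min
    elif threshold_mode == "absolute":
        cutoff = min_score_frac * s_max
    else:
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")

    strands = [seq]
    if strand == "both":
        strands.append(seq.translate(_COMPLEMENT)[::-1])
    hits = 0
    for s in strands:
        scores = _window_scores(pwm, s)
        if scores.size:
            hits += int(np.nansum(scores >= cutoff))
    return hits


def classify_binding(
    hits_rf1: Optional[int], hits_rf2: Optional[int]
) -> str:
    """Classify a gate-consistent triplet by promoter motif presence.

    Returns one of ``both_direct``, ``rf1_indirect``, ``rf2_indirect``,
    ``both_missing`` or ``unscorable`` (a None hit count marks a regulator
    without an available PWM).  A regulator with zero hits is a candidate
    for indirect, protein-protein-interaction-mediated regulation.
    """
    if hits_rf1 is None or hits_rf2 is None:
        return "unscorable"
    if hits_rf1 > 0 and hits_rf2 > 0:
        return "both_direct"
    if hits_rf1 == 0 and hits_rf2 == 0:
        return "both_missing"
    return "rf1_indirect" if hits_rf1 == 0 else "rf2_indirect"


def classify_triplets(
    matches: Sequence[GateMatch],
    promoters: dict[str, str],
    pwms: dict[str, PWM],
    min_score_frac: float = 0.8,
    strand: str = "both",
    threshold_mode: str = "minmax",
) -> pd.DataFrame:
    """Motif-based binding classification for gate-consistent triplets.

    One output row per consistent match with a known target promoter:
    TF1, TF2, target, per-TF promoter hit counts, the matched gate and the
    binding category.  Regulators without a PWM yield None counts and the
    ``unscorable`` category (logged).
    """
    rows = []
    for m in matches:
        if not m.consistent or m.triplet is None:
            continue
        promoter = promoters.get(m.triplet.target)
        if promoter is None:
            logger.warning("target %s: no promoter sequence, skipped", m.triplet.target)
            continue
        counts: list[Optional[int]] = []
        for rf in (m.triplet.rf1, m.triplet.rf2):
            pwm = pwms.get(rf)
            if pwm is None:
                logger.warning("regulator %s: no PWM available", rf)
                counts.append(None)
            else:
                counts.append(
                    scan_pwm(pwm, promoter, min_score_frac, strand, threshold_mode)
                )
        rows.append(
            {
                "TF1": m.triplet.rf1,
                "TF2": m.triplet.rf2,
                "target": m.triplet.target,
                "TF1_hit_count": counts[0],
                "TF2_hit_count": counts[1],
                "gate": m.best_gate.expr,
                "category": classify_binding(counts[0], counts[1]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "TF1", "TF2", "target",
            "TF1_hit_count", "TF2_hit_count", "gate", "category",
        ],
    )
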