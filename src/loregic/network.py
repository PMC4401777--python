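"""Regulatory-network loading, triplet enumeration and feed-forward loops.

The regulatory network is a directed graph of regulator -> target edges,
optionally annotated with a regulator class (``TF``, ``miRNA`` or ``distTF``).
The unit of analysis is the *triplet* (RF1, RF2, T): two distinct regulators
sharing a common target.  A target may itself be a regulator in other
triplets.  A triplet is a feed-forward loop (FFL) when RF1 also regulates
RF2.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Triplet",
    "RegulatoryNetwork",
    "load_network",
    "load_class_map",
    "enumerate_triplets",
    "is_ffl",
    "has_reverse_edge",
]

logger = logging.getLogger(__name__)


class Triplet(NamedTuple):
    """Ordered (RF1, RF2, target) identifier triple."""

    rf1: str
    rf2: str
    target: str


class RegulatoryNetwork:
    """Directed regulator -> target graph with optional regulator classes."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        rf_class: Optional[dict[str, str]] = None,
    ):
        self.graph = nx.DiGraph()
        self.graph.add_edges_from(edges)
        self.rf_class = dict(rf_class) if rf_class else {}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    @property
    def regulators(self) -> set[str]:
        return {u for u, _ in self.graph.edges()}

    @property
    def targets(self) -> set[str]:
        return {v for _, v in self.graph.edges()}

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def class_of(self, gene: str) -> Optional[str]:
        return self.rf_class.get(gene)

    def __len__(self) -> int:
        return self.graph.number_of_edges()


def load_class_map(path) -> dict[str, str]:
    """Read a two-column TSV of (gene, class) into a dict."""
    classes: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}"
            )
        classes[fields[0].strip()] = fields[1].strip()
    return classes


def load_network(path, class_map=None, header: bool = False) -> RegulatoryNetwork:
    """Load a regulator -> target edge list from a two-column TSV.

    Parameters
    ----------
    path : path-like
        Tab-separated file, one ``regulator<TAB>target`` edge per line.
    class_map : path-like, optional
        Two-column TSV mapping regulator id to class (TF / miRNA / distTF).
    header : bool
        Skip the first line when True.

    Duplicate edges are collapsed; a malformed line raises ``ValueError``
    naming the line number.
    """
    lines = Path(path).read_text().splitlines()
    if header:
        lines = lines[1:]
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines, start=2 if header else 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}: {line!r}"
            )
        edges.append((fields[0].strip(), fields[1].strip()))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    classes = load_class_map(class_map) if class_map else None
    net = RegulatoryNetwork(edges, classes)
    logger.info(
        "loaded network: %d edges, %d regulators, %d targets",
        len(net), len(net.regulators), len(net.targets),
    )
    return net


def _assign_roles(
    a: str,
    b: str,
    net: RegulatoryNetwork,
    rf1_class: Optional[str],
    rf2_class: Optional[str],
    rng: Optional[np.random.Generator],
) -> Optional[tuple[str, str]]:
    """Order an unordered regulator pair into (rf1, rf2), or None to drop."""
    ca, cb = net.class_of(a), net.class_of(b)
    if rf1_class or rf2_class:
        # explicit class filter: roles follow the requested classes
        if rf1_class and rf2_class:
            if ca == rf1_class and cb == rf2_class:
                return (a, b) if rf1_class != rf2_class else _order(a, b, rng)
            if cb == rf1_class and ca == rf2_class:
                return (b, a) if rf1_class != rf2_class else _order(a, b, rng)
            return None
        want, slot = (rf1_class, 0) if rf1_class else (rf2_class, 1)
        if ca == want and cb != want:
            return (a, b) if slot == 0 else (b, a)
        if cb == want and ca != want:
            return (b, a) if slot == 0 else (a, b)
        return None
    # no filter: non-TF regulator (miRNA, distTF) takes the RF1 slot when
    # the two classes differ, matching the miRNA-TF / distTF-TF convention
    if ca and cb and ca != cb:
        if ca != "TF" and cb == "TF":
            return (a, b)
        if cb != "TF" and ca == "TF":
            return (b, a)
    return _order(a, b, rng)


def _order(a: str, b: str, rng: Optional[np.random.Generator]) -> tuple[str, str]:
    if rng is not None and rng.random() < 0.5:
        return (b, a)
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def enumerate_triplets(
    net: RegulatoryNetwork,
    rf1_class: Optional[str] = None,
    rf2_class: Optional[str] = None,
    role_order: str = "lex",
    seed: Optional[int] = None,
) -> list[Triplet]:
    """All (RF1, RF2, T) triplets where RF1 and RF2 co-regulate T.

    One triplet is emitted per unordered regulator pair per shared target.
    Targets that are themselves regulators are included.  Pairs involving
    the target itself (self-regulation) are dropped with a logged count.

    Role assignment: by default deterministic lexicographic (``rf1 < rf2``);
    ``role_order="random"`` reproduces a seeded random assignment.  When the
    two regulators carry different class labels the non-TF class always takes
    the RF1 slot; explicit ``rf1_class`` / ``rf2_class`` filters restrict and
    orient pairs by class.
    """
    if role_order not in ("lex", "random"):
        raise ValueError(f"role_order must be 'lex' or 'random', got {role_order!r}")
    rng = np.random.default_rng(seed) if role_order == "random" else None
    triplets: list[Triplet] = []
    dropped_self = 0
    for target in sorted(net.targets):
        regs = sorted(u for u in net.graph.predecessors(target))
        if target in regs:
            regs.remove(target)
            dropped_self += 1
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                roles = _assign_roles(regs[i], regs[j], net, rf1_class, rf2_class, rng)
                if roles is not None:
                    triplets.append(Triplet(roles[0], roles[1], target))
    if dropped_self:
        logger.info("dropped %d self-regulation edges from triplet enumeration",
                    dropped_self)
    logger.info("enumerated %d triplets", len(triplets))
    return triplets


def is_ffl(t: Triplet, net: RegulatoryNetwork) -> bool:
    """True when RF1 also regulates RF2 (the directional FFL definition)."""
    return net.has_edge(t.rf1, t.rf2)


def has_reverse_edge(t: Triplet, net: RegulatoryNetwork) -> bool:
    """True when RF2 regulates RF1 (reported alongside the FFL flag)."""
    return net.has_edge(t.rf2, t.rf1)
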