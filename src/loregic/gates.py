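"""The sixteen two-input one-output Boolean logic gates.

A regulatory triplet RF1-RF2-T is modelled as a two-input one-output logic
gate: the binarized activities of the two regulators are the inputs and the
target's binary state is the output.  A gate is fully described by its truth
table over the four input combinations

    v1 = (0, 0),  v2 = (0, 1),  v3 = (1, 0),  v4 = (1, 1)

so there are exactly 2**4 = 16 gates.  Each gate carries a canonical
algebraic expression over ``{RF1, RF2, ~, *, +}`` (``~`` NOT, ``*`` AND,
``+`` OR) which is the primary identifier in all output tables; the common
electronics names (AND, OR, XOR, ...) are aliases.

Gate ids are the truth-table output vector read most-significant-bit first:
``id = 8*f(0,0) + 4*f(0,1) + 2*f(1,0) + f(1,1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Gate",
    "INPUT_COMBOS",
    "enumerate_gates",
    "gate_output",
    "gate_by_expr",
    "gate_by_alias",
    "gate_by_outputs",
    "symmetric_partner",
    "complement_gate",
    "evaluate_expr",
    "FFL_COHERENT_TYPES",
]

#: The four input combinations (RF1, RF2), in the fixed order v1..v4.
INPUT_COMBOS: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class Gate:
    """One two-input Boolean function.

    Attributes
    ----------
    id : int
        Truth-table output vector read as a 4-bit number, MSB first.
    outputs : tuple[int, int, int, int]
        ``(f(0,0), f(0,1), f(1,0), f(1,1))``.
    expr : str
        Canonical algebraic expression, e.g. ``"T=RF1*RF2"``.
    alias : str or None
        Common electronics name where one exists (AND, OR, XOR, ...).
    """

    id: int
    outputs: tuple[int, int, int, int]
    expr: str
    alias: Optional[str] = field(default=None, compare=False)

    def __call__(self, a: int, b: int) -> int:
        return gate_output(self, a, b)

    @property
    def name(self) -> str:
        return self.alias or self.expr

    @property
    def is_input_sensitive(self) -> bool:
        """True unless the output is constant over the four combinations."""
        return len(set(self.outputs)) > 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.expr


def evaluate_expr(expr: str, a: int, b: int) -> int:
    """Evaluate a canonical gate expression on a single input pair.

    Supports the sum-of-products grammar used by the canonical strings:
    optional ``T=`` prefix, ``+``-separated terms, ``*``-separated factors,
    factors being ``RF1``, ``RF2``, ``~RF1``, ``~RF2``, ``0`` or ``1``.
    """
    body = expr.split("=", 1)[-1].strip()
    env = {"RF1": a, "RF2": b}
    result = 0
    for term in body.split("+"):
        value = 1
        for factor in term.split("*"):
            factor = factor.strip()
            if factor in ("0", "1"):
                value &= int(factor)
            elif factor.startswith("~"):
                value &= 1 - env[factor[1:]]
            else:
                value &= env[factor]
        result |= value
    return result


# id -> (expr, alias); id bits are (f00, f01, f10, f11) MSB-first.
_GATE_TABLE: dict[int, tuple[str, Optional[str]]] = {
    0: ("T=0", None),
    1: ("T=RF1*RF2", "AND"),
    2: ("T=RF1*~RF2", None),
    3: ("T=RF1", None),
    4: ("T=~RF1*RF2", None),
    5: ("T=RF2", None),
    6: ("T=RF1*~RF2+~RF1*RF2", "XOR"),
    7: ("T=RF1+RF2", "OR"),
    8: ("T=~RF1*~RF2", "NOR"),
    9: ("T=RF1*RF2+~RF1*~RF2", "XNOR"),
    10: ("T=~RF2", None),
    11: ("T=RF1+~RF2", None),
    12: ("T=~RF1", None),
    13: ("T=~RF1+RF2", None),
    14: ("T=~RF1+~RF2", "NAND"),
    15: ("T=1", None),
}


def _outputs_of(gate_id: int) -> tuple[int, int, int, int]:
    return ((gate_id >> 3) & 1, (gate_id >> 2) & 1, (gate_id >> 1) & 1, gate_id & 1)


_GATES: tuple[Gate, ...] = tuple(
    Gate(id=i, outputs=_outputs_of(i), expr=_GATE_TABLE[i][0], alias=_GATE_TABLE[i][1])
    for i in range(16)
)
_BY_EXPR = {g.expr: g for g in _GATES}
_BY_ALIAS = {g.alias: g for g in _GATES if g.alias}


def enumerate_gates() -> tuple[Gate, ...]:
    """All 16 gates, ordered by id (0 = constant off .. 15 = constant on)."""
    return _GATES


def gate_by_expr(expr: str) -> Gate:
    """Look a gate up by its canonical expression string."""
    key = expr if expr.startswith("T=") else "T=" + expr
    try:
        return _BY_EXPR[key]
    except KeyError:
        raise KeyError(f"unknown gate expression: {expr!r}") from None


def gate_by_alias(alias: str) -> Gate:
    """Look a gate up by its electronics name (AND, OR, XOR, ...)."""
    try:
        return _BY_ALIAS[alias.upper()]
    except KeyError:
        raise KeyError(f"unknown gate alias: {alias!r}") from None


def gate_by_outputs(outputs) -> Gate:
    o = tuple(int(v) for v in outputs)
    if len(o) != 4 or any(v not in (0, 1) for v in o):
        raise ValueError(f"outputs must be four bits, got {outputs!r}")
    return _GATES[(o[0] << 3) | (o[1] << 2) | (o[2] << 1) | o[3]]


def gate_output(g: Gate, a: int, b: int) -> int:
    """Output of gate ``g`` for the input pair ``(a, b)``."""
    if a not in (0, 1) or b not in (0, 1):
        raise ValueError(f"gate inputs must be 0 or 1, got ({a!r}, {b!r})")
    return g.outputs[(a << 1) | b]


def symmetric_partner(g: Gate) -> Gate:
    """The gate obtained by swapping the RF1 and RF2 roles.

    Swapping inputs exchanges the (0,1) and (1,0) rows of the truth table;
    the operation is an involution.  Eight gates are self-symmetric
    (commutative functions such as AND); the remaining eight form four
    symmetric pairs such as ``T=RF1*~RF2`` / ``T=~RF1*RF2``.
    """
    o = g.outputs
    return gate_by_outputs((o[0], o[2], o[1], o[3]))


def complement_gate(g: Gate) -> Gate:
    """The gate with every output bit flipped (an involution)."""
    return gate_by_outputs(tuple(1 - v for v in g.outputs))


#: Static annotation: gates whose logic corresponds to coherent feed-forward
#: loop types as reported in the regulatory-logic literature.  Interpretation
#: shipped as data, not computed: type 1 — RF1 activates RF2 and both activate
#: T; type 2 — RF1 represses both RF2 and T while RF2 activates T; type 4 —
#: RF1 represses RF2, RF2 represses T, RF1 activates T.
FFL_COHERENT_TYPES: dict[str, tuple[int, ...]] = {
    "T=RF1*RF2": (1,),
    "T=RF1": (1, 4),
    "T=RF1+~RF2": (4,),
    "T=~RF1+RF2": (4,),
    "T=RF2": (4,),
    "T=~RF1*RF2": (2,),
    "T=~RF1": (2,),
}
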