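"""Embedded RNA/RNA nearest-neighbor stacking parameters.

The ten Watson-Crick/Watson-Crick stack free energies (dG at 37 C,
kcal/mol) are the standard published RNA nearest-neighbor values
(Xia et al. 1998 measurement set used by the Turner rules).  Stacks in
which one or both pairs are G:U wobbles are scored with a single uniform
term ``WOBBLE_STACK_DG``: wobble stacking is context-dependent in the
full Turner tables, but a constant mid-range value keeps the table small
and swappable while preserving the property that wobble pairs stabilize
less than canonical pairs.  The table is a module-level constant and can
be replaced wholesale by callers that need different parameters.

Conventions: a stack is written 5'-XY-3' paired antiparallel with
3'-X'Y'-5'; ``stack_dg(x1, x2, y1, y2)`` scores the stack whose top
strand reads x1,x2 in 5'->3' order and whose bottom strand reads y1,y2
in 3'->5' order (so x1 pairs y1 and x2 pairs y2).
"""

from __future__ import annotations

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

#: Watson-Crick stack dG37 values, kcal/mol, keyed by (x1, x2, y1, y2)
#: with x1:y1 and x2:y2 paired (top strand 5'->3', bottom strand 3'->5').
#: Only the ten unique values are listed; symmetry fills the rest.
_WC_STACKS = {
    ("A", "A", "U", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("U", "A", "A", "U"): -1.33,
    ("C", "U", "G", "A"): -2.08,
    ("C", "A", "G", "U"): -2.11,
    ("G", "U", "C", "A"): -2.24,
    ("G", "A", "C", "U"): -2.35,
    ("C", "G", "G", "C"): -2.36,
    ("G", "G", "C", "C"): -3.26,
    ("G", "C", "C", "G"): -3.42,
}

#: Uniform stack term applied when either pair of the stack is a G:U wobble.
WOBBLE_STACK_DG = -1.3

#: Free-energy penalty per unpaired (bulged/mismatched) duplex position.
UNPAIRED_PENALTY_DG = 0.5


def is_wc(a: str, b: str) -> bool:
    """True if a:b is a Watson-Crick pair."""
    return (a, b) in WC_PAIRS


def is_wobble(a: str, b: str) -> bool:
    """True if a:b is a G:U wobble pair."""
    return (a, b) in WOBBLE_PAIRS


def can_pair(a: str, b: str, allow_wobble: bool = True) -> bool:
    """True if a:b is an allowed base pair."""
    return is_wc(a, b) or (allow_wobble and is_wobble(a, b))


def stack_dg(x1: str, x2: str, y1: str, y2: str) -> float:
    """Free energy (kcal/mol) of the stack 5'-x1 x2-3' / 3'-y1 y2-5'.

    x1:y1 and x2:y2 must both be canonical or wobble pairs; raises
    ``ValueError`` otherwise.  Uses the strand-flip symmetry
    stack(x1 x2 / y1 y2) == stack(y2 y1 / x2 x1) to resolve entries not
    listed explicitly.
    """
    for a, b in ((x1, y1), (x2, y2)):
        if not can_pair(a, b):
            raise ValueError(f"{a}:{b} is not a canonical or wobble pair")
    if is_wobble(x1, y1) or is_wobble(x2, y2):
        return WOBBLE_STACK_DG
    key = (x1, x2, y1, y2)
    if key in _WC_STACKS:
        return _WC_STACKS[key]
    flipped = (y2, y1, x2, x1)
    return _WC_STACKS[flipped]
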