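"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or direct
table inspection, sharing no scanning/folding/decomposition code with the
package (the thermodynamic stack table is shared where a check is defined
as "under identical scoring").
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from mirprio.energy import stack_dg
from mirprio.seqio import MiRNARecord, UTRRecord

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
PAIRABLE = WC | WOBBLE


def brute_force_scan(
    mirna: MiRNARecord, utr: UTRRecord, max_mismatch: int = 1, max_wobble: int = 1
) -> list[tuple]:
    """Enumerate every hexamer window and count pairs explicitly.

    Returns sorted (start, end, site_class, mismatches, wobbles) tuples.
    """
    seed = mirna.seed
    seq = utr.sequence
    out = []
    for s in range(len(seq) - 5):
        mm = wb = 0
        for k in range(6):
            pair = (seed[k], seq[s + 5 - k])
            if pair in WC:
                continue
            if pair in WOBBLE and wb < max_wobble:
                wb += 1
            else:
                mm += 1
        if mm > max_mismatch:
            continue
        cls, start, end = "6mer-seed", s, s + 6
        if s >= 1 and (mirna.sequence[7], seq[s - 1]) in WC:
            cls, start = "7mer", s - 1
            if s + 6 < len(seq) and seq[s + 6] == "A":
                cls, end = "8mer", s + 7
        out.append((start, end, cls, mm, wb))
    return sorted(out)


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All nested structures (as tuples of pairs) of ``seq``."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple:
        if j - i + 1 <= min_hairpin + 1:
            return ((),)
        results = list(rec(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        results.append(left + ((i, k),) + right)
        return tuple(results)

    return rec(0, len(seq) - 1)


def score_structure(seq: str, pairs) -> float:
    """Stack-only energy of a structure: consecutive stacked pairs only."""
    pset = set(pairs)
    energy = 0.0
    for i, j in pset:
        if (i + 1, j - 1) in pset:
            energy += stack_dg(seq[i], seq[i + 1], seq[j], seq[j - 1])
    return energy


def min_energy_exhaustive(seq: str) -> float:
    return min(score_structure(seq, p) for p in enumerate_structures(seq))


def classify_runs(dotbracket: str) -> dict:
    """Classify every maximal unpaired run by direct pair-table inspection.

    Returns {'hairpin_loop': [len, ...], 'interior_loop': [...], ...} where
    runs belonging to the same loop (interior/multibranch sides) are merged
    into one entry, plus 'n_pairs'.
    """
    pt = {}
    stack = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pt[j] = i
            pt[i] = j
    n = len(dotbracket)
    runs = []
    a = None
    for i in range(n + 1):
        unpaired = i < n and i not in pt
        if unpaired and a is None:
            a = i
        if not unpaired and a is not None:
            runs.append((a, i - 1))
            a = None

    def enclosing(a: int, b: int):
        best = None
        for p in pt:
            q = pt[p]
            if p < q and p < a and q > b:
                if best is None or q - p < best[1] - best[0]:
                    best = (p, q)
        return best

    loops: dict = {}
    exterior = []
    for a, b in runs:
        enc = enclosing(a, b)
        if enc is None:
            exterior.append(b - a + 1)
            continue
        loops.setdefault(enc, []).append((a, b))
    out = {
        "hairpin_loop": [],
        "interior_loop": [],
        "bulge_loop": [],
        "multibranch_loop": [],
        "exterior_segment": exterior,
        "n_pairs": sum(1 for p in pt if p < pt[p]),
    }
    for (p, q), loop_runs in loops.items():
        # count branch pairs directly inside (p, q)
        branches = 0
        k = p + 1
        while k < q:
            if k in pt and pt[k] > k:
                branches += 1
                k = pt[k] + 1
            else:
                k += 1
        total = sum(b - a + 1 for a, b in loop_runs)
        if branches == 0:
            out["hairpin_loop"].append(total)
        elif branches == 1:
            kind = "interior_loop" if len(loop_runs) == 2 else "bulge_loop"
            out[kind].append(total)
        else:
            out["multibranch_loop"].append(total)
    return out


def random_structure(rng: np.random.Generator, n: int, min_hairpin: int = 3) -> str:
    """A random valid dot-bracket string of length n (no pseudoknots)."""

    def gen(n: int) -> str:
        if n < min_hairpin + 2:
            return "." * n
        if rng.random() < 0.5:
            return "." + gen(n - 1)
        k = int(rng.integers(min_hairpin + 1, n))
        return "(" + gen(k - 1) + ")" + gen(n - k - 1)

    return gen(n)


def sequence_for_structure(rng: np.random.Generator, dotbracket: str) -> str:
    """A sequence compatible with a structure: WC partners for pairs."""
    pt = {}
    stack = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pt[stack.pop()] = i
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    seq = [""] * len(dotbracket)
    for i in range(len(dotbracket)):
        if not seq[i]:
            seq[i] = str(rng.choice(list("ACGU")))
            if i in pt:
                seq[pt[i]] = comp[seq[i]]
    return "".join(seq)
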