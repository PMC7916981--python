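"""RNA secondary-structure folding, loop decomposition and site accessibility.

The default folding backend is an internal dynamic-programming folder:
a Nussinov-style nested-structure recursion scored with the embedded
nearest-neighbor stack table (:mod:`mirprio.energy`), minimum hairpin
loop of 3 nt, no pseudoknots.  Unpaired nucleotides and loop closures
carry no penalty, so the minimum free energy is always <= 0 and equals
the best achievable sum of stack terms.  This keeps every folding result
hand-checkable at desk scale; an adapter to the ViennaRNA thermodynamic
engine is provided for callers who want full Turner-model energies, and
any ``sequence -> FoldResult`` callable can be plugged in downstream.

Accessibility around a candidate binding site is assessed the way
target-site accessibility screens do it: the site is folded alone and
jointly with 70 nt of upstream/downstream flank (free-energy gap rule,
>= 10 kcal/mol vs either flank), and the site +/- 30 nt window is folded
and decomposed into loops and stems.  Long single-stranded elements
(destabilising elements, DSE) favor miRNA access; stems are stabilising
elements (SE), and a site-overlapping stem below -6 kcal/mol is flagged
as inhibitory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .energy import can_pair, stack_dg
from .seqio import UTRRecord, extract_window
from .site_scan import BindingSite

MIN_HAIRPIN = 3  # minimum unpaired nucleotides enclosed by a pair
_INF = float("inf")
_EPS = 1e-9

ELEMENT_KINDS = (
    "hairpin_loop",
    "interior_loop",
    "bulge_loop",
    "multibranch_loop",
    "exterior_segment",
    "stem",
)

LABEL_DSE = "DSE"
LABEL_SE = "SE"
LABEL_NEUTRAL = "neutral"


@dataclass(frozen=True)
class DseCutoffs:
    """Minimum element lengths (nt) for the destabilising-element call."""

    hairpin: int = 11
    interior: int = 9
    bulge: int = 7
    multibranch: int = 11
    exterior: int = 11

    def threshold(self, kind: str) -> Optional[int]:
        return {
            "hairpin_loop": self.hairpin,
            "interior_loop": self.interior,
            "bulge_loop": self.bulge,
            "multibranch_loop": self.multibranch,
            "exterior_segment": self.exterior,
        }.get(kind)


@dataclass(frozen=True)
class FoldResult:
    """A single minimum-free-energy structure in dot-bracket notation."""

    sequence: str
    dotbracket: str
    delta_g: float

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError("dot-bracket length must match sequence length")
        parse_dotbracket(self.dotbracket)  # validates balance


@dataclass(frozen=True)
class StructureElement:
    """One loop, exterior segment or stem of a decomposed structure.

    ``length`` counts unpaired nucleotides for loop elements and base
    pairs for stems.  ``positions`` are the 0-based indices comprising
    the element (for stems: all paired indices).
    """

    kind: str
    length: int
    positions: tuple[int, ...]
    element_dg: Optional[float] = None
    label: str = LABEL_NEUTRAL

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class AccessibilityVerdict:
    """Free-energy and structural accessibility calls for one site."""

    site_window_dg: float
    upstream_flank_dg: float
    downstream_flank_dg: float
    energy_gap_pass: bool
    dse_present: bool
    inhibitory_structure: bool
    #: signed differences site - flank window, kcal/mol (reported because
    #: the direction of the gap rule is a configuration concern)
    diff_upstream: float = 0.0
    diff_downstream: float = 0.0
    #: flank lengths actually folded (truncated at UTR boundaries)
    upstream_flank_len: int = 0
    downstream_flank_len: int = 0
    elements: tuple[StructureElement, ...] = ()


class DotBracketError(ValueError):
    """Unbalanced or crossing dot-bracket input."""


def parse_dotbracket(dotbracket: str) -> dict[int, int]:
    """Parse Vienna-dialect dot-bracket into a symmetric pair table.

    Returns a dict mapping each paired index to its partner (both
    directions).  Raises :class:`DotBracketError` at the first offending
    index for unbalanced input or foreign characters.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at index {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise DotBracketError(f"invalid character {ch!r} at index {i}")
    if stack:
        raise DotBracketError(f"unmatched '(' at index {stack[-1]}")
    return pairs


def _stack_matrix(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Pairability mask P[i, j] and stack energies S[i, j].

    ``S[i, j]`` is the stack formed by pairs (i, j) and (i+1, j-1), valid
    only where both are pairable.
    """
    n = len(seq)
    P = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            P[i, j] = can_pair(seq[i], seq[j])
    S = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + MIN_HAIRPIN + 2, n):
            if P[i, j] and P[i + 1, j - 1]:
                S[i, j] = stack_dg(seq[i], seq[i + 1], seq[j], seq[j - 1])
    return P, S


def fold(sequence: str) -> FoldResult:
    """Fold an RNA sequence with the internal stack-scored DP.

    Deterministic: ties are broken toward leaving 5' nucleotides
    unpaired, then toward the 5'-most pairing partner, then toward
    stacked continuation.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    if n < MIN_HAIRPIN + 2:
        return FoldResult(seq, "." * n, 0.0)

    P, S = _stack_matrix(seq)
    # E[i, j]: MFE of segment i..j (inclusive); padded so E[j+1, j] == 0.
    E = np.zeros((n + 1, n + 1))
    Ep = np.full((n, n), _INF)  # MFE of i..j given (i, j) paired

    for span in range(MIN_HAIRPIN + 2, n + 1):
        for i in range(n - span + 1):
            j = i + span - 1
            if P[i, j]:
                best = E[i + 1, j - 1]
                if j - i >= MIN_HAIRPIN + 3 and P[i + 1, j - 1]:
                    best = min(best, S[i, j] + Ep[i + 1, j - 1])
                Ep[i, j] = best
            ks = np.arange(i + MIN_HAIRPIN + 1, j + 1)
            cand = Ep[i, ks] + E[ks + 1, j]
            E[i, j] = min(E[i + 1, j], cand.min()) if len(cand) else E[i + 1, j]

    pairs: dict[int, int] = {}
    _traceback(0, n - 1, seq, P, S, E, Ep, pairs)
    db = ["."] * n
    for a, b in pairs.items():
        if a < b:
            db[a], db[b] = "(", ")"
    return FoldResult(seq, "".join(db), float(E[0, n - 1]))


def _traceback(
    i: int,
    j: int,
    seq: str,
    P: np.ndarray,
    S: np.ndarray,
    E: np.ndarray,
    Ep: np.ndarray,
    pairs: dict[int, int],
) -> None:
    """Recover one optimal structure from the filled DP matrices."""
    stack: list[tuple[int, int, bool]] = [(i, j, False)]
    while stack:
        i, j, paired = stack.pop()
        if paired:
            pairs[i] = j
            pairs[j] = i
            if (
                j - i >= MIN_HAIRPIN + 3
                and P[i + 1, j - 1]
                and abs(S[i, j] + Ep[i + 1, j - 1] - Ep[i, j]) < _EPS
            ):
                stack.append((i + 1, j - 1, True))
            elif j - 1 >= i + 1:
                stack.append((i + 1, j - 1, False))
            continue
        if j - i < MIN_HAIRPIN + 1:
            continue
        if abs(E[i, j] - E[i + 1, j]) < _EPS:
            stack.append((i + 1, j, False))
            continue
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if P[i, k] and abs(Ep[i, k] + E[k + 1, j] - E[i, j]) < _EPS:
                stack.append((i, k, True))
                if k + 1 <= j:
                    stack.append((k + 1, j, False))
                break
        else:  # pragma: no cover - would indicate a DP bookkeeping bug
            raise AssertionError("traceback failed to reproduce the DP optimum")


def fold_vienna(sequence: str) -> FoldResult:
    """Fold with the ViennaRNA thermodynamic engine (optional backend).

    Requires the ``RNA`` python bindings; raises ``ImportError`` when
    they are not installed.  Returns the same :class:`FoldResult`
    contract as :func:`fold`.
    """
    import RNA

    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    db, mfe = RNA.fold_compound(seq).mfe()
    return FoldResult(seq, db, float(mfe))


FoldBackend = Callable[[str], FoldResult]


def _stems(pairs: dict[int, int]) -> list[list[tuple[int, int]]]:
    """Maximal helices: runs of pairs (i, j), (i+1, j-1), ..."""
    plist = sorted((i, j) for i, j in pairs.items() if i < j)
    pset = set(plist)
    seen: set[tuple[int, int]] = set()
    stems = []
    for i, j in plist:
        if (i, j) in seen or (i - 1, j + 1) in pset:
            continue
        run = []
        a, b = i, j
        while (a, b) in pset:
            run.append((a, b))
            seen.add((a, b))
            a, b = a + 1, b - 1
        stems.append(run)
    return stems


def decompose(fold_result: FoldResult) -> list[StructureElement]:
    """Standard loop decomposition of a nested secondary structure.

    Maximal stacked runs of pairs become stems; each unpaired region is
    assigned to exactly one loop element according to how many pairs
    close it (one: hairpin; two, nucleotides on both sides: interior;
    two, one side: bulge; three or more: multibranch; none: exterior
    segment).  Junctions with no unpaired nucleotides produce no loop
    element.  Stem ``element_dg`` is the stem's summed stack energy.
    """
    db = fold_result.dotbracket
    seq = fold_result.sequence
    pairs = parse_dotbracket(db)
    n = len(db)
    elements: list[StructureElement] = []

    for run in _stems(pairs):
        positions = tuple(sorted([p for ij in run for p in ij]))
        dg = 0.0
        for (a, b), (a2, b2) in zip(run, run[1:]):
            dg += stack_dg(seq[a], seq[a2], seq[b], seq[b2])
        elements.append(
            StructureElement("stem", len(run), positions, element_dg=dg, label=LABEL_SE)
        )

    # loops closed by each pair
    for i in sorted(p for p in pairs if p < pairs[p]):
        j = pairs[i]
        unpaired: list[int] = []
        branches: list[tuple[int, int]] = []
        k = i + 1
        while k < j:
            if k in pairs:
                branches.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired.append(k)
                k += 1
        if not branches:
            elements.append(
                StructureElement("hairpin_loop", len(unpaired), tuple(unpaired), 0.0)
            )
        elif len(branches) == 1 and unpaired:
            left = branches[0][0] - i - 1
            right = j - branches[0][1] - 1
            kind = "interior_loop" if (left > 0 and right > 0) else "bulge_loop"
            elements.append(
                StructureElement(kind, len(unpaired), tuple(unpaired), 0.0)
            )
        elif len(branches) >= 2 and unpaired:
            elements.append(
                StructureElement("multibranch_loop", len(unpaired), tuple(unpaired), 0.0)
            )

    # exterior-level unpaired runs (5' end, joints between stems, 3' end)
    k = 0
    run_start: Optional[int] = None
    while k <= n:
        at_unpaired = k < n and k not in pairs
        if at_unpaired and run_start is None:
            run_start = k
        if not at_unpaired and run_start is not None:
            positions = tuple(range(run_start, k))
            elements.append(
                StructureElement("exterior_segment", len(positions), positions, 0.0)
            )
            run_start = None
        if k < n and k in pairs and pairs[k] > k:
            k = pairs[k] + 1
        else:
            k += 1

    elements.sort(key=lambda e: (e.positions[0] if e.positions else -1, e.kind))
    return elements


def label_elements(
    elements: Sequence[StructureElement], cutoffs: DseCutoffs = DseCutoffs()
) -> list[StructureElement]:
    """Apply DSE/SE labels: loops at/above their length cutoff are DSE,
    stems are SE, everything else neutral."""
    out = []
    for el in elements:
        if el.kind == "stem":
            out.append(replace(el, label=LABEL_SE))
            continue
        cutoff = cutoffs.threshold(el.kind)
        label = LABEL_DSE if (cutoff is not None and el.length >= cutoff) else LABEL_NEUTRAL
        out.append(replace(el, label=label))
    return out


def assess_accessibility(
    utr: UTRRecord,
    site: BindingSite,
    fold_backend: FoldBackend = fold,
    energy_flank: int = 70,
    structure_flank: int = 30,
    gap_threshold: float = 10.0,
    inhibition_dg: float = -6.0,
    cutoffs: DseCutoffs = DseCutoffs(),
    flank_mode: str = "joint",
    inhibition_granularity: str = "substructure",
) -> AccessibilityVerdict:
    """Apply the free-energy and structural accessibility rules to a site.

    Folds the site alone and jointly with ``energy_flank`` nt of
    upstream/downstream sequence (``flank_mode='alone'`` folds the flank
    without the site); the energy-gap rule passes when the absolute
    difference between the site window and either flank window is at
    least ``gap_threshold`` kcal/mol.  The site +/- ``structure_flank``
    window is folded, decomposed and labelled; ``dse_present`` is true
    when any destabilising element lies in that window, and
    ``inhibitory_structure`` when a stem-containing substructure
    overlapping the site has an attributed free energy below
    ``inhibition_dg`` (``inhibition_granularity='window'`` instead tests
    the whole window's MFE).
    """
    if flank_mode not in ("joint", "alone"):
        raise ValueError("flank_mode must be 'joint' or 'alone'")
    if inhibition_granularity not in ("substructure", "window"):
        raise ValueError("inhibition_granularity must be 'substructure' or 'window'")

    s, e = site.start, site.end
    site_fold = fold_backend(utr.sequence[s:e])

    n = len(utr)
    up_start = max(0, s - energy_flank)
    down_end = min(n, e + energy_flank)
    if flank_mode == "joint":
        up_seq = utr.sequence[up_start:e]
        down_seq = utr.sequence[s:down_end]
    else:
        up_seq = utr.sequence[up_start:s]
        down_seq = utr.sequence[e:down_end]
    up_dg = fold_backend(up_seq).delta_g if up_seq else 0.0
    down_dg = fold_backend(down_seq).delta_g if down_seq else 0.0

    diff_up = site_fold.delta_g - up_dg
    diff_down = site_fold.delta_g - down_dg
    gap_pass = max(abs(diff_up), abs(diff_down)) >= gap_threshold

    struct_win = extract_window(utr, s, e, structure_flank)
    struct_fold = fold_backend(struct_win.sequence)
    elements = label_elements(decompose(struct_fold), cutoffs)
    dse_present = any(el.label == LABEL_DSE for el in elements)

    if inhibition_granularity == "window":
        inhibitory = struct_fold.delta_g < inhibition_dg
    else:
        # site range in window-local coordinates
        lo, hi = s - struct_win.start, e - struct_win.start
        inhibitory = False
        for el in elements:
            if el.kind != "stem" or el.element_dg is None:
                continue
            span_lo, span_hi = el.positions[0], el.positions[-1] + 1
            if span_lo < hi and lo < span_hi and el.element_dg < inhibition_dg:
                inhibitory = True
                break

    return AccessibilityVerdict(
        site_window_dg=site_fold.delta_g,
        upstream_flank_dg=up_dg,
        downstream_flank_dg=down_dg,
        energy_gap_pass=gap_pass,
        dse_present=dse_present,
        inhibitory_structure=inhibitory,
        diff_upstream=diff_up,
        diff_downstream=diff_down,
        upstream_flank_len=s - up_start,
        downstream_flank_len=down_end - e,
        elements=tuple(elements),
    )


def read_verdicts_tsv(
    path: Union[str, Path],
) -> list[tuple[tuple[str, str], AccessibilityVerdict]]:
    """Read back a verdict TSV; returns ((mirna, gene), verdict) rows.

    Element decompositions are not round-tripped through the TSV.
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            verdict = AccessibilityVerdict(
                site_window_dg=float(row["site_dg"]),
                upstream_flank_dg=float(row["upstream_dg"]),
                downstream_flank_dg=float(row["downstream_dg"]),
                energy_gap_pass=bool(int(row["energy_gap_pass"])),
                dse_present=bool(int(row["dse_present"])),
                inhibitory_structure=bool(int(row["inhibitory_structure"])),
                diff_upstream=float(row["diff_upstream"]),
                diff_downstream=float(row["diff_downstream"]),
            )
            out.append(((row["mirna"], row["gene"]), verdict))
    return out


def write_verdicts_tsv(
    rows: Sequence[tuple[BindingSite, AccessibilityVerdict]],
    path: Union[str, Path],
) -> None:
    """Write per-site accessibility verdicts as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "mirna",
                "gene",
                "start",
                "end",
                "site_dg",
                "upstream_dg",
                "downstream_dg",
                "diff_upstream",
                "diff_downstream",
                "energy_gap_pass",
                "dse_present",
                "inhibitory_structure",
            ]
        )
        for site, v in rows:
            writer.writerow(
                [
                    site.mirna,
                    site.gene,
                    site.start,
                    site.end,
                    f"{v.site_window_dg:.2f}",
                    f"{v.upstream_flank_dg:.2f}",
                    f"{v.downstream_flank_dg:.2f}",
                    f"{v.diff_upstream:.2f}",
                    f"{v.diff_downstream:.2f}",
                    int(v.energy_gap_pass),
                    int(v.dse_present),
                    int(v.inhibitory_structure),
                ]
            )
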