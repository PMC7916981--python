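"""Seed-match scanning and constrained heteroduplex search on 3'-UTRs.

A candidate site is any target hexamer whose antiparallel pairing to the
miRNA seed (mature positions 2-7) has at most ``max_mismatch``
non-pairing positions.  G:U wobbles are budgeted separately (default 1,
the usual RNA22-style setting); wobbles beyond the budget degrade to
mismatches.  Site classes follow canonical nomenclature: a 7mer adds a
Watson-Crick pair at miRNA position 8, an 8mer additionally has an A on
the target opposite miRNA position 1.  Overlapping sites are all
reported; deduplication is left to report-level options.

The heteroduplex energy of a site is a nearest-neighbor stack sum over
the full-length miRNA:target alignment (see :mod:`mirprio.energy`), with
a fixed per-position penalty for unpaired positions.  This stands in for
an external hybridization tool so that the whole search is
self-contained and desk-testable; the parameter table is swappable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .energy import UNPAIRED_PENALTY_DG, can_pair, is_wc, is_wobble, stack_dg
from .seqio import MiRNARecord, UTRRecord

SITE_CLASSES = ("8mer", "7mer", "6mer-seed")

#: default RNA22-style heteroduplex energy cutoffs, kcal/mol
DEFAULT_ENERGY_CUTOFFS = (-12.0, -20.0)

PAIR_WC = "WC"
PAIR_WOBBLE = "wobble"
PAIR_NONE = "unpaired"


@dataclass(frozen=True)
class BindingSite:
    """A located seed-complementary site on a UTR.

    ``start``/``end`` are 0-based half-open target coordinates of the
    seed-pairing region; their span equals the site-class span (6, 7 or
    8 nt).  ``mismatches`` and ``wobbles`` are counted within the seed
    hexamer pairing only.
    """

    mirna: str
    gene: str
    start: int
    end: int
    site_class: str
    mismatches: int
    wobbles: int
    alignment: str

    def __post_init__(self) -> None:
        span = {"8mer": 8, "7mer": 7, "6mer-seed": 6}[self.site_class]
        if self.end - self.start != span:
            raise ValueError(
                f"{self.site_class} site must span {span} nt, got "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class DuplexResult:
    """Free energy and per-position pairing of a miRNA:target duplex."""

    energy: float
    pairing: tuple[str, ...]


def _classify_hexamer(
    seed: str, hexamer: str, max_mismatch: int, max_wobble: int
) -> Optional[tuple[int, int, tuple[str, ...]]]:
    """Score one target hexamer against the seed.

    The target hexamer is given 5'->3'; seed position k (0-based within
    the seed) pairs target position 5-k.  Returns (mismatches, wobbles,
    per-seed-position pair codes) or None when the mismatch budget is
    exceeded.  Wobbles are consumed 5'->3' along the miRNA seed; excess
    wobbles count as mismatches.
    """
    mismatches = 0
    wobbles = 0
    codes = []
    for k in range(6):
        a, b = seed[k], hexamer[5 - k]
        if is_wc(a, b):
            codes.append(PAIR_WC)
        elif is_wobble(a, b) and wobbles < max_wobble:
            wobbles += 1
            codes.append(PAIR_WOBBLE)
        else:
            mismatches += 1
            codes.append(PAIR_NONE)
    if mismatches > max_mismatch:
        return None
    return mismatches, wobbles, tuple(codes)


def _render_alignment(
    mirna: MiRNARecord, utr: UTRRecord, s: int, codes: Sequence[str], site_class: str
) -> str:
    """Paired-string rendering: target 5'->3' over miRNA 3'->5'."""
    symbols = {PAIR_WC: "|", PAIR_WOBBLE: ":", PAIR_NONE: " "}
    target = utr.sequence[s : s + 6]
    match = "".join(symbols[codes[5 - j]] for j in range(6))
    mirna_rev = mirna.seed[::-1]
    return (
        f"target 5'-{target}-3' [{site_class}]\n"
        f"          {match}\n"
        f"miRNA  3'-{mirna_rev}-5' (seed, positions 7..2)"
    )


def scan_seed_sites(
    mirna: MiRNARecord,
    utr: UTRRecord,
    max_mismatch: int = 1,
    max_wobble: int = 1,
) -> list[BindingSite]:
    """Locate all seed-complementary sites of ``mirna`` on ``utr``.

    Every hexamer window is tested; qualifying sites are upgraded to
    7mer/8mer when the flanking pairing supports it, and returned sorted
    by start coordinate (overlaps included).
    """
    seed = mirna.seed
    seq = utr.sequence
    n = len(seq)
    sites: list[BindingSite] = []
    for s in range(n - 5):
        scored = _classify_hexamer(seed, seq[s : s + 6], max_mismatch, max_wobble)
        if scored is None:
            continue
        mismatches, wobbles, codes = scored
        site_class = "6mer-seed"
        start, end = s, s + 6
        # position 8 of the mature miRNA pairs the target nucleotide 5' of
        # the hexamer; an A opposite position 1 sits 3' of it
        pos8_pairs = s >= 1 and is_wc(mirna.sequence[7], seq[s - 1])
        if pos8_pairs:
            site_class = "7mer"
            start = s - 1
            if s + 6 < n and seq[s + 6] == "A":
                site_class = "8mer"
                end = s + 7
        sites.append(
            BindingSite(
                mirna=mirna.name,
                gene=utr.gene,
                start=start,
                end=end,
                site_class=site_class,
                mismatches=mismatches,
                wobbles=wobbles,
                alignment=_render_alignment(mirna, utr, s, codes, site_class),
            )
        )
    sites.sort(key=lambda x: (x.start, x.end))
    return sites


def infer_pairing(
    mirna_sub: str, target_sub: str, allow_wobble: bool = True
) -> tuple[str, ...]:
    """Greedy per-position pairing of two aligned, antiparallel strands.

    Both substrings are given 5'->3'; miRNA position i aligns target
    position L-1-i.  Each position is classified independently as WC,
    wobble or unpaired.
    """
    if len(mirna_sub) != len(target_sub):
        raise ValueError("aligned substrings must have equal length")
    rev = target_sub[::-1]
    codes = []
    for a, b in zip(mirna_sub, rev):
        if is_wc(a, b):
            codes.append(PAIR_WC)
        elif allow_wobble and is_wobble(a, b):
            codes.append(PAIR_WOBBLE)
        else:
            codes.append(PAIR_NONE)
    return tuple(codes)


def duplex_energy(
    mirna_sub: str,
    target_sub: str,
    pairing: Optional[Sequence[str]] = None,
    unpaired_penalty: float = UNPAIRED_PENALTY_DG,
) -> DuplexResult:
    """Nearest-neighbor free energy of an aligned miRNA:target duplex.

    Both strands are 5'->3' and aligned antiparallel (miRNA position i
    against target position L-1-i).  ``pairing`` gives one code per
    miRNA position (``WC`` / ``wobble`` / ``unpaired``); when omitted it
    is inferred greedily.  Energy is the sum of stack contributions over
    consecutive paired positions plus ``unpaired_penalty`` per unpaired
    position.
    """
    if len(mirna_sub) != len(target_sub):
        raise ValueError("aligned substrings must have equal length")
    if pairing is None:
        pairing = infer_pairing(mirna_sub, target_sub)
    elif len(pairing) != len(mirna_sub):
        raise ValueError("pairing mask length must match the alignment length")
    rev = target_sub[::-1]
    for i, code in enumerate(pairing):
        if code == PAIR_NONE:
            continue
        a, b = mirna_sub[i], rev[i]
        if code == PAIR_WC and not is_wc(a, b):
            raise ValueError(f"position {i} marked WC but {a}:{b} is not Watson-Crick")
        if code == PAIR_WOBBLE and not is_wobble(a, b):
            raise ValueError(f"position {i} marked wobble but {a}:{b} is not G:U")
    energy = 0.0
    for i in range(len(mirna_sub) - 1):
        if pairing[i] != PAIR_NONE and pairing[i + 1] != PAIR_NONE:
            energy += stack_dg(mirna_sub[i], mirna_sub[i + 1], rev[i], rev[i + 1])
    energy += unpaired_penalty * sum(1 for c in pairing if c == PAIR_NONE)
    return DuplexResult(energy=energy, pairing=tuple(pairing))


def rna22_like_sites(
    mirna: MiRNARecord,
    utr: UTRRecord,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFFS[0],
    seed_len: int = 7,
    max_unpaired_in_seed: int = 1,
    max_wobble: int = 1,
) -> list[tuple[BindingSite, DuplexResult]]:
    """Constrained heteroduplex site search.

    Keeps seed sites of at least the requested class (``seed_len`` 7
    keeps 7mer and 8mer sites, 8 keeps only 8mer) with at most
    ``max_unpaired_in_seed`` unpaired seed positions and ``max_wobble``
    G:U wobbles, then filters on the full-length miRNA:target
    heteroduplex energy (emit iff energy <= ``energy_cutoff``).  Output
    is deterministic, ordered by target coordinate.
    """
    if seed_len not in (7, 8):
        raise ValueError("seed_len must be 7 or 8")
    wanted = {"8mer"} if seed_len == 8 else {"8mer", "7mer"}
    seq = utr.sequence
    n = len(seq)
    L = len(mirna.sequence)
    out: list[tuple[BindingSite, DuplexResult]] = []
    for site in scan_seed_sites(mirna, utr, max_unpaired_in_seed, max_wobble):
        if site.site_class not in wanted:
            continue
        # seed hexamer start on the target
        s = site.start + 1 if site.site_class in ("7mer", "8mer") else site.start
        # mature position k (1-based) pairs target index s + 6 - (k - 1)
        lo = max(0, s + 7 - L)
        hi = min(n, s + 7)
        target_sub = seq[lo:hi]
        mir_lo = s + 7 - hi  # 0-based miRNA index aligned to target index hi-1
        mirna_sub = mirna.sequence[mir_lo : s + 7 - lo]
        duplex = duplex_energy(mirna_sub, target_sub)
        if duplex.energy <= energy_cutoff:
            out.append((site, duplex))
    return out


def read_sites_tsv(
    path: Union[str, Path],
) -> list[tuple[BindingSite, Optional[DuplexResult]]]:
    """Read back a sites TSV written by :func:`write_sites_tsv`.

    The alignment rendering is not round-tripped through the TSV; reloaded
    sites carry an empty alignment string.
    """
    out: list[tuple[BindingSite, Optional[DuplexResult]]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            site = BindingSite(
                mirna=row["mirna"],
                gene=row["gene"],
                start=int(row["start"]),
                end=int(row["end"]),
                site_class=row["site_class"],
                mismatches=int(row["mismatches"]),
                wobbles=int(row["wobbles"]),
                alignment="",
            )
            raw = row.get("duplex_energy_kcal_mol", "")
            duplex = (
                DuplexResult(energy=float(raw), pairing=()) if raw not in ("", None) else None
            )
            out.append((site, duplex))
    return out


def write_sites_tsv(
    rows: Sequence[tuple[BindingSite, Optional[DuplexResult]]],
    path: Union[str, Path],
) -> None:
    """Write scanned sites (optionally with duplex energies) as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "mirna",
                "gene",
                "start",
                "end",
                "site_class",
                "mismatches",
                "wobbles",
                "duplex_energy_kcal_mol",
            ]
        )
        for site, duplex in rows:
            writer.writerow(
                [
                    site.mirna,
                    site.gene,
                    site.start,
                    site.end,
                    site.site_class,
                    site.mismatches,
                    site.wobbles,
                    "" if duplex is None else f"{duplex.energy:.2f}",
                ]
            )
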