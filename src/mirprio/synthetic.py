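"""Synthetic inputs with ground truth for every pipeline stage.

Nothing in the study's raw data is public, so the package ships a
generator that emulates its two kinds of input: candidate 3'-UTRs with
binding sites planted at known positions (class, mismatch and wobble
counts recorded), and sample x assay Cq tables with known per-group
expression shifts, stable reference assays and Gaussian Cq noise on the
study's five-group design (normal mucosa, adenoma, adenoma with early
carcinoma, CRC N0, CRC N+).  Group sizes default to the study's cohort
(23/11/13/10/13 samples) and the Cq noise default is 0.25 cycles.  An
optional Gaussian-copula coupling plants a target rank correlation
between one miRNA assay and one gene assay (rho_pearson =
2 sin(pi rho_spearman / 6)).

All randomness flows through one numpy Generator seeded from
``SyntheticSpec.seed``; outputs are byte-identical across runs for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .energy import is_wc, is_wobble
from .qpcr import GROUPS, CqTable
from .seqio import MiRNARecord, UTRRecord

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: study cohort sizes per group
DEFAULT_N_PER_GROUP = {
    "normal": 23,
    "adenoma": 11,
    "adenoma_early_ca": 13,
    "crc_n0": 10,
    "crc_n+": 13,
}


def load_reference_mirnas() -> list[MiRNARecord]:
    """The packaged mature-miRNA fixture table."""
    from .seqio import read_mirna_table

    with resources.as_file(
        resources.files("mirprio.data") / "mature_mirnas.tsv"
    ) as path:
        return read_mirna_table(path)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class PlantedSiteSpec:
    """One site to plant: which miRNA, what class, how degraded."""

    mirna: str
    site_class: str = "7mer"  # 8mer | 7mer | 6mer-seed
    mismatches: int = 0
    wobbles: int = 0
    position: Optional[int] = None  # start of the seed hexamer; None = random

    def __post_init__(self) -> None:
        if self.site_class not in ("8mer", "7mer", "6mer-seed"):
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.mismatches < 0 or self.wobbles < 0:
            raise ValueError("mismatches and wobbles must be non-negative")


@dataclass(frozen=True)
class CouplingSpec:
    """Planted rank dependence between a miRNA assay and a gene assay."""

    mirna_assay: str
    gene_assay: str
    spearman_rho: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.spearman_rho <= 1.0:
            raise ValueError("spearman_rho must lie in [-1, 1]")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    ``cq_groups`` maps assay -> group -> true shift in cycles relative to
    the normal-mucosa baseline (a negative shift means more template,
    i.e. upregulation).  Reference assays always have shift 0.
    """

    seed: int = 0
    n_utrs: int = 20
    utr_length: int = 200
    planted_sites: Optional[Sequence[PlantedSiteSpec]] = None
    background_gc: float = 0.4
    mirnas: Sequence[MiRNARecord] = field(default_factory=load_reference_mirnas)
    cq_groups: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    cq_noise_sd: float = 0.25
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    reference_assays: Sequence[str] = ("ref1", "ref2")
    coupling: Optional[CouplingSpec] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must lie in [0, 1]")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be non-negative")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 3:
                raise ValueError(f"n_per_group[{g!r}] must be >= 3, got {n}")
        if not self.mirnas:
            raise ValueError("at least one miRNA is required")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return list(rng.choice(np.array(["A", "U", "G", "C"]), size=length, p=probs))


def _non_pairing_base(rng: np.random.Generator, mirna_base: str) -> str:
    choices = [
        b
        for b in "ACGU"
        if not is_wc(mirna_base, b) and not is_wobble(mirna_base, b)
    ]
    return str(rng.choice(choices))


def _build_site(
    rng: np.random.Generator, mirna: MiRNARecord, spec: PlantedSiteSpec
) -> tuple[str, str, str, int, int]:
    """Construct (left_context, hexamer, right_context) for one planted site.

    The hexamer is the seed-pairing region (reverse complement of mature
    positions 2-7, degraded as requested); left/right context fix the
    site class deterministically (position-8 pairing 5' of the hexamer,
    the A anchor 3' of it).  Returns the three segments and the final
    mismatch/wobble counts.
    """
    seed = mirna.seed
    hexamer = list(_revcomp(seed))  # hexamer[5 - k] pairs seed[k]
    wobbles = 0
    mismatches = 0
    # degrade: wobbles first (seed G or U positions), then mismatches
    wobble_ok = [k for k in range(6) if seed[k] in "GU"]
    rng.shuffle(wobble_ok)
    touched: set[int] = set()
    for k in wobble_ok[: spec.wobbles]:
        hexamer[5 - k] = "U" if seed[k] == "G" else "G"
        touched.add(k)
        wobbles += 1
    mm_candidates = [k for k in range(6) if k not in touched]
    rng.shuffle(mm_candidates)
    for k in mm_candidates[: spec.mismatches]:
        hexamer[5 - k] = _non_pairing_base(rng, seed[k])
        mismatches += 1

    pos8 = mirna.sequence[7]
    if spec.site_class in ("7mer", "8mer"):
        left = _COMPLEMENT[pos8]  # Watson-Crick partner of position 8
    else:
        left = _non_pairing_base(rng, pos8)
    if spec.site_class == "8mer":
        right = "A"
    else:
        right = str(rng.choice(["C", "G", "U"]))  # anything but the A anchor
    return left, "".join(hexamer), right, mismatches, wobbles


def gen_utrs(spec: SyntheticSpec, rng: Optional[np.random.Generator] = None) -> tuple[list[UTRRecord], pd.DataFrame]:
    """Generate UTRs with planted sites and the ground-truth site table.

    Background nucleotides are i.i.d. at ``background_gc``; each planted
    site is written over the background at a collision-free position.
    The truth table columns are gene, mirna, start, end, site_class,
    mismatches, wobbles (coordinates of the seed-pairing region, matching
    the scanner's reporting convention).
    """
    rng = spec.rng() if rng is None else rng
    by_name = {m.name: m for m in spec.mirnas}
    if spec.planted_sites is None:
        planted = [
            PlantedSiteSpec(mirna=spec.mirnas[i % len(spec.mirnas)].name)
            for i in range(spec.n_utrs)
        ]
    else:
        planted = list(spec.planted_sites)

    utrs: list[UTRRecord] = []
    truth_rows = []
    for i in range(spec.n_utrs):
        gene = f"GENE{i + 1:03d}"
        seq = _background(rng, spec.utr_length, spec.background_gc)
        # sites assigned round-robin over UTRs when there are more specs
        # than UTRs, one per UTR otherwise
        assigned = [ps for j, ps in enumerate(planted) if j % spec.n_utrs == i]
        used: list[tuple[int, int]] = []
        for ps in assigned:
            if ps.mirna not in by_name:
                raise ValueError(f"planted site references unknown miRNA {ps.mirna!r}")
            mirna = by_name[ps.mirna]
            left, hexamer, right, mm, wb = _build_site(rng, mirna, ps)
            # occupied block: [s-1, s+7) to pin down class context
            if ps.position is not None:
                s = ps.position
                if not (1 <= s and s + 7 <= spec.utr_length):
                    raise ValueError(
                        f"planted position {s} does not fit a site block in a "
                        f"{spec.utr_length} nt UTR"
                    )
            else:
                for _ in range(1000):
                    s = int(rng.integers(1, spec.utr_length - 7))
                    if all(not (s - 1 < e and b < s + 7) for b, e in used):
                        break
                else:
                    raise ValueError("could not place planted sites without collision")
            if any(s - 1 < e and b < s + 7 for b, e in used):
                raise ValueError("planted site positions collide")
            used.append((s - 1, s + 7))
            seq[s - 1] = left
            seq[s : s + 6] = list(hexamer)
            seq[s + 6] = right
            if ps.site_class == "8mer":
                start, end = s - 1, s + 7
            elif ps.site_class == "7mer":
                start, end = s - 1, s + 6
            else:
                start, end = s, s + 6
            truth_rows.append(
                {
                    "gene": gene,
                    "mirna": ps.mirna,
                    "start": start,
                    "end": end,
                    "site_class": ps.site_class,
                    "mismatches": mm,
                    "wobbles": wb,
                }
            )
        utrs.append(UTRRecord(gene=gene, sequence="".join(seq), source_id="synthetic"))
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "mirna", "start", "end", "site_class", "mismatches", "wobbles"],
    )
    return utrs, truth


@dataclass(frozen=True)
class CqTruth:
    """Ground truth behind a generated Cq table."""

    baselines: Mapping[str, float]
    shifts: Mapping[str, Mapping[str, float]]  # assay -> group -> cycles
    noise_sd: float
    coupling: Optional[CouplingSpec]


def gen_cq(
    spec: SyntheticSpec,
    target_assays: Sequence[str] = ("GENE1", "miR1"),
    rng: Optional[np.random.Generator] = None,
) -> tuple[CqTable, CqTruth]:
    """Generate a Cq table with known group effects.

    Cq(sample, assay) = baseline(assay) + shift(group, assay) +
    N(0, cq_noise_sd).  Baselines are drawn once per assay in [18, 32]
    cycles; reference assays are forced to shift 0 in every group.  When
    a :class:`CouplingSpec` is set, the noise of the two named assays is
    drawn from a Gaussian copula at the requested Spearman rho
    (comonotone for rho = +/-1).  CRC samples carry a paired
    normal-mucosa link (assigned round-robin over the normal samples) so
    that paired and per-sample ddCq analyses have a pairing to use.
    """
    rng = spec.rng() if rng is None else rng
    assays = list(dict.fromkeys(list(target_assays) + list(spec.reference_assays)))
    baselines = {a: float(rng.uniform(18.0, 32.0)) for a in assays}
    shifts = {
        a: {
            g: (
                0.0
                if a in spec.reference_assays
                else float(spec.cq_groups.get(a, {}).get(g, 0.0))
            )
            for g in GROUPS
        }
        for a in assays
    }

    samples = []
    groups = []
    for g in GROUPS:
        for i in range(spec.n_per_group.get(g, 0)):
            samples.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    n = len(samples)

    noise = {a: rng.normal(0.0, spec.cq_noise_sd, size=n) for a in assays}
    if spec.coupling is not None:
        c = spec.coupling
        for name in (c.mirna_assay, c.gene_assay):
            if name not in assays:
                raise ValueError(f"coupling references unknown assay {name!r}")
        rho_p = 2.0 * np.sin(np.pi * c.spearman_rho / 6.0)
        rho_p = float(np.clip(rho_p, -1.0, 1.0))
        z1 = rng.normal(size=n)
        if abs(c.spearman_rho) == 1.0:
            z2 = np.sign(c.spearman_rho) * z1
        else:
            z2 = rho_p * z1 + np.sqrt(1.0 - rho_p**2) * rng.normal(size=n)
        noise[c.mirna_assay] = spec.cq_noise_sd * z1 if spec.cq_noise_sd > 0 else z1
        noise[c.gene_assay] = spec.cq_noise_sd * z2 if spec.cq_noise_sd > 0 else z2

    data = {
        a: [
            baselines[a] + shifts[a][groups[i]] + noise[a][i]
            for i in range(n)
        ]
        for a in assays
    }
    cq = pd.DataFrame(data, index=samples)
    group_series = pd.Series(groups, index=samples)

    normals = [s for s, g in zip(samples, groups) if g == "normal"]
    paired = {}
    k = 0
    for s, g in zip(samples, groups):
        if g in ("crc_n0", "crc_n+") and normals:
            paired[s] = normals[k % len(normals)]
            k += 1

    table = CqTable(
        cq=cq,
        group=group_series,
        reference_assays=tuple(spec.reference_assays),
        paired_normal=paired,
    )
    truth = CqTruth(
        baselines=baselines,
        shifts=shifts,
        noise_sd=spec.cq_noise_sd,
        coupling=spec.coupling,
    )
    return table, truth


def gen_evidence(
    spec: SyntheticSpec,
    pairs: Sequence[tuple[str, str]],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Random but reproducible evidence table for (mirna, gene) pairs."""
    rng = spec.rng() if rng is None else rng
    rows = []
    for mirna, gene in pairs:
        rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "db_count": int(rng.integers(0, 5)),
                "cancer_assoc": int(rng.random() < 0.5),
                "crc_assoc": int(rng.random() < 0.7),
                "gene_assoc": int(rng.random() < 0.7),
                "direct_validation": int(rng.random() < 0.2),
                "mirbase_valid": int(rng.random() < 0.9),
            }
        )
    return pd.DataFrame(rows)
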