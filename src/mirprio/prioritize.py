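"""Evidence aggregation into a per-pair prioritization decision.

Each miRNA-gene pair carries externally supplied evidence (how many
target-prediction databases report the pair, prior cancer/CRC/gene
associations, direct experimental validation, and whether the miRNA is
annotated as a true miRNA) plus the sequence/structure results computed
upstream.  Candidates are first gated (true miRNA, and either a known
cancer association or at least two databases), then four evidence flags
are assembled per pair:

* two_dbs - reported by at least two databases;
* energy  - folding free-energy constraints met (energy gap or DSE
  present; configurable to require both);
* rna22   - at least one 7mer/8mer site passes the heteroduplex energy
  cutoff (tri-state: a pair with sites that all miss the cutoff is a
  near-miss, reported distinctly and counted as a pass only when
  configured to);
* direct_validation - prior direct experimental validation.

A pair is *included* only when a destabilising element is present at a
site, the pair has a previous association with the target gene and a
previous association with CRC.  Included pairs are *selected* for the
validation shortlist when at least ``min_flags`` of the four flags are
positive (default 2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .site_scan import BindingSite, DuplexResult
from .structure import AccessibilityVerdict

RNA22_PASS = "pass"
RNA22_NEAR_MISS = "near_miss"
RNA22_FAIL = "fail"

_TRUTHY = {"1", "true", "yes", "+", "y"}
_FALSY = {"0", "false", "no", "-", "−", "n", ""}


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean {value!r} for {context}")


@dataclass(frozen=True)
class EvidenceRecord:
    """Externally supplied evidence for one miRNA-gene pair."""

    mirna: str
    gene: str
    db_count: int
    cancer_assoc: bool
    crc_assoc: bool
    gene_assoc: bool
    direct_validation: bool
    mirbase_valid: bool

    def __post_init__(self) -> None:
        if self.db_count < 0:
            raise ValueError("db_count must be non-negative")


@dataclass(frozen=True)
class PrioritizationResult:
    """Aggregated flags and the inclusion/selection decision for a pair."""

    mirna: str
    gene: str
    flag_two_dbs: bool
    flag_energy: bool
    flag_rna22: str  # pass | near_miss | fail
    flag_direct_validation: bool
    included: bool
    selected: bool
    rationale: str


@dataclass(frozen=True)
class PrioritizeConfig:
    """Tunable thresholds of the aggregation rules."""

    min_flags: int = 2
    near_miss_counts: bool = False
    energy_rule: str = "or"  # 'or': gap OR DSE; 'and': both required
    rna22_cutoff: float = -12.0

    def __post_init__(self) -> None:
        if self.energy_rule not in ("or", "and"):
            raise ValueError("energy_rule must be 'or' or 'and'")


def gate_candidates(evidence: Sequence[EvidenceRecord]) -> list[EvidenceRecord]:
    """Keep pairs whose miRNA is a true annotated miRNA and that either
    have a known cancer association or appear in at least two databases.
    Input order is preserved."""
    return [
        rec
        for rec in evidence
        if rec.mirbase_valid and (rec.cancer_assoc or rec.db_count >= 2)
    ]


def _decide(
    mirna: str,
    gene: str,
    two_dbs: bool,
    energy: bool,
    rna22: str,
    direct: bool,
    dse_present: bool,
    gene_assoc: bool,
    crc_assoc: bool,
    config: PrioritizeConfig,
) -> PrioritizationResult:
    rna22_positive = rna22 == RNA22_PASS or (
        config.near_miss_counts and rna22 == RNA22_NEAR_MISS
    )
    n_flags = sum([two_dbs, energy, rna22_positive, direct])
    included = dse_present and gene_assoc and crc_assoc
    selected = included and n_flags >= config.min_flags
    reasons = []
    reasons.append("DSE present" if dse_present else "no DSE")
    reasons.append("gene association" if gene_assoc else "no gene association")
    reasons.append("CRC association" if crc_assoc else "no CRC association")
    reasons.append(f"{n_flags}/4 evidence flags (rna22={rna22})")
    verdict = "selected" if selected else ("included" if included else "excluded")
    return PrioritizationResult(
        mirna=mirna,
        gene=gene,
        flag_two_dbs=two_dbs,
        flag_energy=energy,
        flag_rna22=rna22,
        flag_direct_validation=direct,
        included=included,
        selected=selected,
        rationale=f"{verdict}: " + "; ".join(reasons),
    )


PairKey = tuple[str, str]  # (mirna, gene)


def aggregate(
    evidence: Sequence[EvidenceRecord],
    sites: Mapping[PairKey, Sequence[tuple[BindingSite, DuplexResult]]],
    verdicts: Mapping[PairKey, Sequence[AccessibilityVerdict]],
    config: PrioritizeConfig = PrioritizeConfig(),
    known_mirnas: Optional[set[str]] = None,
    known_genes: Optional[set[str]] = None,
) -> list[PrioritizationResult]:
    """Compute the four flags and the decision for every evidence pair.

    ``sites`` maps each pair to its candidate 7mer/8mer sites with
    heteroduplex energies (unfiltered: the rna22 flag is 'pass' when any
    energy meets ``config.rna22_cutoff``, 'near_miss' when sites exist
    but none do, 'fail' when the pair has no sites).  ``verdicts`` maps
    each pair to its per-site accessibility verdicts.  Output is sorted
    by (gene, miRNA) and is invariant to input order.  Evidence
    referencing a miRNA or gene outside the supplied universe raises a
    ``KeyError`` listing all offenders.
    """
    if known_mirnas is not None or known_genes is not None:
        offenders = []
        for rec in evidence:
            if known_mirnas is not None and rec.mirna not in known_mirnas:
                offenders.append(f"unknown miRNA {rec.mirna!r}")
            if known_genes is not None and rec.gene not in known_genes:
                offenders.append(f"unknown gene {rec.gene!r}")
        if offenders:
            raise KeyError("; ".join(sorted(set(offenders))))

    results = []
    for rec in evidence:
        key = (rec.mirna, rec.gene)
        pair_sites = list(sites.get(key, ()))
        pair_verdicts = list(verdicts.get(key, ()))
        if pair_sites:
            if any(d.energy <= config.rna22_cutoff for _, d in pair_sites):
                rna22 = RNA22_PASS
            else:
                rna22 = RNA22_NEAR_MISS
        else:
            rna22 = RNA22_FAIL
        gap = any(v.energy_gap_pass for v in pair_verdicts)
        dse = any(v.dse_present for v in pair_verdicts)
        if config.energy_rule == "or":
            energy = gap or dse
        else:
            energy = gap and dse
        results.append(
            _decide(
                rec.mirna,
                rec.gene,
                two_dbs=rec.db_count >= 2,
                energy=energy,
                rna22=rna22,
                direct=rec.direct_validation,
                dse_present=dse,
                gene_assoc=rec.gene_assoc,
                crc_assoc=rec.crc_assoc,
                config=config,
            )
        )
    results.sort(key=lambda r: (r.gene, r.mirna))
    return results


@dataclass(frozen=True)
class FlagRow:
    """A pre-tabulated flag matrix row (e.g. transcribed from a published
    prioritization table) for driving the decision logic directly."""

    mirna: str
    gene: str
    two_dbs: bool
    energy: bool
    rna22: str  # pass | near_miss | fail
    direct_validation: bool
    dse_present: bool = True
    gene_assoc: bool = True
    crc_assoc: bool = True


def aggregate_from_flags(
    rows: Sequence[FlagRow], config: PrioritizeConfig = PrioritizeConfig()
) -> list[PrioritizationResult]:
    """Decision logic on a pre-tabulated flag matrix (order-invariant)."""
    results = [
        _decide(
            r.mirna,
            r.gene,
            r.two_dbs,
            r.energy,
            r.rna22,
            r.direct_validation,
            r.dse_present,
            r.gene_assoc,
            r.crc_assoc,
            config,
        )
        for r in rows
    ]
    results.sort(key=lambda r: (r.gene, r.mirna))
    return results


def read_evidence(path: Union[str, Path]) -> list[EvidenceRecord]:
    """Read an evidence TSV (columns: mirna, gene, db_count, cancer_assoc,
    crc_assoc, gene_assoc, direct_validation, mirbase_valid)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        records = []
        for row in reader:
            records.append(
                EvidenceRecord(
                    mirna=row["mirna"].strip(),
                    gene=row["gene"].strip(),
                    db_count=int(row["db_count"]),
                    cancer_assoc=_parse_bool(row["cancer_assoc"], "cancer_assoc"),
                    crc_assoc=_parse_bool(row["crc_assoc"], "crc_assoc"),
                    gene_assoc=_parse_bool(row["gene_assoc"], "gene_assoc"),
                    direct_validation=_parse_bool(
                        row["direct_validation"], "direct_validation"
                    ),
                    mirbase_valid=_parse_bool(row["mirbase_valid"], "mirbase_valid"),
                )
            )
    return records


def read_flag_table(path: Union[str, Path]) -> list[FlagRow]:
    """Read a pre-tabulated flag matrix TSV (columns: gene, mirna, two_dbs,
    energy, rna22, direct_validation[, dse_present, gene_assoc, crc_assoc])."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            rna22 = row["rna22"].strip().lower()
            if rna22 not in (RNA22_PASS, RNA22_NEAR_MISS, RNA22_FAIL):
                rna22 = RNA22_PASS if _parse_bool(row["rna22"], "rna22") else RNA22_FAIL
            rows.append(
                FlagRow(
                    mirna=row["mirna"].strip(),
                    gene=row["gene"].strip(),
                    two_dbs=_parse_bool(row["two_dbs"], "two_dbs"),
                    energy=_parse_bool(row["energy"], "energy"),
                    rna22=rna22,
                    direct_validation=_parse_bool(
                        row["direct_validation"], "direct_validation"
                    ),
                    dse_present=_parse_bool(
                        row.get("dse_present", "+"), "dse_present"
                    ),
                    gene_assoc=_parse_bool(row.get("gene_assoc", "+"), "gene_assoc"),
                    crc_assoc=_parse_bool(row.get("crc_assoc", "+"), "crc_assoc"),
                )
            )
    return rows


def report(results: Sequence[PrioritizationResult], path: Union[str, Path]) -> None:
    """Write the prioritization table as TSV (stable column and row order:
    gene, then miRNA).  Raises ``ValueError`` on an empty result set."""
    if not results:
        raise ValueError("refusing to write an empty prioritization report")
    ordered = sorted(results, key=lambda r: (r.gene, r.mirna))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "gene",
                "mirna",
                "two_dbs",
                "energy",
                "rna22",
                "direct_validation",
                "included",
                "selected",
                "rationale",
            ]
        )
        for r in ordered:
            writer.writerow(
                [
                    r.gene,
                    r.mirna,
                    int(r.flag_two_dbs),
                    int(r.flag_energy),
                    r.flag_rna22,
                    int(r.flag_direct_validation),
                    int(r.included),
                    int(r.selected),
                    r.rationale,
                ]
            )
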