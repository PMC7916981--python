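"""Run configuration and stage orchestration behind the command line.

The configuration file is a flat YAML of paths, thresholds and flags;
every threshold defaults to the workflow's standard value (one seed
mismatch and one G:U wobble, heteroduplex cutoff -12 kcal/mol with -20
as the strict alternative, a 10 kcal/mol flank energy gap, DSE length
cutoffs 11/9/7/11/11, -6 kcal/mol inhibitory-structure rule, two of four
evidence flags for selection).  Each stage reads/writes plain TSV so
stages can be run separately or chained with ``run_all``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import prioritize as pz
from . import qpcr, seqio, site_scan, structure, synthetic

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All paths, thresholds and flags of a pipeline run."""

    # paths
    mirna_table: str = "mirnas.tsv"
    utr_fasta: str = "utrs.fasta"
    evidence_tsv: str = "evidence.tsv"
    cq_tsv: str = "cq.tsv"
    out_dir: str = "out"
    # site scan thresholds
    max_mismatch: int = 1
    max_wobble: int = 1
    energy_cutoff: float = -12.0
    energy_cutoff_strict: float = -20.0
    seed_len: int = 7
    # accessibility thresholds
    gap_threshold: float = 10.0
    energy_flank: int = 70
    structure_flank: int = 30
    dse_hairpin: int = 11
    dse_interior: int = 9
    dse_bulge: int = 7
    dse_multibranch: int = 11
    dse_exterior: int = 11
    inhibition_dg: float = -6.0
    # prioritization
    min_flags: int = 2
    near_miss_counts: bool = False
    energy_rule: str = "or"
    # qpcr
    efficiency_correction: bool = False
    correlation_pairs: list = field(default_factory=list)  # [[mirna_assay, gene_assay]]
    # simulation / reproducibility
    seed: int = 0

    def cutoffs(self) -> structure.DseCutoffs:
        return structure.DseCutoffs(
            hairpin=self.dse_hairpin,
            interior=self.dse_interior,
            bulge=self.dse_bulge,
            multibranch=self.dse_multibranch,
            exterior=self.dse_exterior,
        )

    def prioritize_config(self) -> pz.PrioritizeConfig:
        return pz.PrioritizeConfig(
            min_flags=self.min_flags,
            near_miss_counts=self.near_miss_counts,
            energy_rule=self.energy_rule,
            rna22_cutoff=self.energy_cutoff,
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_run_log(config: RunConfig, out: Path, counts: dict) -> None:
    """Config echo + version + stage counts; deterministic content."""
    payload = {
        "mirprio_version": __version__,
        "config": dataclasses.asdict(config),
        "counts": counts,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def run_simulate(config: RunConfig) -> dict:
    """Generate all pipeline inputs into ``out_dir`` with ground truth."""
    out = _outdir(config)
    spec = synthetic.SyntheticSpec(
        seed=config.seed,
        cq_groups={
            "GENE001": {"adenoma": 2.0, "adenoma_early_ca": 1.0, "crc_n0": 2.5, "crc_n+": 2.5},
            "miR1": {"adenoma": -2.0, "adenoma_early_ca": -1.0, "crc_n0": -2.5, "crc_n+": -1.5},
        },
    )
    utrs, truth = synthetic.gen_utrs(spec)
    seqio.write_fasta(utrs, out / "utrs.fasta")
    seqio.write_mirna_table(spec.mirnas, out / "mirnas.tsv")
    truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    pairs = sorted({(row.mirna, row.gene) for row in truth.itertuples()})
    evidence = synthetic.gen_evidence(spec, pairs)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    table, _cq_truth = synthetic.gen_cq(spec, target_assays=("GENE001", "miR1"))
    table.to_long_tsv(out / "cq.tsv")
    counts = {"utrs": len(utrs), "planted_sites": len(truth), "cq_samples": len(table.cq)}
    write_run_log(config, out, counts)
    return counts


def run_scan(config: RunConfig) -> dict:
    """Seed-site scan + heteroduplex energies -> sites.tsv."""
    out = _outdir(config)
    mirnas = seqio.read_mirna_table(config.mirna_table)
    utrs = seqio.read_fasta(config.utr_fasta)
    rows = []
    for mirna in mirnas:
        for utr in utrs:
            # all candidate 7/8mer sites with energies, unfiltered, so that
            # downstream stages can apply pass/near-miss cutoffs
            hits = site_scan.rna22_like_sites(
                mirna,
                utr,
                energy_cutoff=0.0,
                seed_len=config.seed_len,
                max_unpaired_in_seed=config.max_mismatch,
                max_wobble=config.max_wobble,
            )
            rows.extend(hits)
    site_scan.write_sites_tsv(rows, out / "sites.tsv")
    counts = {"sites": len(rows)}
    write_run_log(config, out, counts)
    return counts


def run_assess(config: RunConfig) -> dict:
    """Accessibility folding for every scanned site -> verdicts.tsv."""
    out = _outdir(config)
    utrs = {u.gene: u for u in seqio.read_fasta(config.utr_fasta)}
    sites = site_scan.read_sites_tsv(out / "sites.tsv")
    rows = []
    for site, _duplex in sites:
        verdict = structure.assess_accessibility(
            utrs[site.gene],
            site,
            energy_flank=config.energy_flank,
            structure_flank=config.structure_flank,
            gap_threshold=config.gap_threshold,
            inhibition_dg=config.inhibition_dg,
            cutoffs=config.cutoffs(),
        )
        rows.append((site, verdict))
    structure.write_verdicts_tsv(rows, out / "verdicts.tsv")
    counts = {"verdicts": len(rows)}
    write_run_log(config, out, counts)
    return counts


def run_prioritize(config: RunConfig) -> dict:
    """Aggregate evidence + sites + verdicts -> prioritization.tsv."""
    out = _outdir(config)
    evidence = pz.gate_candidates(pz.read_evidence(config.evidence_tsv))
    site_rows = site_scan.read_sites_tsv(out / "sites.tsv")
    sites: dict = {}
    for site, duplex in site_rows:
        sites.setdefault((site.mirna, site.gene), []).append((site, duplex))
    verdicts: dict = {}
    for key, verdict in structure.read_verdicts_tsv(out / "verdicts.tsv"):
        verdicts.setdefault(key, []).append(verdict)
    results = pz.aggregate(evidence, sites, verdicts, config.prioritize_config())
    if results:
        pz.report(results, out / "prioritization.tsv")
    counts = {
        "pairs": len(results),
        "included": sum(r.included for r in results),
        "selected": sum(r.selected for r in results),
    }
    write_run_log(config, out, counts)
    return counts


def run_qpcr(config: RunConfig) -> dict:
    """Relative quantification and statistics -> expression.tsv,
    correlations.tsv."""
    out = _outdir(config)
    table = qpcr.CqTable.from_long_tsv(config.cq_tsv)
    normalized = qpcr.normalize(table, efficiency_correction=config.efficiency_correction)
    delta = normalized.delta_cq
    results = []
    for assay in delta.columns:
        series = delta[assay]
        for group in ("adenoma", "adenoma_early_ca", "crc_n0", "crc_n+"):
            try:
                results.append(
                    qpcr.compare_groups(series, table.group, group, "normal", assay=assay)
                )
            except qpcr.AnalysisError:
                continue
        # per-sample ddCq vs corresponding normal: CRC N0 vs CRC N+
        try:
            n0 = qpcr.per_sample_ddcq(
                series,
                table.paired_normal,
                [s for s in delta.index if table.group.loc[s] == "crc_n0"],
            )
            nplus = qpcr.per_sample_ddcq(
                series,
                table.paired_normal,
                [s for s in delta.index if table.group.loc[s] == "crc_n+"],
            )
            results.append(
                qpcr.compare_independent_ddcq(list(n0), list(nplus), assay=assay)
            )
        except qpcr.AnalysisError:
            pass
    qpcr.write_expression_tsv(results, out / "expression.tsv")

    corr_rows = []
    levels = qpcr.malignancy_levels(table.group.loc[delta.index])
    for assay in delta.columns:
        try:
            rho, p = qpcr.correlate(delta[assay], levels)
            corr_rows.append((assay, "malignancy_level", rho, p))
        except qpcr.AnalysisError:
            continue
    for pair in config.correlation_pairs:
        a, b = pair
        if a in delta.columns and b in delta.columns:
            rho, p = qpcr.correlate(delta[a], delta[b])
            corr_rows.append((a, b, rho, p))
    with open(out / "correlations.tsv", "w") as fh:
        fh.write("x\ty\tspearman_rho\tp_two_tailed\n")
        for a, b, rho, p in corr_rows:
            fh.write(f"{a}\t{b}\t{rho:.4f}\t{p:.6g}\n")
    counts = {"comparisons": len(results), "correlations": len(corr_rows)}
    write_run_log(config, out, counts)
    return counts


def run_all(config: RunConfig) -> dict:
    """simulate-independent full chain: scan -> assess -> prioritize, and
    separately the qPCR analysis.  Inputs must already exist."""
    counts = {}
    counts.update(run_scan(config))
    counts.update(run_assess(config))
    counts.update(run_prioritize(config))
    counts.update(run_qpcr(config))
    out = _outdir(config)
    write_run_log(config, out, counts)
    return counts
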