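# mirprio

miRNA target-site prioritization and efficiency-corrected qPCR relative
quantification, packaged as a tested, desk-scale pipeline.

`mirprio` is for researchers who have a shortlist of differentially
expressed genes (here framed around colorectal-cancer stem-cell genes
and the adenoma–carcinoma sequence) and want to (a) prioritize candidate
regulatory miRNAs from sequence, secondary structure and curated
evidence, and (b) analyse the resulting qPCR validation experiment.
Everything runs on plain FASTA/TSV inputs, and a synthetic-data module
generates ground-truthed inputs for every stage so the whole pipeline is
testable without access to patient data.

## What it computes

**Seed scanning.** The seed of a mature miRNA is positions 2–7. Every
hexamer of a 3′-UTR is aligned antiparallel to the seed; a site is kept
when it has at most one non-pairing position, with G:U wobbles budgeted
separately (default one; excess wobbles degrade to mismatches). Sites
are classed canonically: **7mer** when miRNA position 8 also pairs
Watson–Crick, **8mer** when additionally the target shows an A opposite
miRNA position 1.

**Heteroduplex energy.** The full-length miRNA:target hybrid is scored
with an embedded nearest-neighbor stack table (the published
Watson–Crick RNA/RNA ΔG°₃₇ parameters; +0.5 kcal/mol per unpaired
position). A constrained search (7mer/8mer seed, ≤1 unpaired seed
position, ≤1 wobble) keeps sites with duplex ΔG ≤ −12.0 kcal/mol
(−20.0 as the strict alternative).

**Accessibility.** Windows around each site are folded with an internal
stack-scored dynamic-programming folder (nested structures, minimum
hairpin 3; a ViennaRNA adapter is optional). The site is folded alone
and jointly with 70 nt of each flank — the *energy-gap rule* passes when
|ΔG(site) − ΔG(flank window)| ≥ 10 kcal/mol on either side. The
site ± 30 nt window is decomposed into loops and stems; long
single-stranded elements are **destabilising elements (DSE)**
(hairpin ≥ 11, interior ≥ 9, bulge ≥ 7, multibranch ≥ 11, free
end/joint ≥ 11 nt), stems are stabilising (SE), and a site-overlapping
stem below −6 kcal/mol flags the site as occluded.

**Prioritization.** Candidates are gated (annotated true miRNA, and
either a known cancer association or ≥ 2 databases reporting the pair),
then four flags are tabulated per pair — two-databases, folding
free-energy constraints, constrained-search hit (with a distinct
*near-miss* state for pairs whose sites all miss the energy cutoff), and
direct validation. A pair is *included* when a DSE is present and both a
prior gene association and a prior CRC association exist; *selected* for
validation when ≥ 2 of the four flags are positive.

**qPCR.** Amplification efficiency E = 10^(−1/slope) from Cq regressed
on log₁₀ (relative input) over a dilution series; ΔCq = Cq(target) −
mean Cq(references) (the geometric mean of reference quantities);
ΔΔCq = mean ΔCq(group A) − mean ΔCq(group B); fold = 2^(−ΔΔCq).
Wilcoxon signed-rank for paired (lesion vs corresponding normal
mucosa), Mann–Whitney U for independent groups and for per-sample ΔΔCq
(N0 vs N+), Spearman correlation for miRNA–mRNA anticorrelation and for
the ordinal level of malignancy (normal = 0 … CRC N+ = 4).

## Worked example

```python
import math
from mirprio import (load_reference_mirnas, UTRRecord, scan_seed_sites,
                     assess_accessibility, fit_efficiency,
                     compare_groups, normalize)
from mirprio.synthetic import SyntheticSpec, gen_cq

mir = {m.name: m for m in load_reference_mirnas()}["hsa-miR-425-5p"]
print("seed:", mir.seed)                     # seed: AUGACA

utr = UTRRecord("SLITRK6",
    "GCGGCCAAAGAGGAAAAUGUCAUCGGCCGCUUAAGCGGCCGAUGAAAAAAAAAAAAAAAGGCCGC")
for s in scan_seed_sites(mir, utr):
    v = assess_accessibility(utr, s)
    print(s.site_class, (s.start, s.end), v.energy_gap_pass, v.inhibitory_structure)
# 6mer-seed (17, 23) True True

fit = fit_efficiency([(5**k, 21.0 + k * math.log2(5)) for k in range(1, 5)])
print(round(fit.efficiency, 3), round(fit.slope, 3))   # 2.0 -3.322

spec = SyntheticSpec(seed=1, cq_noise_sd=0.25,
                     cq_groups={"GENE1": {"adenoma": -2.0}},
                     n_per_group={"normal": 10, "adenoma": 10})
table, _ = gen_cq(spec, target_assays=("GENE1",))
delta = normalize(table).delta_cq["GENE1"]
res = compare_groups(delta, table.group, "adenoma", "normal")
print(f"ddCq={res.delta_delta_cq:.3f} fold={res.fold_change:.2f} p={res.p_value:.2e}")
# ddCq=-2.026 fold=4.07 p=1.08e-05
```

The site at [17, 23) is a perfect seed complement (`UGUCAU`, the
reverse complement of `AUGACA`); its downstream flank folds to
−27.3 kcal/mol against 0.0 for the unstructured site, so the
≥ 10 kcal/mol energy-gap rule passes, while the GC-rich stem overlapping
the window marks it as potentially occluded. The Cq table was simulated
with a −2-cycle shift in adenoma (a true 4-fold upregulation); the
pipeline recovers fold 4.07 with Mann–Whitney p ≈ 10⁻⁵.

The same stages are available from a shell:

```bash
mirprio simulate --seed 7 --out run/      # synthetic inputs + ground truth
mirprio all --config run/config.yaml      # scan -> fold -> prioritize + qPCR
```

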