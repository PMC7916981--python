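"""Efficiency-corrected relative quantification and nonparametric statistics.

Implements the standard qPCR workflow: amplification efficiency from a
dilution series (Cq regressed on log10 of relative input), per-sample
normalization of target Cq against the reference-gene aggregate (the
geometric mean of reference quantities, i.e. the arithmetic mean of
reference Cq values, with a literal geometric-mean-of-Cq option for
sensitivity checks), group comparison via ddCq with fold change
2**(-ddCq), and Wilcoxon signed-rank / Mann-Whitney U / Spearman
statistics.

Sample groups follow the adenoma-carcinoma sequence: normal mucosa,
adenoma, adenoma with early carcinoma, carcinoma without (CRC N0) and
with (CRC N+) lymph-node metastases; the ordinal coding 0..4 of that
sequence is the "level of malignancy" used for rank correlations.
Not-detected assays stay missing and are excluded from comparisons,
never imputed.  No multiple-testing correction is applied by default
(p <= 0.05 is the significance convention); a Benjamini-Hochberg helper
is available but off by default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("normal", "adenoma", "adenoma_early_ca", "crc_n0", "crc_n+")

#: ordinal coding of the adenoma-carcinoma sequence
MALIGNANCY_LEVEL = {g: i for i, g in enumerate(GROUPS)}

CQ_MAX = 45.0


class AnalysisError(ValueError):
    """Raised when an analysis precondition is not met."""


@dataclass
class CqTable:
    """Raw quantification cycles for samples x assays.

    ``cq`` has samples as the index and assays as columns; missing values
    mean not detected.  ``group`` maps every sample to its study group,
    ``reference_assays`` names the stable normalizer assays, and
    ``paired_normal`` optionally links a lesion sample to its patient's
    normal-mucosa sample.
    """

    cq: pd.DataFrame
    group: pd.Series
    reference_assays: tuple[str, ...]
    paired_normal: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reference_assays:
            raise ValueError("at least one reference assay is required")
        missing_refs = set(self.reference_assays) - set(self.cq.columns)
        if missing_refs:
            raise ValueError(f"reference assays not in table: {sorted(missing_refs)}")
        missing_groups = set(self.cq.index) - set(self.group.index)
        if missing_groups:
            raise ValueError(f"samples without a group: {sorted(missing_groups)}")
        unknown = set(self.group.loc[list(self.cq.index)]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown sample groups: {sorted(unknown)}")
        values = self.cq.to_numpy(dtype=float)
        bad = (values <= 0) | (values > CQ_MAX)
        if np.any(bad & ~np.isnan(values)):
            raise ValueError(f"Cq values must lie in (0, {CQ_MAX}] or be missing")

    @property
    def target_assays(self) -> tuple[str, ...]:
        return tuple(a for a in self.cq.columns if a not in self.reference_assays)

    @classmethod
    def from_long_tsv(cls, path: Union[str, Path]) -> "CqTable":
        """Read the long-format Cq TSV (columns: sample, group,
        paired_normal_id, assay, role, cq; empty cq = not detected)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "group", "assay", "role", "cq"}
        if not required <= set(df.columns):
            raise ValueError(f"Cq table needs columns {sorted(required)}")
        df["cq_val"] = pd.to_numeric(df["cq"], errors="coerce")
        cq = df.pivot_table(
            index="sample", columns="assay", values="cq_val", aggfunc="mean", sort=False
        )
        group = df.drop_duplicates("sample").set_index("sample")["group"]
        refs = tuple(sorted(df.loc[df["role"] == "reference", "assay"].unique()))
        paired = {}
        if "paired_normal_id" in df.columns:
            sub = df.drop_duplicates("sample").set_index("sample")["paired_normal_id"]
            paired = {s: p for s, p in sub.items() if isinstance(p, str) and p}
        return cls(cq=cq, group=group, reference_assays=refs, paired_normal=paired)

    def to_long_tsv(self, path: Union[str, Path]) -> None:
        """Write the table back in the long TSV format."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample", "group", "paired_normal_id", "assay", "role", "cq"])
            for sample in self.cq.index:
                for assay in self.cq.columns:
                    value = self.cq.loc[sample, assay]
                    writer.writerow(
                        [
                            sample,
                            self.group.loc[sample],
                            self.paired_normal.get(sample, ""),
                            assay,
                            "reference" if assay in self.reference_assays else "target",
                            "" if pd.isna(value) else f"{value:.6g}",
                        ]
                    )


@dataclass(frozen=True)
class EfficiencyFit:
    """Amplification efficiency from a dilution series."""

    assay: str
    slope: float  # Cq per log10(relative concentration); negative
    efficiency: float  # amplification factor per cycle; 2.0 = perfect
    r_squared: float

    @property
    def accepted(self) -> bool:
        """Standard acceptance band for qPCR efficiencies."""
        return 1.0 < self.efficiency <= 2.3 and self.slope < 0


@dataclass(frozen=True)
class ExpressionResult:
    """A group comparison of normalized expression for one assay."""

    assay: str
    comparison: tuple[str, str]
    delta_cq_a: tuple[float, ...]
    delta_cq_b: tuple[float, ...]
    delta_delta_cq: float
    fold_change: float
    p_value: float
    test_name: str  # wilcoxon_signed_rank | mann_whitney_u
    #: U (Mann-Whitney, for the first group) or W (Wilcoxon signed-rank)
    statistic: Optional[float] = None

    @property
    def direction(self) -> str:
        if self.fold_change > 1:
            return "up"
        if self.fold_change < 1:
            return "down"
        return "none"

    @property
    def fold_display(self) -> str:
        """Human-readable fold: reciprocal x-fold for downregulation."""
        if self.fold_change >= 1:
            return f"{self.fold_change:.2f}-fold up"
        return f"{1.0 / self.fold_change:.2f}-fold down"


def fit_efficiency(
    dilution_cqs: Sequence[tuple[float, float]], assay: str = ""
) -> EfficiencyFit:
    """Fit amplification efficiency from (dilution_factor, Cq) points.

    Cq is regressed on log10 of the relative concentration (1/dilution);
    efficiency = 10**(-1/slope).  A 4-point 5-fold series (5x to 625x)
    from a perfectly doubling assay yields efficiency 2.0 exactly.
    Requires >= 3 distinct dilution points and a negative, non-zero
    slope.
    """
    if len(dilution_cqs) < 3:
        raise AnalysisError(
            f"efficiency fit needs >= 3 dilution points, got {len(dilution_cqs)}"
        )
    dilutions = np.array([d for d, _ in dilution_cqs], dtype=float)
    cqs = np.array([c for _, c in dilution_cqs], dtype=float)
    if np.any(dilutions <= 0):
        raise AnalysisError("dilution factors must be positive")
    x = -np.log10(dilutions)  # log10 relative concentration
    if len(np.unique(x)) < 3:
        raise AnalysisError("efficiency fit needs >= 3 distinct dilutions")
    slope, intercept = np.polyfit(x, cqs, 1)
    predicted = slope * x + intercept
    ss_res = float(np.sum((cqs - predicted) ** 2))
    ss_tot = float(np.sum((cqs - cqs.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if abs(slope) < 1e-12 or slope > 0:
        raise AnalysisError(
            f"non-negative or zero slope ({slope:.3g}): efficiency undefined"
        )
    efficiency = 10.0 ** (-1.0 / slope)
    return EfficiencyFit(assay=assay, slope=float(slope), efficiency=float(efficiency), r_squared=r_squared)


@dataclass(frozen=True)
class NormalizedCq:
    """Per-sample dCq per target assay, with exclusions logged."""

    delta_cq: pd.DataFrame  # samples x target assays; NaN = not detected
    excluded: tuple[tuple[str, str], ...]  # (sample, reason)


def normalize(
    table: CqTable,
    efficiency_correction: bool = False,
    efficiencies: Optional[Mapping[str, float]] = None,
    ref_aggregate: str = "mean",
) -> NormalizedCq:
    """dCq(sample, target) = Cq_target - aggregate(reference Cqs).

    The default aggregate is the arithmetic mean of reference Cq values,
    which equals the geometric mean of the linear reference quantities;
    ``ref_aggregate='geometric'`` takes a literal geometric mean of the
    Cq values instead.  With ``efficiency_correction`` each assay's Cq
    is first rescaled to a common log2 basis as log2(E) * Cq (an assay
    with efficiency 2 is unchanged).  Samples missing any reference
    assay are excluded with a reason; missing targets stay missing.
    """
    if ref_aggregate not in ("mean", "geometric"):
        raise ValueError("ref_aggregate must be 'mean' or 'geometric'")
    cq = table.cq.astype(float).copy()
    if efficiency_correction:
        efficiencies = dict(efficiencies or {})
        for assay in cq.columns:
            e = efficiencies.get(assay, 2.0)
            if not (1.0 < e):
                raise AnalysisError(f"efficiency for {assay!r} must exceed 1, got {e}")
            cq[assay] = cq[assay] * math.log2(e)
    refs = cq[list(table.reference_assays)]
    excluded = []
    keep = []
    for sample in cq.index:
        if refs.loc[sample].isna().any():
            missing = [a for a in table.reference_assays if pd.isna(refs.loc[sample, a])]
            excluded.append((sample, f"reference assay(s) not detected: {missing}"))
        else:
            keep.append(sample)
    refs = refs.loc[keep]
    if ref_aggregate == "mean":
        ref_agg = refs.mean(axis=1)
    else:
        ref_agg = np.exp(np.log(refs).mean(axis=1))
    targets = [a for a in cq.columns if a not in table.reference_assays]
    delta = cq.loc[keep, targets].sub(ref_agg, axis=0)
    return NormalizedCq(delta_cq=delta, excluded=tuple(excluded))


def _test_mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first group, p-value):
    exact for n <= 12 without ties, else normal approximation with tie
    correction (no continuity shift)."""
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and max(len(a), len(b)) <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def _test_wilcoxon(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank (W, p) on paired differences."""
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    nz = diffs[diffs != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (not has_ties and len(nz) <= 12) else "approx"
    res = stats.wilcoxon(
        diffs, alternative="two-sided", zero_method="wilcox", method=method,
        correction=False,
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    delta_cq: pd.Series,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    paired: bool = False,
    paired_normal: Optional[Mapping[str, str]] = None,
    assay: str = "",
    agg: str = "mean",
) -> ExpressionResult:
    """Compare normalized expression between two sample groups.

    ddCq = mean dCq(group_a) - mean dCq(group_b) (median optional via
    ``agg``); fold change = 2**(-ddCq), so a negative ddCq is
    upregulation of group_a.  The p-value comes from the Wilcoxon
    signed-rank test on within-patient pairs (``paired=True``, pairing
    via ``paired_normal``) or the Mann-Whitney U test for independent
    groups.  Requires >= 3 usable samples (pairs) per group.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    values = delta_cq.dropna()
    in_a = values.index[groups.loc[values.index] == group_a]
    in_b = values.index[groups.loc[values.index] == group_b]
    if paired:
        if paired_normal is None:
            raise AnalysisError("paired comparison requires a paired_normal mapping")
        pairs = [
            (s, paired_normal[s])
            for s in in_a
            if s in paired_normal and paired_normal[s] in set(in_b)
        ]
        if len(pairs) < 3:
            raise AnalysisError(
                f"paired comparison {group_a} vs {group_b}: {len(pairs)} usable "
                "pairs, need >= 3"
            )
        a = values.loc[[p[0] for p in pairs]].to_numpy()
        b = values.loc[[p[1] for p in pairs]].to_numpy()
        statistic, p_value = _test_wilcoxon(a - b)
        test_name = "wilcoxon_signed_rank"
    else:
        a = values.loc[in_a].to_numpy()
        b = values.loc[in_b].to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise AnalysisError(
                f"independent comparison {group_a} (n={len(a)}) vs {group_b} "
                f"(n={len(b)}): need >= 3 per group"
            )
        statistic, p_value = _test_mwu(a, b)
        test_name = "mann_whitney_u"
    reduce = np.mean if agg == "mean" else np.median
    ddcq = float(reduce(a) - reduce(b))
    return ExpressionResult(
        assay=assay,
        comparison=(group_a, group_b),
        delta_cq_a=tuple(float(v) for v in a),
        delta_cq_b=tuple(float(v) for v in b),
        delta_delta_cq=ddcq,
        fold_change=float(2.0 ** (-ddcq)),
        p_value=p_value,
        test_name=test_name,
        statistic=statistic,
    )


def per_sample_ddcq(
    delta_cq: pd.Series,
    paired_normal: Mapping[str, str],
    samples: Iterable[str],
) -> pd.Series:
    """ddCq per sample against its corresponding normal-mucosa sample."""
    out = {}
    for s in samples:
        normal = paired_normal.get(s)
        if normal is None:
            continue
        a, b = delta_cq.get(s), delta_cq.get(normal)
        if a is not None and b is not None and not (pd.isna(a) or pd.isna(b)):
            out[s] = float(a - b)
    return pd.Series(out, dtype=float)


def compare_independent_ddcq(
    ddcq_a: Sequence[float],
    ddcq_b: Sequence[float],
    comparison: tuple[str, str] = ("crc_n0", "crc_n+"),
    assay: str = "",
) -> ExpressionResult:
    """Mann-Whitney U on per-sample ddCq values of two independent groups
    (each sample's ddCq computed against its corresponding normal)."""
    a = np.asarray([v for v in ddcq_a if not pd.isna(v)], dtype=float)
    b = np.asarray([v for v in ddcq_b if not pd.isna(v)], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise AnalysisError(
            f"ddCq comparison needs >= 3 per group, got {len(a)} and {len(b)}"
        )
    diff = float(np.mean(a) - np.mean(b))
    statistic, p_value = _test_mwu(a, b)
    return ExpressionResult(
        assay=assay,
        comparison=comparison,
        delta_cq_a=tuple(float(v) for v in a),
        delta_cq_b=tuple(float(v) for v in b),
        delta_delta_cq=diff,
        fold_change=float(2.0 ** (-diff)),
        p_value=p_value,
        test_name="mann_whitney_u",
        statistic=statistic,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-tailed p.

    Used both for miRNA-mRNA anticorrelation (dCq vs dCq) and for
    correlation with the level of malignancy (dCq vs the ordinal group
    code from :data:`MALIGNANCY_LEVEL`).  Requires n >= 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise AnalysisError("correlate needs paired observations of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise AnalysisError(f"correlation needs >= 4 complete pairs, got {len(x)}")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def malignancy_levels(groups: pd.Series) -> pd.Series:
    """Ordinal malignancy coding (normal=0 ... CRC N+=4) per sample."""
    return groups.map(MALIGNANCY_LEVEL).astype(float)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional, off by default in
    all pipelines; provided for sensitivity analyses)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adjusted[i] = running
    return [float(v) for v in adjusted]


def write_expression_tsv(
    results: Sequence[ExpressionResult], path: Union[str, Path]
) -> None:
    """Write comparison results as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "assay",
                "group_a",
                "group_b",
                "n_a",
                "n_b",
                "delta_delta_cq",
                "fold_change",
                "direction",
                "fold_display",
                "test",
                "p_value",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.assay,
                    r.comparison[0],
                    r.comparison[1],
                    len(r.delta_cq_a),
                    len(r.delta_cq_b),
                    f"{r.delta_delta_cq:.4f}",
                    f"{r.fold_change:.4f}",
                    r.direction,
                    r.fold_display,
                    r.test_name,
                    f"{r.p_value:.6g}",
                ]
            )
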