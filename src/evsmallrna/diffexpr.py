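"""Count matrices and negative-binomial Wald differential expression.

The testing engine is a transparent reimplementation of the standard
RNA-seq count workflow: median-of-ratios size factors, a per-feature
method-of-moments negative-binomial dispersion, a Wald test on the log2
fold change of group means (delta-method standard error, normal reference),
and Benjamini-Hochberg adjustment.  It deliberately omits dispersion
shrinkage toward a fitted trend, so per-feature results will differ in
detail from shrinkage-based tools while agreeing on strong signals.

Two significance conventions are provided: the miRNA rule
(|log2FC| >= 1 and raw p < 0.05) and the tsRNA rule (additionally
BH-adjusted p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotatedRead
from .tsrna import TsRNARecord

__all__ = [
    "SampleInfo",
    "CountMatrix",
    "DETestResult",
    "build_count_matrix",
    "filter_low_expression",
    "estimate_size_factors",
    "normalized_counts",
    "nb_wald_test",
    "call_significant",
    "results_to_frame",
]

CELL_TYPES = ("ASC", "BMSC")
COMPARTMENTS = ("cell", "EV")
DAYS = ("D0", "D7")

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    cell_type: str
    compartment: str
    day: str
    donor: int

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.day not in DAYS:
            raise ValueError(f"unknown day {self.day!r}")


@dataclass
class CountMatrix:
    """Integer feature x sample counts with per-sample design metadata."""

    counts: pd.DataFrame  # features x samples, integer
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if list(self.counts.columns) != ids:
            raise ValueError("count columns must match sample sheet order")
        design = {(s.cell_type, s.compartment, s.day, s.donor)
                  for s in self.samples}
        if len(design) != len(self.samples):
            raise ValueError("duplicate (cell_type, compartment, day, donor)")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def subset(self, cell_type: str | None = None,
               compartment: str | None = None) -> "CountMatrix":
        keep = [s for s in self.samples
                if (cell_type is None or s.cell_type == cell_type)
                and (compartment is None or s.compartment == compartment)]
        ids = [s.sample_id for s in keep]
        return CountMatrix(self.counts[ids].copy(), keep)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.cell_type, s.compartment, s.day, s.donor)
             for s in self.samples],
            columns=["sample_id", "cell_type", "compartment", "day", "donor"],
        ).set_index("sample_id")


@dataclass
class DETestResult:
    feature: str
    base_mean: float
    log2fc: float
    lfc_se: float
    wald_p: float
    padj: float = np.nan
    significant: bool = False


def build_count_matrix(annotations: dict[str, list[AnnotatedRead]],
                       samples: list[SampleInfo],
                       level: str,
                       tsrna_records: dict[str, list[TsRNARecord]] | None = None,
                       ) -> CountMatrix:
    """Count annotated reads per feature and sample.

    ``level`` is "miRNA" (count by mature-miRNA name) or "tsRNA" (count by
    tRNA isoacceptor, collapsing half/fragment records per isoacceptor).
    Features absent from a sample get 0.
    """
    if level not in ("miRNA", "tsRNA"):
        raise ValueError("level must be 'miRNA' or 'tsRNA'")
    ids = [s.sample_id for s in samples]
    if set(annotations) != set(ids):
        raise ValueError("annotations and sample sheet disagree on sample ids")
    per_sample: dict[str, dict[str, int]] = {}
    for sid in ids:
        counts: dict[str, int] = {}
        if level == "miRNA":
            for a in annotations[sid]:
                if a.category == "miRNA":
                    counts[a.ref_name] = counts.get(a.ref_name, 0) + 1
        else:
            recs = (tsrna_records or {}).get(sid)
            if recs is None:
                recs = [TsRNARecord(a.read_id, a.ref_name, a.ref_start,
                                    a.ref_end, "fragment")
                        for a in annotations[sid] if a.category == "tRNA"]
            for r in recs:
                counts[r.trna_name] = counts.get(r.trna_name, 0) + 1
        per_sample[sid] = counts
    features = sorted({f for c in per_sample.values() for f in c})
    mat = pd.DataFrame(0, index=features, columns=ids, dtype=int)
    for sid, counts in per_sample.items():
        for feat, n in counts.items():
            mat.loc[feat, sid] = n
    return CountMatrix(mat, samples)


def filter_low_expression(cm: CountMatrix, threshold: int = 50) -> CountMatrix:
    """Drop features whose raw counts are below ``threshold`` in every sample.

    A feature is kept iff its maximum count over all samples is >= threshold
    (boundary inclusive); feature order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = cm.counts.max(axis=1) >= threshold
    return CountMatrix(cm.counts.loc[keep].copy(), cm.samples)


def estimate_size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over features with positive
    counts in every sample of count / geometric-mean-of-that-feature.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no feature has positive counts in every sample")
    ref = arr[all_pos]
    geo = np.exp(np.log(ref).mean(axis=1))
    ratios = ref / geo[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix,
                      size_factors: pd.Series | None = None) -> pd.DataFrame:
    sf = estimate_size_factors(cm) if size_factors is None else size_factors
    return cm.counts / sf


def nb_wald_test(cm: CountMatrix, contrast: tuple[str, str] = ("D7", "D0"),
                 size_factors: pd.Series | None = None) -> list[DETestResult]:
    """Per-feature NB Wald test of ``contrast[0]`` vs ``contrast[1]`` (by day).

    log2FC = log2((mean_num + 0.5) / (mean_den + 0.5)) on size-factor
    normalized counts; positive values mean higher at the first (D7) level.
    Dispersion is method-of-moments on normalized counts pooled across both
    groups, floored at 1e-8; the Wald SE comes from the delta method with
    NB variance mu*s + alpha*(mu*s)^2 per sample.  Features with all-zero
    counts are reported with NaN p-values and excluded from BH adjustment.
    """
    num, den = contrast
    groups = {day: [s.sample_id for s in cm.samples if s.day == day]
              for day in (num, den)}
    for day, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"need >= 2 samples at {day}, got {len(ids)}")
    sf = estimate_size_factors(cm) if size_factors is None else size_factors
    norm = cm.counts / sf
    results: list[DETestResult] = []
    ln2 = np.log(2.0)
    for feat in cm.counts.index:
        row = norm.loc[feat]
        raw = cm.counts.loc[feat]
        x_num = row[groups[num]].to_numpy()
        x_den = row[groups[den]].to_numpy()
        base_mean = float(np.concatenate([x_num, x_den]).mean())
        if (raw[groups[num] + groups[den]] == 0).all():
            results.append(DETestResult(feat, 0.0, 0.0, np.nan, np.nan))
            continue
        mu_num, mu_den = x_num.mean(), x_den.mean()
        pooled = np.concatenate([x_num, x_den])
        mu, s2 = pooled.mean(), pooled.var(ddof=1)
        alpha = max(DISPERSION_FLOOR, (s2 - mu) / max(mu, 1e-12) ** 2)
        log2fc = float(np.log2((mu_num + LOG2FC_PSEUDOCOUNT)
                               / (mu_den + LOG2FC_PSEUDOCOUNT)))
        var_terms = []
        for mu_g, ids in ((mu_num, groups[num]), (mu_den, groups[den])):
            s_i = sf[ids].to_numpy()
            # Var(X_i / s_i) for X_i ~ NB(mu_g * s_i, alpha)
            v_mean = ((mu_g / s_i + alpha * mu_g ** 2).sum()
                      / len(ids) ** 2)
            var_terms.append(v_mean / (mu_g + LOG2FC_PSEUDOCOUNT) ** 2)
        lfc_se = float(np.sqrt(sum(var_terms)) / ln2)
        if lfc_se <= 0:
            z = 0.0
        else:
            z = log2fc / lfc_se
        p = float(2.0 * sps.norm.sf(abs(z)))
        results.append(DETestResult(feat, base_mean, log2fc, lfc_se, p))
    tested = [r for r in results if np.isfinite(r.wald_p)]
    if tested:
        padj = multipletests([r.wald_p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, padj):
            r.padj = float(q)
    return results


def call_significant(results: list[DETestResult],
                     rule: str) -> list[DETestResult]:
    """Apply a significance convention in place and return the results.

    ``mirna``: |log2FC| >= 1 and raw p < 0.05.
    ``tsrna``: |log2FC| >= 1 and BH-adjusted p < 0.05.
    """
    if rule not in ("mirna", "tsrna"):
        raise ValueError(f"unknown rule {rule!r}")
    for r in results:
        if not np.isfinite(r.wald_p):
            r.significant = False
            continue
        strong = abs(r.log2fc) >= 1.0
        if rule == "mirna":
            r.significant = bool(strong and r.wald_p < 0.05)
        else:
            r.significant = bool(strong and np.isfinite(r.padj)
                                 and r.padj < 0.05)
    return results


def results_to_frame(results: list[DETestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.base_mean, r.log2fc, r.lfc_se, r.wald_p, r.padj,
          r.significant) for r in results],
        columns=["feature", "baseMean", "log2FoldChange", "lfcSE", "pvalue",
                 "padj", "significant"],
    ).set_index("feature")
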