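"""Statistical assessment of a core collection against the full collection.

Per trait: a bootstrap Levene test decides between the pooled-variance
Student t-test (homogeneous variances) and Welch's t-test for the mean
comparison of quantitative traits; qualitative traits use the chi-squared
test of homogeneity (Yates-corrected for 2x2 tables). The aggregate
report carries the five classical core-collection percentages —

    MD% = (1/m) sum |M_e - M_c| / M_c * 100      (mean difference)
    VD% = (1/m) sum |V_e - V_c| / V_c * 100      (variance difference)
    CR% = (1/m) sum R_c / R_e * 100              (coincidence rate)
    VR% = (1/m) sum CV_c / CV_e * 100            (variable rate)
    Coverage% = (1/m) sum D_c / D_e * 100        (class/cluster coverage)

with subscripts e = entire collection, c = core. MD/VD/CR/VR aggregate
over the quantitative traits (ranges and CVs are undefined for
qualitative ones); Coverage% is reported separately for quantitative,
qualitative and combined trait sets. The representativeness verdict
requires at most 20% of traits with a significant mean difference and a
coincidence rate above 80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
DEFAULT_BOOTSTRAP = 1000


@dataclass
class TraitTestResult:
    trait: str
    test: str  # student_t | welch_t | chi2 | chi2_yates
    statistic: float
    p: float
    levene_p: float | None = None

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class EvaluationReport:
    MD_pct: float
    VD_pct: float
    CR_pct: float
    VR_pct: float
    coverage_quant_pct: float
    coverage_qual_pct: float
    coverage_combined_pct: float
    pct_significant: float
    per_trait: list[TraitTestResult] = field(default_factory=list)

    @property
    def verdict(self) -> bool:
        return self.pct_significant <= 20.0 and self.CR_pct > 80.0

    def to_dict(self) -> dict:
        return {
            "MD_pct": self.MD_pct,
            "VD_pct": self.VD_pct,
            "CR_pct": self.CR_pct,
            "VR_pct": self.VR_pct,
            "coverage_quant_pct": self.coverage_quant_pct,
            "coverage_qual_pct": self.coverage_qual_pct,
            "coverage_combined_pct": self.coverage_combined_pct,
            "pct_significant": self.pct_significant,
            "verdict": self.verdict,
            "per_trait": [
                {
                    "trait": r.trait,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p": r.p,
                    "levene_p": r.levene_p,
                    "significant": r.significant,
                }
                for r in self.per_trait
            ],
        }


def _levene_W(groups: list[np.ndarray]) -> float:
    """Mean-centered Levene statistic on absolute deviations."""
    z = [np.abs(g - g.mean()) for g in groups]
    k = len(z)
    ns = np.array([len(g) for g in z])
    N = ns.sum()
    zbars = np.array([g.mean() for g in z])
    zbar = np.concatenate(z).mean()
    num = (N - k) * (ns * (zbars - zbar) ** 2).sum()
    den = (k - 1) * sum(((g - gb) ** 2).sum() for g, gb in zip(z, zbars))
    if den == 0:
        return 0.0 if num == 0 else np.inf
    return float(num / den)


def levene_bootstrap(
    x_e, x_c, B: int = DEFAULT_BOOTSTRAP, seed: int = 0
) -> float:
    """Bootstrap p-value for Levene's test of variance homogeneity.

    The observed mean-centered Levene statistic W is referred to its
    bootstrap null distribution: both groups are centered, pooled, and B
    resamples of the original group sizes are drawn with replacement from
    the pooled centered values. p = (1 + #{W* >= W}) / (B + 1). Two
    zero-variance groups return p = 1.
    """
    x_e = np.asarray(x_e, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    if len(x_e) < 2 or len(x_c) < 2:
        raise ValueError("both samples need >= 2 observations")
    if B < 1:
        raise ValueError("B must be >= 1")
    if x_e.var() == 0 and x_c.var() == 0:
        return 1.0
    W = _levene_W([x_e, x_c])
    pooled = np.concatenate([x_e - x_e.mean(), x_c - x_c.mean()])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        a = rng.choice(pooled, size=len(x_e), replace=True)
        b = rng.choice(pooled, size=len(x_c), replace=True)
        if _levene_W([a, b]) >= W:
            exceed += 1
    return float((1 + exceed) / (B + 1))


def levene_asymptotic(x_e, x_c) -> float:
    """Asymptotic-F fallback (mean-centered Levene)."""
    return float(stats.levene(x_e, x_c, center="mean").pvalue)


def mean_difference_test(
    x_e=None,
    x_c=None,
    levene_p: float = 1.0,
    summary_e: tuple[int, float, float] | None = None,
    summary_c: tuple[int, float, float] | None = None,
    trait: str = "",
) -> TraitTestResult:
    """Two-sided two-sample t-test, pooled or Welch by the Levene verdict.

    Works from raw samples or from summary statistics (n, mean, SD).
    The pooled-variance Student test is used when ``levene_p`` >= 0.05,
    Welch's test otherwise. Zero pooled variance gives p = 1 when the
    means agree and p = 0 otherwise.
    """
    if summary_e is None:
        x_e = np.asarray(x_e, dtype=float)
        summary_e = (len(x_e), float(x_e.mean()), float(x_e.std(ddof=1)))
    if summary_c is None:
        x_c = np.asarray(x_c, dtype=float)
        summary_c = (len(x_c), float(x_c.mean()), float(x_c.std(ddof=1)))
    n1, m1, s1 = summary_e
    n2, m2, s2 = summary_c
    equal_var = levene_p >= ALPHA
    name = "student_t" if equal_var else "welch_t"
    if s1 == 0 and s2 == 0:
        p = 1.0 if m1 == m2 else 0.0
        return TraitTestResult(trait, name, 0.0 if m1 == m2 else np.inf, p, levene_p)
    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=equal_var
    )
    return TraitTestResult(
        trait, name, float(res.statistic), float(res.pvalue), levene_p
    )


def chi2_homogeneity(counts_a, counts_b, trait: str = "") -> TraitTestResult:
    """Chi-squared test of homogeneity on a 2 x S contingency table.

    Categories that are zero in both groups are dropped; the Yates
    continuity correction is applied iff two categories remain. A single
    shared category gives p = 1 by convention.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the category order")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each group needs at least one observation")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    S = a.size
    if S == 1:
        return TraitTestResult(trait, "chi2", 0.0, 1.0)
    correction = S == 2
    res = stats.chi2_contingency(np.vstack([a, b]), correction=correction)
    return TraitTestResult(
        trait,
        "chi2_yates" if correction else "chi2",
        float(res.statistic),
        float(res.pvalue),
    )


@dataclass
class QuantSummary:
    """Per-trait quantitative summary used by the aggregate percentages."""

    n: int
    mean: float
    var: float
    range: float
    cv: float

    @classmethod
    def from_sample(cls, x) -> "QuantSummary":
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        mean = float(x.mean())
        return cls(
            n=len(x),
            mean=mean,
            var=float(x.var(ddof=1)) if len(x) > 1 else 0.0,
            range=float(x.max() - x.min()),
            cv=float(np.sqrt(x.var(ddof=1)) / abs(mean)) if mean != 0 else np.nan,
        )


def cc_properties(
    quant_summaries: dict[str, tuple[QuantSummary, QuantSummary]],
    class_counts: dict[str, tuple[int, int]],
    qual_traits: set[str] | None = None,
    per_trait: list[TraitTestResult] | None = None,
) -> EvaluationReport:
    """Aggregate the five core-collection percentages and the verdict.

    ``quant_summaries`` maps quantitative trait -> (EC summary, CC
    summary); ``class_counts`` maps every trait -> (D_e, D_c), the number
    of clusters/levels represented in each collection. Traits with a zero
    denominator (core mean, EC range, EC CV, D_e) are excluded from the
    affected average with a warning. ``per_trait`` supplies the
    significance tests whose share feeds the verdict.
    """
    import warnings

    md, vd, cr, vr = [], [], [], []
    for name, (e, c) in quant_summaries.items():
        if c.mean == 0 or c.var == 0 or e.range == 0 or e.cv == 0 or np.isnan(e.cv):
            warnings.warn(f"trait {name!r} excluded (zero denominator)")
            continue
        md.append(abs(e.mean - c.mean) / abs(c.mean) * 100)
        vd.append(abs(e.var - c.var) / c.var * 100)
        cr.append(c.range / e.range * 100)
        vr.append(c.cv / e.cv * 100)

    qual_traits = qual_traits or set()
    cov_q, cov_l = [], []
    for name, (d_e, d_c) in class_counts.items():
        if d_e == 0:
            warnings.warn(f"trait {name!r} excluded from coverage (D_e = 0)")
            continue
        (cov_l if name in qual_traits else cov_q).append(d_c / d_e * 100)

    per_trait = per_trait or []
    n_sig = sum(r.significant for r in per_trait)
    pct_sig = 100.0 * n_sig / len(per_trait) if per_trait else 0.0

    def _mean(v):
        return float(np.mean(v)) if v else np.nan

    return EvaluationReport(
        MD_pct=_mean(md),
        VD_pct=_mean(vd),
        CR_pct=_mean(cr),
        VR_pct=_mean(vr),
        coverage_quant_pct=_mean(cov_q),
        coverage_qual_pct=_mean(cov_l),
        coverage_combined_pct=_mean(cov_q + cov_l),
        pct_significant=pct_sig,
        per_trait=per_trait,
    )


def evaluate_collections(
    ec,
    cc,
    clusterings: dict | None = None,
    B: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> EvaluationReport:
    """Full EC-vs-CC assessment from two phenotype tables.

    Runs the per-trait Levene + t / chi-squared battery, collects the
    quantitative summaries and the per-trait class counts (qualitative
    levels; cluster occupancy for quantitative traits when per-trait
    clusterings are supplied), and aggregates the report.
    """
    from .diversity_metrics import trait_class_counts

    clusterings = clusterings or {}
    rng = np.random.default_rng(seed)
    per_trait: list[TraitTestResult] = []
    quant_summaries = {}
    class_counts = {}
    for spec in ec.schema:
        if spec.is_quantitative:
            x_e = ec.data[spec.name].dropna().to_numpy(dtype=float)
            x_c = cc.data[spec.name].dropna().to_numpy(dtype=float)
            lp = levene_bootstrap(x_e, x_c, B=B, seed=int(rng.integers(2**31)))
            per_trait.append(
                mean_difference_test(x_e, x_c, levene_p=lp, trait=spec.name)
            )
            quant_summaries[spec.name] = (
                QuantSummary.from_sample(x_e),
                QuantSummary.from_sample(x_c),
            )
            model = clusterings.get(spec.name)
            if model is not None:
                class_counts[spec.name] = (
                    len(trait_class_counts(ec, spec.name, model)),
                    len(trait_class_counts(cc, spec.name, model)),
                )
        else:
            order = [
                lv
                for lv in spec.levels
                if lv in set(ec.data[spec.name].dropna())
                or lv in set(cc.data[spec.name].dropna())
            ]
            a = [int((ec.data[spec.name] == lv).sum()) for lv in order]
            b = [int((cc.data[spec.name] == lv).sum()) for lv in order]
            per_trait.append(chi2_homogeneity(a, b, trait=spec.name))
            class_counts[spec.name] = (
                len(trait_class_counts(ec, spec.name)),
                len(trait_class_counts(cc, spec.name)),
            )
    return cc_properties(
        quant_summaries,
        class_counts,
        qual_traits=set(ec.schema.qualitative),
        per_trait=per_trait,
    )
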