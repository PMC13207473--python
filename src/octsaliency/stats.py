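"""Two-phase clinician-evaluation statistics for saliency-method comparison.

Phase 1 screens candidate methods: two independent reviewers score 100
heatmaps per method on a 0-4 Likert scale; method-level means are compared
between reviewers (Kendall tau-b, Spearman rho) and combined into a ranking.
Phase 2 analyses the multi-expert questionnaire: ordinal descriptives,
repeated-measures Friedman tests with Kendall's W effect size, Wilcoxon
signed-rank post hoc comparisons with Holm correction, and Kruskal-Wallis
tests across professional groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PHASE1_SCREENING",
    "TestResult",
    "load_ratings",
    "validate_ratings",
    "describe",
    "rank_concordance",
    "phase1_rank",
    "friedman_w",
    "wilcoxon_holm",
    "kruskal_groups",
    "build_report",
]

RATER_GROUPS = ("retina", "general", "resident")
FORMS = ("main", "supplementary")

# Published Phase-1 screening table: mean score over 100 heatmaps per method
# for each reviewer.  Shipped as input data for ranking and concordance.
_PHASE1_CSV = """\
method,variant,ophthalmologist,ai_specialist
Grad-CAM,Baseline,2.26,2.88
Grad-CAM++,Baseline,3.14,2.94
Score-CAM,Baseline,1.55,1.03
Eigen-CAM,Baseline,1.47,1.17
HighRes-CAM,Baseline,2.24,1.88
EL-GWAA,Baseline,2.45,2.13
Self-Attention,Baseline,2.35,3.17
TRAST,vs1,3.38,3.25
TRAST,vs2,2.1,2.56
CGFM,vs1,2.72,2.41
CGFM,vs2,3.19,2.89
CGFM-weighted,Baseline,3.03,3.36
"""


def PHASE1_SCREENING() -> pd.DataFrame:
    """The Phase-1 reviewer mean-score table (12 methods x 2 reviewers)."""
    return pd.read_csv(StringIO(_PHASE1_CSV))


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int | None
    p_value: float
    effect_size: float | None = None
    adjusted_p: dict[tuple[str, str], float] = field(default_factory=dict)
    note: str = ""


# ----------------------------------------------------------------- ratings
RATING_COLUMNS = ("rater_id", "group", "form", "image_set", "diagnosis", "method", "score")


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    if not df["score"].between(0, 4).all():
        raise ValueError("scores must lie in 0..4")
    dup = df.duplicated(subset=["rater_id", "form", "image_set", "method"])
    if dup.any():
        raise ValueError("duplicate (rater, form, image_set, method) records")
    return df


def load_ratings(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))


def describe(records: pd.DataFrame, by=("method",)) -> pd.DataFrame:
    """Ordinal descriptives per group: mean, median, IQR, % favorable (3-4),
    % low (0-1)."""
    if len(records) == 0:
        raise ValueError("no rating records")
    rows = []
    for keys, grp in records.groupby(list(by)):
        s = grp["score"].to_numpy()
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(zip(by, keys))
            | {
                "n": len(s),
                "mean": s.mean(),
                "median": float(np.median(s)),
                "q25": float(np.percentile(s, 25)),
                "q75": float(np.percentile(s, 75)),
                "pct_favorable": 100.0 * np.isin(s, (3, 4)).mean(),
                "pct_low": 100.0 * np.isin(s, (0, 1)).mean(),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- phase 1
def rank_concordance(x, y) -> dict[str, float]:
    """Kendall tau-b and Spearman rho between two sets of method-level means."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    tau = sps.kendalltau(x, y, method="auto")
    rho = sps.spearmanr(x, y)
    return {
        "tau_b": float(tau.statistic),
        "rho": float(rho.statistic),
        "p_tau": float(tau.pvalue),
        "p_rho": float(rho.pvalue),
    }


def _half_up(value: Decimal, places: int = 2) -> float:
    return float(value.quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


def phase1_rank(scores: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Rank methods by the mean of the two reviewer means (half-up to 2 dp).

    Accepts either the wide screening table (ophthalmologist / ai_specialist
    columns) or a long table with `rater_role` and `mean_score`.  Ties are
    reported explicitly via dense ranks and an `in_top_k` flag that includes
    every method tied at the k-th rank.
    """
    df = scores.copy()
    if "rater_role" in df.columns:
        df = df.pivot_table(index=["method", "variant"], columns="rater_role",
                            values="mean_score", aggfunc="first").reset_index()
        df.columns.name = None
        missing = {"ophthalmologist", "ai_specialist"} - set(df.columns)
        if missing or df[["ophthalmologist", "ai_specialist"]].isna().any().any():
            raise ValueError("both reviewer roles are required for every method")
    combined = [
        _half_up((Decimal(str(o)) + Decimal(str(a))) / 2)
        for o, a in zip(df["ophthalmologist"], df["ai_specialist"])
    ]
    df["combined_mean"] = combined
    df = df.sort_values("combined_mean", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank"] = df["combined_mean"].rank(method="dense", ascending=False).astype(int)
    kth_rank = df["rank"].iloc[min(k, len(df)) - 1]
    df["in_top_k"] = df["rank"] <= kth_rank
    df["tied"] = df.duplicated("combined_mean", keep=False)
    return df


# ----------------------------------------------------------------- phase 2
def kendalls_w(chi2: float, n_raters: int, k_methods: int) -> float:
    """Kendall's coefficient of concordance W = chi2 / (N (k - 1))."""
    if n_raters < 2 or k_methods < 2:
        raise ValueError("need N >= 2 raters and k >= 2 methods")
    return chi2 / (n_raters * (k_methods - 1))


def friedman_w(matrix: np.ndarray) -> TestResult:
    """Tie-corrected Friedman test with Kendall's W = chi2 / (N (k-1)).

    `matrix` is N raters x k methods with no missing cells; ranks are
    midranks within each rater's row.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an N x k matrix with N >= 2 and k >= 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not allowed")
    N, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    R = ranks.sum(axis=0)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = N * k * (k + 1) - ties / (k - 1)
    if denom <= 0:
        # every row completely tied: no information
        return TestResult("friedman", 0.0, k - 1, 1.0, effect_size=0.0,
                          note="all rows fully tied")
    chi2 = (12.0 * (R**2).sum() - 3.0 * N**2 * k * (k + 1) ** 2) / denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult("friedman", float(chi2), k - 1, p,
                      effect_size=float(chi2 / (N * (k - 1))))


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment with monotonicity, capped at 1."""
    p = np.asarray(pvals, dtype=np.float64)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def wilcoxon_holm(matrix: np.ndarray, labels=None) -> list[TestResult]:
    """Pairwise Wilcoxon signed-rank tests with Holm-corrected p-values.

    Zero differences are discarded; the exact null is used for n <= 25
    without ties, otherwise the normal approximation with tie and continuity
    correction.  A pair whose differences are all zero gets p = 1.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need an N x k matrix with N >= 2")
    k = m.shape[1]
    labels = list(labels) if labels is not None else [f"m{j}" for j in range(k)]
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    results = []
    for a, b in pairs:
        d = m[:, a] - m[:, b]
        nz = d[d != 0]
        if len(nz) == 0:
            results.append(TestResult(f"wilcoxon:{labels[a]}-{labels[b]}", 0.0,
                                      None, 1.0, note="all differences zero"))
            continue
        method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) else "approx"
        stat, p = sps.wilcoxon(m[:, a], m[:, b], zero_method="wilcox",
                               correction=(method == "approx"), method=method)
        results.append(TestResult(f"wilcoxon:{labels[a]}-{labels[b]}",
                                  float(stat), None, float(p)))
    adj = holm_adjust([r.p_value for r in results])
    shared = {(labels[a], labels[b]): float(adj[i]) for i, (a, b) in enumerate(pairs)}
    for r in results:
        r.adjusted_p = shared
    return results


def kruskal_groups(respondent_means, groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across professional groups."""
    respondent_means = np.asarray(respondent_means, dtype=np.float64)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [respondent_means[groups == g] for g in uniq]
    if np.ptp(respondent_means) == 0:
        return TestResult("kruskal", 0.0, len(uniq) - 1, 1.0,
                          note="identical distributions")
    stat, p = sps.kruskal(*samples)
    return TestResult("kruskal", float(stat), len(uniq) - 1, float(p))


# ------------------------------------------------------------------ report
def participant_matrix(records: pd.DataFrame, form: str,
                       aggregator: str = "mean") -> pd.DataFrame:
    """Rater x method table of per-rater summary scores within one form."""
    sub = records[records["form"] == form]
    if len(sub) == 0:
        raise ValueError(f"no records for form {form!r}")
    return sub.pivot_table(index="rater_id", columns="method", values="score",
                           aggfunc=aggregator)


def build_report(records: pd.DataFrame, alpha: float = 0.05,
                 aggregator: str = "mean") -> dict:
    """Full Phase-2 analysis: omnibus and post hoc tests per form, per-image
    Friedman tests, pooled / diagnosis-stratified descriptives, and
    group-stratified Kruskal-Wallis tests on the main form."""
    records = validate_ratings(records)
    report: dict = {"forms": {}, "per_image_set": {}, "pooled": None,
                    "by_diagnosis": None, "by_group": {}}

    for form in records["form"].unique():
        pm = participant_matrix(records, form, aggregator)
        methods = list(pm.columns)
        fr = friedman_w(pm.to_numpy())
        entry = {"participant_matrix": pm, "friedman": fr,
                 "descriptives": describe(records[records["form"] == form])}
        if fr.p_value < alpha:
            entry["posthoc"] = wilcoxon_holm(pm.to_numpy(), labels=methods)
        report["forms"][form] = entry

        sets = {}
        sub = records[records["form"] == form]
        for image_set, grp in sub.groupby("image_set"):
            mat = grp.pivot_table(index="rater_id", columns="method",
                                  values="score").to_numpy()
            sets[int(image_set)] = {
                "friedman": friedman_w(mat),
                "method_means": grp.groupby("method")["score"].mean().to_dict(),
                "diagnosis": grp["diagnosis"].iloc[0],
            }
        report["per_image_set"][form] = sets

    report["pooled"] = describe(records)
    report["by_diagnosis"] = describe(records, by=("diagnosis", "method"))

    main = records[records["form"] == "main"]
    if len(main):
        rater_groups = main.groupby("rater_id")["group"].first()
        for method, grp in main.groupby("method"):
            means = grp.groupby("rater_id")["score"].mean()
            report["by_group"][method] = kruskal_groups(
                means.to_numpy(), rater_groups.loc[means.index].to_numpy()
            )
    return report


def report_to_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Flatten a report into delimited-text-friendly tables."""
    tables: dict[str, pd.DataFrame] = {"pooled": report["pooled"],
                                       "by_diagnosis": report["by_diagnosis"]}
    for form, entry in report["forms"].items():
        tables[f"descriptives_{form}"] = entry["descriptives"]
        rows = []
        for iset, res in report["per_image_set"][form].items():
            rows.append({"image_set": iset, "diagnosis": res["diagnosis"],
                         **{f"mean_{k}": v for k, v in res["method_means"].items()},
                         "chi2": res["friedman"].statistic,
                         "p_value": res["friedman"].p_value})
        tables[f"per_image_set_{form}"] = pd.DataFrame(rows).sort_values("image_set")
    return tables
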