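"""Cohort statistics: Pearson correlations, Mann-Whitney U comparisons,
descriptive summaries and a one-command replication of the published
analysis from the bundled cohort table.

Conventions follow the study: two-tailed tests, significance at P < 0.05,
no multiple-testing correction, Pearson correlation applied directly to the
ordinal 1-4 venous-contrast score, and pairwise deletion of missing values
(each statistic uses every record with both variables present).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .core import CohortTable, read_cohort_csv
from .errors import ValidationError

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "Summary",
    "pearson",
    "mann_whitney_u",
    "summarize",
    "count_by_predicate",
    "replicate_published_statistics",
    "simulate_type_i_error",
    "round_half_up",
    "PUBLISHED_RESULTS",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (report formatting; 7.45 -> 7.5, not 7.4)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_tailed: float
    n_pairs: int
    variables: tuple[str, str]

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


@dataclass(frozen=True)
class GroupComparisonResult:
    u_statistic: float  # U of the first group
    p_two_tailed: float
    group_sizes: tuple[int, int]
    group_means: tuple[float, float]
    method: str  # "exact" or "asymptotic"

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


@dataclass(frozen=True)
class Summary:
    n: int
    mean: float
    sd: Optional[float]  # sample SD (n-1); None for a single value
    min: float
    max: float

    def rounded(self, decimals: int = 1) -> dict:
        return {
            "n": self.n,
            "mean": round_half_up(self.mean, decimals),
            "sd": None if self.sd is None else round_half_up(self.sd, decimals),
            "min": round_half_up(self.min, decimals),
            "max": round_half_up(self.max, decimals),
        }


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson(x, y, variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Sample Pearson correlation with a two-tailed t-distribution p-value.

    Missing values (NaN) are dropped pairwise; at least 3 complete pairs and
    nonzero variance in both variables are required.
    """
    xs, ys = _complete_pairs(x, y)
    n = xs.size
    if n < 3:
        raise ValidationError(
            f"pearson({variables[0]}, {variables[1]}): "
            f"needs >= 3 complete pairs, got {n}")
    for name, v in zip(variables, (xs, ys)):
        if np.ptp(v) == 0:
            raise ValidationError(
                f"variable {name!r} is constant; correlation undefined")
    res = sps.pearsonr(xs, ys)  # p from t with n-2 df, two-sided
    return CorrelationResult(r=float(res.statistic),
                             p_two_tailed=float(res.pvalue),
                             n_pairs=int(n), variables=tuple(variables))


def mann_whitney_u(a, b) -> GroupComparisonResult:
    """Two-tailed Mann-Whitney U test.

    U is computed from midranks. The p-value uses the exact null
    distribution when ``n1 * n2 <= 400`` and the pooled data are tie-free;
    otherwise a normal approximation with tie correction and a sign-aware
    continuity correction (U at its null mean gives z = 0, p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be nonempty")

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n1 * n2 <= 400:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue)
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:  # every observation identical
            p = 1.0
        else:
            d = abs(u1 - mu)
            z = max(0.0, d - 0.5) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        method = "asymptotic"
    return GroupComparisonResult(
        u_statistic=float(u1), p_two_tailed=p,
        group_sizes=(n1, n2),
        group_means=(float(a.mean()), float(b.mean())),
        method=method,
    )


def summarize(values) -> Summary:
    """n, mean, sample SD, min, max of the non-missing values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no non-missing values to summarize")
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return Summary(n=int(v.size), mean=float(v.mean()), sd=sd,
                   min=float(v.min()), max=float(v.max()))


# --------------------------------------------------------------------------
# cohort predicates
# --------------------------------------------------------------------------

def _require_field(table: CohortTable, field: str):
    col = table.column(field)
    if not np.any(np.isfinite(col)):
        raise ValidationError(
            f"predicate needs field {field!r}, which is missing for every record")
    return col


_PREDICATES = {
    "complete_loss": ("swi_score", lambda col, thr: col == 1),
    "low_contrast": ("swi_score", lambda col, thr: col <= 3),
    "etco2_above": ("etco2_mmHg", lambda col, thr: col > thr),
    "mri_abnormal": ("mri_signal_code", lambda col, thr: col != 0),
}


def count_by_predicate(
    table: CohortTable,
    predicate: Union[str, Callable],
    threshold: Optional[float] = None,
) -> int:
    """Count records satisfying a named filter (missing values never count).

    Built-ins: ``complete_loss`` (score = 1), ``low_contrast`` (score <= 3),
    ``etco2_above`` (requires ``threshold``), ``mri_abnormal`` (signal code
    != 0). A callable receives each record and returns a bool.
    """
    if callable(predicate):
        return sum(bool(predicate(rec)) for rec in table)
    try:
        field, fn = _PREDICATES[predicate]
    except KeyError:
        raise ValidationError(
            f"unknown predicate {predicate!r}; "
            f"built-ins: {sorted(_PREDICATES)}") from None
    if predicate == "etco2_above" and threshold is None:
        raise ValidationError("etco2_above requires a threshold")
    col = _require_field(table, field)
    ok = np.isfinite(col)
    return int(np.sum(fn(col[ok], threshold)))


# --------------------------------------------------------------------------
# full replication
# --------------------------------------------------------------------------

#: Values printed in the publication, used only to flag which of them the
#: current table reproduces (r to two decimals, means to one, counts exact).
PUBLISHED_RESULTS = {
    "r_swi_ttp": 0.35,
    "p_swi_ttp": 0.036,
    "r_swi_hemoglobin": 0.52,
    "r_swi_hematocrit": 0.65,
    "r_ttp_hemoglobin": 0.35,
    "r_ttp_hematocrit": 0.36,
    "ttp_mean": 7.9, "ttp_sd": 1.4, "ttp_min": 3.7, "ttp_max": 10.2,
    "etco2_mean": 30.9, "etco2_sd": 5.5,
    "n_complete_loss": 19,
    "n_low_contrast": 33,
    "n_etco2_above_35": 2,
    "swi_mean_mri_abnormal": 1.41,
    "swi_mean_mri_normal": 2.05,
    "p_swi_by_mri": 0.04,
}

_CORRELATION_PLAN = [
    ("swi_score", "ttp_frames"),
    ("swi_score", "hemoglobin_g_dl"),
    ("swi_score", "hematocrit_pct"),
    ("swi_score", "etco2_mmHg"),
    ("swi_score", "creatinine"),
    ("swi_score", "urea"),
    ("ttp_frames", "hemoglobin_g_dl"),
    ("ttp_frames", "hematocrit_pct"),
    ("ttp_frames", "etco2_mmHg"),
]

_SUMMARY_PLAN = ["ttp_frames", "etco2_mmHg", "age_years", "hemoglobin_g_dl",
                 "hematocrit_pct", "creatinine", "urea"]

_GROUP_PLAN = [("anesthesia", ["ttp_frames", "swi_score", "hemoglobin_g_dl"]),
               ("mri_abnormal", ["swi_score", "ttp_frames", "hemoglobin_g_dl",
                                 "hematocrit_pct"])]


@dataclass
class ReplicationReport:
    """JSON-able replication of the cohort statistics."""

    report: dict

    def to_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2) + "\n"

    def to_markdown(self) -> str:
        rep = self.report
        lines = ["# Cohort statistics replication", ""]
        lines.append(f"Records: {rep['n_records']}")
        lines.append("")
        lines.append("## Correlations (Pearson, two-tailed)")
        lines.append("")
        lines.append("| pair | r | p | n |")
        lines.append("|---|---|---|---|")
        for key, c in rep["correlations"].items():
            lines.append(f"| {key} | {c['r']:.3f} | {c['p']:.4f} | {c['n']} |")
        if rep["skipped"]:
            lines.append("")
            lines.append("## Skipped")
            lines.append("")
            for msg in rep["skipped"]:
                lines.append(f"- {msg}")
        lines.append("")
        lines.append("## Group comparisons (Mann-Whitney U, two-tailed)")
        lines.append("")
        lines.append("| split | variable | means | U | p | method |")
        lines.append("|---|---|---|---|---|---|")
        for key, g in rep["group_comparisons"].items():
            split, var = key.split(":", 1)
            means = "{:.2f} / {:.2f}".format(*g["group_means"])
            lines.append(f"| {split} | {var} | {means} | {g['u']:.1f} "
                         f"| {g['p']:.4f} | {g['method']} |")
        lines.append("")
        lines.append("## Summaries")
        lines.append("")
        lines.append("| variable | n | mean | sd | min | max |")
        lines.append("|---|---|---|---|---|---|")
        for key, s in rep["summaries"].items():
            sd = "-" if s["sd"] is None else f"{s['sd']:.1f}"
            lines.append(f"| {key} | {s['n']} | {s['mean']:.1f} | {sd} "
                         f"| {s['min']:.1f} | {s['max']:.1f} |")
        lines.append("")
        lines.append("## Counts")
        lines.append("")
        for key, v in rep["counts"].items():
            lines.append(f"- {key}: {v}")
        lines.append("")
        lines.append("## Agreement with the published values")
        lines.append("")
        for key, entry in rep["published_comparison"].items():
            mark = "reproduced" if entry["reproduced"] else "NOT reproduced"
            lines.append(f"- {key}: computed {entry['computed']} vs published "
                         f"{entry['published']} -> {mark}")
        return "\n".join(lines) + "\n"


def _published_check(computed: Optional[float], published: float,
                     decimals: int) -> dict:
    entry = {"published": published, "computed": None, "reproduced": False}
    if computed is not None:
        rounded = round_half_up(computed, decimals)
        entry["computed"] = rounded
        entry["reproduced"] = bool(abs(rounded - published) < 10 ** (-decimals) / 2)
    return entry


def replicate_published_statistics(
    table: CohortTable,
    clinical_csv=None,
    clinical_schema: Optional[dict] = None,
) -> ReplicationReport:
    """Run every correlation, group comparison, summary and count of the
    cohort analysis and flag which published values they reproduce.

    Hemoglobin/hematocrit/creatinine/urea come from the supplementary
    clinical table; pass it as ``clinical_csv`` (CSV with a ``patient_id``
    column, optionally renamed through ``clinical_schema``). Without it the
    chemistry-dependent statistics are skipped with an explicit message.
    """
    skipped: list[str] = []
    if clinical_csv is not None:
        clinical = read_cohort_csv(clinical_csv, schema=clinical_schema)
        table = table.with_clinical(clinical)

    def available(field: str) -> bool:
        return bool(np.any(np.isfinite(table.column(field))))

    correlations: dict = {}
    for xa, xb in _CORRELATION_PLAN:
        if not (available(xa) and available(xb)):
            missing = xb if not available(xb) else xa
            skipped.append(
                f"correlation {xa} vs {xb} skipped: no values for {missing!r}"
                + ("" if clinical_csv else
                   " (supplementary clinical table not provided)"))
            continue
        c = pearson(table.column(xa), table.column(xb), variables=(xa, xb))
        correlations[f"{xa}__{xb}"] = {"r": c.r, "p": c.p_two_tailed,
                                       "n": c.n_pairs}

    groups: dict = {}
    for flag, variables in _GROUP_PLAN:
        sel = table.flag(flag)
        for var in variables:
            if not available(var):
                skipped.append(f"group comparison {var} by {flag} skipped: "
                               f"no values for {var!r}")
                continue
            col = table.column(var)
            g = mann_whitney_u(col[sel], col[~sel])
            groups[f"{flag}:{var}"] = {
                "u": g.u_statistic, "p": g.p_two_tailed,
                "group_sizes": list(g.group_sizes),
                "group_means": list(g.group_means),
                "method": g.method,
            }

    summaries: dict = {}
    for var in _SUMMARY_PLAN:
        if not available(var):
            skipped.append(f"summary of {var} skipped: no values")
            continue
        s = summarize(table.column(var))
        summaries[var] = {"n": s.n, "mean": s.mean, "sd": s.sd,
                          "min": s.min, "max": s.max}

    counts = {
        "complete_loss": count_by_predicate(table, "complete_loss"),
        "low_contrast": count_by_predicate(table, "low_contrast"),
        "etco2_above_35": count_by_predicate(table, "etco2_above", threshold=35),
        "mri_abnormal": count_by_predicate(table, "mri_abnormal"),
    }

    # agreement with the printed numbers, at their printed precision
    def corr_r(key):
        c = correlations.get(key)
        return None if c is None else c["r"]

    ttp = summaries.get("ttp_frames") or {}
    etco2 = summaries.get("etco2_mmHg") or {}
    swi_mri = groups.get("mri_abnormal:swi_score") or {}
    published = {
        "r_swi_ttp": _published_check(corr_r("swi_score__ttp_frames"),
                                      PUBLISHED_RESULTS["r_swi_ttp"], 2),
        "r_swi_hemoglobin": _published_check(
            corr_r("swi_score__hemoglobin_g_dl"),
            PUBLISHED_RESULTS["r_swi_hemoglobin"], 2),
        "r_swi_hematocrit": _published_check(
            corr_r("swi_score__hematocrit_pct"),
            PUBLISHED_RESULTS["r_swi_hematocrit"], 2),
        "ttp_mean": _published_check(ttp.get("mean"),
                                     PUBLISHED_RESULTS["ttp_mean"], 1),
        "ttp_sd": _published_check(ttp.get("sd"),
                                   PUBLISHED_RESULTS["ttp_sd"], 1),
        "ttp_min": _published_check(ttp.get("min"),
                                    PUBLISHED_RESULTS["ttp_min"], 1),
        "ttp_max": _published_check(ttp.get("max"),
                                    PUBLISHED_RESULTS["ttp_max"], 1),
        "etco2_mean": _published_check(etco2.get("mean"),
                                       PUBLISHED_RESULTS["etco2_mean"], 1),
        "n_complete_loss": _published_check(
            counts["complete_loss"], PUBLISHED_RESULTS["n_complete_loss"], 0),
        "n_low_contrast": _published_check(
            counts["low_contrast"], PUBLISHED_RESULTS["n_low_contrast"], 0),
        "n_etco2_above_35": _published_check(
            counts["etco2_above_35"], PUBLISHED_RESULTS["n_etco2_above_35"], 0),
        "p_swi_by_mri": _published_check(
            swi_mri.get("p"), PUBLISHED_RESULTS["p_swi_by_mri"], 2),
    }

    report = {
        "n_records": len(table),
        "correlations": correlations,
        "group_comparisons": groups,
        "summaries": summaries,
        "counts": counts,
        "skipped": skipped,
        "published_comparison": published,
    }
    return ReplicationReport(report)


# --------------------------------------------------------------------------
# calibration simulations
# --------------------------------------------------------------------------

def simulate_type_i_error(
    test: str = "pearson",
    n: int = 36,
    group_sizes: tuple[int, int] = (16, 20),
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null replicates rejected at ``alpha`` (type-I error rate).

    Draws independent standard-normal data (no association / no group
    difference) at the cohort's sample size and applies the package's own
    test implementation to every replicate.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        if test == "pearson":
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            p = pearson(x, y).p_two_tailed
        elif test == "mannwhitney":
            a = rng.standard_normal(group_sizes[0])
            b = rng.standard_normal(group_sizes[1])
            p = mann_whitney_u(a, b).p_two_tailed
        else:
            raise ValidationError(f"unknown test {test!r}")
        hits += p < alpha
    return hits / n_replicates
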