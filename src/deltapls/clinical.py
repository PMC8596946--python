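"""Symptom scoring and nonparametric clinical test battery.

Implements SCAT-style 22-item symptom scoring (total count, total severity
and four domain sums), Wilcoxon signed-rank and rank-sum tests reported as
tie-corrected normal z statistics, Benjamini-Hochberg FDR control, and a
Spearman-based attrition check relating session retention to demographics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# 22 symptom items partitioned into four domains (9 + 6 + 3 + 4).
SOMATIC_ITEMS = (
    "headache", "pressure in head", "neck pain", "nausea", "dizziness",
    "blurred vision", "balance problems", "sensitivity to light",
    "sensitivity to noise",
)
COGNITIVE_ITEMS = (
    "feeling slowed down", "feeling 'in a fog'", "don't feel right",
    "difficulty concentrating", "difficulty remembering", "confusion",
)
SLEEP_ITEMS = ("fatigue", "drowsiness", "trouble falling asleep")
MOOD_ITEMS = ("more emotional", "irritability", "sadness", "nervous/anxious")

SYMPTOM_ITEMS = SOMATIC_ITEMS + COGNITIVE_ITEMS + SLEEP_ITEMS + MOOD_ITEMS
assert len(SYMPTOM_ITEMS) == 22

DOMAINS = {
    "somatic": SOMATIC_ITEMS,
    "cognitive": COGNITIVE_ITEMS,
    "sleep": SLEEP_ITEMS,
    "mood": MOOD_ITEMS,
}


@dataclass
class SymptomRecord:
    """Scored symptom questionnaire for one subject/session."""

    subject_id: str
    session: str
    items: np.ndarray            # 22 ratings, 0-6
    total_symptoms: int          # count of nonzero items
    total_severity: int          # sum of ratings (0-132)
    domain_sums: dict[str, int]


def score_symptoms(
    items, subject_id: str = "", session: str = ""
) -> SymptomRecord:
    """Score a 22-item rating vector (seven-point Likert, 0-6 per item)."""
    items = np.asarray(items)
    if items.shape != (22,):
        raise ValueError(f"expected 22 item ratings, got shape {items.shape}")
    if not np.issubdtype(items.dtype, np.integer):
        as_int = items.astype(int)
        if not np.array_equal(as_int, items):
            raise ValueError("item ratings must be integers")
        items = as_int
    if items.min() < 0 or items.max() > 6:
        raise ValueError("item ratings must lie in 0-6")
    lookup = dict(zip(SYMPTOM_ITEMS, items))
    domain_sums = {
        name: int(sum(lookup[i] for i in members))
        for name, members in DOMAINS.items()
    }
    return SymptomRecord(
        subject_id=subject_id,
        session=session,
        items=items,
        total_symptoms=int(np.count_nonzero(items)),
        total_severity=int(items.sum()),
        domain_sums=domain_sums,
    )


def score_symptom_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score every row of an item table (columns: subject_id, session, items)."""
    rows = []
    for _, row in table.iterrows():
        rec = score_symptoms(
            row[list(SYMPTOM_ITEMS)].to_numpy(),
            subject_id=str(row["subject_id"]),
            session=str(row["session"]),
        )
        rows.append({
            "subject_id": rec.subject_id, "session": rec.session,
            "total_symptoms": rec.total_symptoms,
            "total_severity": rec.total_severity, **rec.domain_sums,
        })
    return pd.DataFrame(rows)


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-ranks plus the tie-correction term sum(t^3 - t)."""
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    return ranks, tie_term


_EXACT_N = 25   # exact null distribution used below this size (no ties)


def wilcoxon_paired(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired samples.

    Returns (z, p) where z is the tie-corrected normal statistic (positive
    when x > y).  Zero differences are dropped; ties among |differences|
    use mid-ranks with the standard variance correction.  For small untied
    samples the p-value comes from the exact signed-rank null distribution
    (equivalent to enumerating all sign assignments); otherwise from the
    normal approximation.  With all differences zero, z = 0 (p = 0.5
    one-sided).
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, _normal_p(0.0, alternative)
    ranks, tie_term = _rank_with_ties(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = 0.0 if var <= 0 else (w_plus - mean) / np.sqrt(var)
    if n <= _EXACT_N and tie_term == 0:
        res = stats.wilcoxon(d, alternative=alternative, method="exact")
        return z, float(res.pvalue)
    return z, _normal_p(z, alternative)


def wilcoxon_twosample(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (z, p): z is the tie-corrected normal rank-sum statistic
    (positive when x tends to exceed y); p is exact (enumeration of group
    assignments) for small untied samples and the normal approximation
    otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks, tie_term = _rank_with_ties(pooled)
    r1 = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if var <= 0 else (r1 - mean) / np.sqrt(var)
    if n <= _EXACT_N and tie_term == 0:
        res = stats.mannwhitneyu(x, y, alternative=alternative,
                                 method="exact")
        return z, float(res.pvalue)
    return z, _normal_p(z, alternative)


def _normal_p(z: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def fdr_adjust(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def attrition_check(
    retained: pd.DataFrame, variables: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Spearman screen for attrition bias.

    ``retained`` is a subjects x sessions boolean frame; ``variables`` a
    subjects x covariates frame (age, sex, HOC, symptom scores, days to
    RTP, ...) on the same index.  Each (session, variable) pair yields a
    Spearman rho of the retention indicator against the covariate, with a
    single Benjamini-Hochberg pass over all defined p-values.  Constant
    covariates give undefined rho (reported as NaN, never flagged).
    """
    if len(retained) < 10:
        raise ValueError("attrition check needs at least 10 subjects")
    variables = variables.loc[retained.index]
    rows = []
    for session in retained.columns:
        keep = retained[session].to_numpy().astype(float)
        for var in variables.columns:
            vals = variables[var].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() < 3 or np.unique(vals[ok]).size < 2 or np.unique(keep[ok]).size < 2:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(keep[ok], vals[ok])
            rows.append({"session": session, "variable": var,
                         "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["significant"] = False
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "significant"] = fdr_adjust(out.loc[defined, "p"], q=q)
    return out


def clinical_report(
    scores: pd.DataFrame, subjects: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """The study's clinical battery on a scored symptom table.

    Within each sex: paired Wilcoxon of ACU (and RTP) vs baseline for the
    symptom totals (one-sided, elevation).  Between sexes at each session:
    two-sample Wilcoxon for totals and the four domain sums, plus age and
    days to RTP.  All p-values enter a single BH-FDR pass at level ``q``.

    ``subjects`` must carry subject_id, sex and group columns.
    """
    merged = scores.merge(
        subjects[["subject_id", "sex", "group"]], on="subject_id"
    )
    conc = merged[merged["group"] == "concussed"]
    rows = []

    for sex, label in ((0, "male"), (1, "female")):
        sub = conc[conc["sex"] == sex]
        base = sub[sub["session"] == "baseline"].set_index("subject_id")
        for sess in ("ACU", "RTP"):
            post = sub[sub["session"] == sess].set_index("subject_id")
            common = base.index.intersection(post.index)
            if len(common) < 5:
                continue
            for measure in ("total_symptoms", "total_severity"):
                z, p = wilcoxon_paired(
                    post.loc[common, measure], base.loc[common, measure],
                    alternative="greater",
                )
                rows.append({"comparison": f"{label} {sess} vs baseline",
                             "measure": measure, "z": z, "p": p})

    domain_cols = list(DOMAINS)
    for sess in ("baseline", "ACU", "RTP"):
        males = conc[(conc["sex"] == 0) & (conc["session"] == sess)]
        females = conc[(conc["sex"] == 1) & (conc["session"] == sess)]
        if len(males) < 3 or len(females) < 3:
            continue
        measures = ["total_symptoms", "total_severity"]
        if sess == "ACU":
            measures += domain_cols
        for measure in measures:
            z, p = wilcoxon_twosample(
                females[measure], males[measure], alternative="two-sided"
            )
            rows.append({"comparison": f"female vs male at {sess}",
                         "measure": measure, "z": z, "p": p})

    report = pd.DataFrame(rows)
    if len(report):
        report["significant"] = fdr_adjust(report["p"], q=q)
    return report
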