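"""Group-level statistics: prevalence tests, metric comparisons, clinical correlations.

The group layer compares the two subject groups on (i) the prevalence of the
directed PFC->TL network pattern (Fisher's exact test on the 2x2 table), and
(ii) each graph metric (pooled-variance two-sample Student t-test), with two
multiple-comparison treatments reported side by side: Bonferroni thresholds
for the 5-band (alpha/5 = 0.01) and 5-band x 4-metric (alpha/20 = 0.0025)
families, and Benjamini-Hochberg FDR rejection flags.  Clinical covariates
are related to the graph metrics within the patient group by Spearman rank
correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortResult",
    "fisher_exact_2x2",
    "ttest_two_sample",
    "bonferroni",
    "fdr_bh",
    "spearman",
    "run_group_analysis",
]


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Exact probability-summation convention: with margins fixed, sum the
    hypergeometric probabilities of every table at most as probable as the
    observed one.  A zero margin makes every table equally (un)informative;
    p = 1 with a warning.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table_f = np.asarray(table, dtype=float)
        if np.any(table_f < 0) or np.any(table_f != np.round(table_f)):
            raise ValueError("table entries must be non-negative integers")
        table = table_f.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def ttest_two_sample(
    x: np.ndarray, y: np.ndarray, two_tailed: bool = True
) -> dict[str, float]:
    """Pooled-variance (Student) two-sample t-test.

    Returns {t, p, df} with df = n_x + n_y - 2.  One-tailed halves the p for
    the observed direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2
    if not two_tailed:
        p = p / 2.0
    return {"t": float(t), "p": float(p), "df": float(df)}


def bonferroni(alpha: float, n_tests: int) -> float:
    """Per-test Bonferroni threshold alpha / n.

    The two families used in the analysis are the five frequency bands
    (0.05/5 = 0.01) and five bands x four graph metrics (0.05/20 = 0.0025).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags.

    Sort p ascending and reject every p(i) with i at most the largest rank
    satisfying p(i) <= q * i / N.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n only)."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rhos = []
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        rhos.append(r)
    rhos = np.asarray(rhos)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray, exact: bool = False) -> dict[str, float]:
    """Spearman rank correlation with midrank tie handling.

    The p-value uses the t approximation with n - 2 degrees of freedom;
    ``exact=True`` computes the full permutation null instead (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if x.size > 10:
            raise ValueError("exact permutation p supported only for n <= 10")
        p = _spearman_exact_p(x, y, rho)
    return {"rho": float(rho), "p": float(p)}


@dataclass
class CohortResult:
    """Full group-level report for one cohort analysis."""

    prevalence_table: np.ndarray  # rows: patient/control; cols: present/absent
    fisher_p: float
    metric_tests: pd.DataFrame  # band, metric, condition, t, p_raw, thresholds, flags
    clinical_correlations: pd.DataFrame  # covariate, metric, band, condition, rho, p
    provenance: dict = field(default_factory=dict)


METRICS = ("D", "S", "L", "C")


def run_group_analysis(
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    clinical_covariates: tuple[str, ...] = (
        "history_years",
        "freq_per_month",
        "duration_hours",
        "ham_a",
        "ham_d",
    ),
    provenance: dict | None = None,
) -> CohortResult:
    """Group comparison and clinical-correlation layer over a subject table.

    ``subjects`` needs one row per subject / band / condition with columns
    ``subject_id, group, band, condition, pattern_detected, D, S, L, C`` plus
    any clinical covariate columns.  Per (condition, band): Fisher's exact
    test on pattern prevalence and a Student t-test per metric.  Bonferroni
    thresholds for the band family (alpha/5) and the band x metric family
    (alpha/20) are attached to every metric test, along with BH-FDR rejection
    flags computed over the full metric-test family.  Spearman correlations
    relate clinical covariates to metrics within the patient group.
    """
    required = {"subject_id", "group", "band", "condition", "pattern_detected"}
    missing = required - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table missing columns {sorted(missing)}")

    thr_bands = bonferroni(alpha, 5)
    thr_bands_metrics = bonferroni(alpha, 20)

    # ---- pattern prevalence (pooled over bands/conditions tables are also
    # reported per condition+band; the headline table is the first one)
    fisher_rows = []
    metric_rows = []
    corr_rows = []
    for (condition, band), sub in subjects.groupby(["condition", "band"], sort=True):
        pat = sub[sub.group == "patient"]
        ctl = sub[sub.group == "control"]
        table = np.array(
            [
                [int(pat.pattern_detected.sum()), int((~pat.pattern_detected.astype(bool)).sum())],
                [int(ctl.pattern_detected.sum()), int((~ctl.pattern_detected.astype(bool)).sum())],
            ]
        )
        fisher_rows.append(
            {
                "condition": condition,
                "band": band,
                "n_patients_present": table[0, 0],
                "n_controls_present": table[1, 0],
                "fisher_p": fisher_exact_2x2(table),
                "table": table,
            }
        )
        for metric in METRICS:
            x = pat[metric].to_numpy(dtype=float)
            y = ctl[metric].to_numpy(dtype=float)
            ok = np.isfinite(x), np.isfinite(y)
            x, y = x[ok[0]], y[ok[1]]
            if x.size < 2 or y.size < 2:
                continue
            res = ttest_two_sample(x, y)
            metric_rows.append(
                {
                    "condition": condition,
                    "band": band,
                    "metric": metric,
                    "t": res["t"],
                    "df": res["df"],
                    "p_raw": res["p"],
                    "bonferroni_5": res["p"] < thr_bands,
                    "bonferroni_20": res["p"] < thr_bands_metrics,
                }
            )
        for cov in clinical_covariates:
            if cov not in sub.columns:
                continue
            for metric in METRICS:
                x = pat[cov].to_numpy(dtype=float)
                y = pat[metric].to_numpy(dtype=float)
                keep = np.isfinite(x) & np.isfinite(y)
                if keep.sum() < 4:
                    continue
                res = spearman(x[keep], y[keep])
                corr_rows.append(
                    {
                        "condition": condition,
                        "band": band,
                        "covariate": cov,
                        "metric": metric,
                        "n": int(keep.sum()),
                        "rho": res["rho"],
                        "p": res["p"],
                    }
                )

    metric_tests = pd.DataFrame(metric_rows)
    if len(metric_tests):
        metric_tests["fdr_reject"] = fdr_bh(
            metric_tests.p_raw.to_numpy(), q=alpha
        )
    clinical = pd.DataFrame(corr_rows)
    head = fisher_rows[0] if fisher_rows else {"table": np.zeros((2, 2), int), "fisher_p": 1.0}
    prov = dict(provenance or {})
    prov.update(
        {
            "alpha": alpha,
            "bonferroni_threshold_bands": thr_bands,
            "bonferroni_threshold_bands_x_metrics": thr_bands_metrics,
            "fisher_tables": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in row.items()}
                for row in fisher_rows
            ],
        }
    )
    return CohortResult(
        prevalence_table=head["table"],
        fisher_p=head["fisher_p"],
        metric_tests=metric_tests,
        clinical_correlations=clinical,
        provenance=prov,
    )
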