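"""Phenome-wide association scans of phenogroup membership.

Two approaches mirror the analysis design: a disease scan (logistic
regression of each binary incident-disease column on the 0/1 phenogroup
variable, effect reported as an odds ratio) and a biobank scan (univariate
correlation between the 0/1 phenogroup variable and each numeric phenotype,
point-biserial for continuous columns).  Family-wise error is controlled by
Bonferroni over the testable comparisons of a scan; phenogroup C subjects
must be excluded upstream before encoding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["encode_group", "disease_phewas", "biobank_phewas",
           "bonferroni", "manhattan_table"]


def encode_group(assignment) -> np.ndarray:
    """Encode phenogroup labels as 0 (A) and 1 (B).

    Any other label — in particular C — is rejected: callers must filter to
    the A/B subset first.
    """
    labels = np.asarray(assignment)
    if np.any(labels == "C"):
        raise ValueError("phenogroup C present: filter to A/B subjects "
                         "before encoding")
    bad = set(np.unique(labels)) - {"A", "B"}
    if bad:
        raise ValueError(f"unknown phenogroup labels: {sorted(bad)}")
    return (labels == "B").astype(int)


def _finish(rows: list[dict], alpha: float) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return bonferroni(df, alpha)


def disease_phewas(group01, disease_table: pd.DataFrame,
                   alpha: float = 0.05,
                   covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Logistic-regression scan over binary incident-disease columns.

    The effect is OR = exp(slope of the 0/1 phenogroup variable); on a
    single binary predictor this equals the closed-form 2x2 odds ratio.
    Diseases with zero cases or zero controls (or a failed fit) are marked
    untestable and excluded from the Bonferroni denominator.
    """
    g = np.asarray(group01, dtype=float)
    cols = [c for c in disease_table.columns if c != "subject_id"]
    design_extra = None
    if covariates is not None:
        design_extra = covariates.to_numpy(dtype=float)
    rows = []
    for c in cols:
        y = disease_table[c].to_numpy(dtype=float)
        row = {"phenotype": c, "approach": "disease", "effect": np.nan,
               "se": np.nan, "p": np.nan, "n": int(np.isfinite(y).sum()),
               "testable": False}
        if len(np.unique(y[np.isfinite(y)])) == 2:
            X = g[:, None] if design_extra is None else np.column_stack([g, design_extra])
            try:
                fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
                row.update(effect=float(np.exp(fit.params[1])),
                           se=float(fit.bse[1]),
                           p=float(fit.pvalues[1]), testable=True)
            except Exception:
                pass  # leaves the row untestable
        rows.append(row)
    return _finish(rows, alpha)


def biobank_phewas(group01, phenotype_table: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Univariate-correlation scan over numeric phenotype columns.

    Pearson correlation between the 0/1 phenogroup variable and each
    phenotype (point-biserial when the phenotype is continuous), two-sided
    p, computed on pairwise-complete observations.  Constant phenotypes are
    untestable.
    """
    g = np.asarray(group01, dtype=float)
    rows = []
    for c in [c for c in phenotype_table.columns if c != "subject_id"]:
        y = phenotype_table[c].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(g)
        row = {"phenotype": c, "approach": "biobank", "effect": np.nan,
               "se": np.nan, "p": np.nan, "n": int(ok.sum()),
               "testable": False}
        if ok.sum() >= 3 and np.std(y[ok]) > 0 and np.std(g[ok]) > 0:
            r, p = stats.pearsonr(g[ok], y[ok])
            row.update(effect=float(r), p=float(p), testable=True,
                       se=float(np.sqrt((1 - r ** 2) / max(ok.sum() - 2, 1))))
        rows.append(row)
    return _finish(rows, alpha)


def bonferroni(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag results at the alpha/m threshold, m = testable comparisons.

    Stores ``m`` and ``threshold`` in ``DataFrame.attrs`` and a boolean
    ``significant`` column (always False for untestable rows).
    """
    df = results.copy()
    m = int(df["testable"].sum())
    if m < 1:
        raise ValueError("no testable comparisons in the scan")
    threshold = alpha / m
    df["significant"] = df["testable"] & (df["p"] < threshold)
    df.attrs["m"] = m
    df.attrs["threshold"] = threshold
    df.attrs["alpha"] = alpha
    return df


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: -log10 p, effect sign, sorted by approach then p.

    Untestable comparisons are dropped; the Bonferroni line is carried in
    ``attrs["neglog10_threshold"]``.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    df = results[results["testable"]].copy()
    df["neglog10_p"] = -np.log10(df["p"])
    df["effect_sign"] = np.sign(
        np.where(df["approach"] == "disease", np.log(df["effect"]),
                 df["effect"]))
    df = df.sort_values(["approach", "p"]).reset_index(drop=True)
    if "threshold" in results.attrs:
        df.attrs["neglog10_threshold"] = -np.log10(results.attrs["threshold"])
    return df
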