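"""Per-molecule linear-model associations, BH correction, signed
significance scores and signature extraction.

For a binary 0/1 outcome the OLS slope on log2 abundances equals the log2
fold change between the groups, and the slope t-test is numerically the
pooled-variance two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .matrix import OmicsMatrix, check_samples_match

log = logging.getLogger(__name__)

#: outcomes and their types; "group" is the diagnosis contrast
BINARY_OUTCOMES = {"group", "aki", "mortality"}
CONTINUOUS_OUTCOMES = {"platelet_count", "pao2_fio2"}
CLINICAL_OUTCOMES = ("aki", "platelet_count", "pao2_fio2", "mortality")

#: 0/1 coding of binary outcomes: positive estimates mean higher in the
#: second level (covid / non-survivor / AKI-positive)
GROUP_CODING = {"bacterial": 0.0, "covid": 1.0}


@dataclass
class AssociationResult:
    """Statistics of one molecule against one outcome."""

    molecule_id: str
    omics_label: str
    outcome_name: str
    estimate: float
    t_statistic: float
    p: float
    p_adj: float
    d: int
    p_score: float
    n_used: int


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise AnalysisError("bh_adjust expects a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise AnalysisError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def compute_p_score(p_adj: float, d: int) -> float:
    """Signed significance score: -log10(adjusted p) times the direction."""
    if not 0 < p_adj <= 1:
        raise AnalysisError("p_adj must lie in (0, 1]; floor zero values upstream")
    if d not in (-1, 1):
        raise AnalysisError("direction must be -1 or +1")
    return float(-np.log10(p_adj) * d)


def _encode_outcome(samples: pd.DataFrame, outcome_name: str) -> pd.Series:
    if outcome_name == "group":
        y = samples["group"].map(GROUP_CODING)
    elif outcome_name in samples.columns:
        y = samples[outcome_name].astype(float)
    else:
        raise AnalysisError(f"outcome {outcome_name!r} not in sample table")
    return y


def fit_association(
    m: OmicsMatrix,
    samples: pd.DataFrame,
    outcome_name: str,
    subset_group: str | None = None,
) -> list[AssociationResult]:
    """OLS of each molecule's abundance on one outcome, with BH correction.

    Samples with a missing outcome are dropped; with ``subset_group`` the
    fit is restricted to that diagnosis group. Two-sided p-values come from
    the t distribution with ``n_used - 2`` degrees of freedom; BH runs
    jointly across every molecule tested here. A constant molecule gets
    estimate 0 and p = 1 (flagged via a log message, not an error).
    """
    m.require_state("imputed")
    check_samples_match(m, samples)
    meta = samples.loc[m.sample_ids]
    if subset_group is not None:
        meta = meta[meta["group"] == subset_group]
    y = _encode_outcome(meta, outcome_name).dropna()
    n = len(y)
    if n < 3:
        raise AnalysisError(f"only {n} usable samples for outcome {outcome_name!r}")
    if y.nunique() < 2:
        raise AnalysisError(f"outcome {outcome_name!r} is constant in this cohort")

    X = m.data[y.index].to_numpy()  # p x n
    if np.isnan(X).any():
        raise AnalysisError("imputed matrix still contains missing values")
    x = y.to_numpy(dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = X - X.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    syy = np.einsum("ij,ij->i", yc, yc)
    beta = sxy / sxx
    dof = n - 2
    resid = np.maximum(syy - beta**2 * sxx, 0.0)
    sigma2 = resid / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    constant = syy <= 1e-300
    if constant.any():
        log.warning(
            "%d constant molecules set to p=1 for outcome %s",
            int(constant.sum()),
            outcome_name,
        )
    t = np.where(constant, 0.0, t)
    beta = np.where(constant, 0.0, beta)
    # a perfect fit (resid == 0, non-constant molecule) gives |t| = inf, p -> 0
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[constant] = 1.0
    p_adj = bh_adjust(p)
    d = np.where(t < 0, -1, 1)

    results = []
    for i, mol in enumerate(m.feature_ids):
        results.append(
            AssociationResult(
                molecule_id=str(mol),
                omics_label=str(m.omics[mol]),
                outcome_name=outcome_name,
                estimate=float(beta[i]),
                t_statistic=float(t[i]),
                p=float(p[i]),
                p_adj=float(p_adj[i]),
                d=int(d[i]),
                p_score=compute_p_score(float(p_adj[i]), int(d[i])),
                n_used=n,
            )
        )
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def significant(results: list[AssociationResult], fdr: float = 0.05) -> list[AssociationResult]:
    """Molecules passing the FDR cut (strict inequality)."""
    return [r for r in results if r.p_adj < fdr]


def extract_signature(
    results: list[AssociationResult],
    fdr: float = 0.05,
    lfc_threshold: float = 2.0,
) -> list[AssociationResult]:
    """Significant molecules with |log2 fold change| >= threshold,
    sorted by effect magnitude (descending)."""
    if lfc_threshold < 0:
        raise AnalysisError("lfc_threshold must be >= 0")
    hits = [r for r in results if r.p_adj < fdr and abs(r.estimate) >= lfc_threshold]
    return sorted(hits, key=lambda r: (-abs(r.estimate), r.molecule_id))


@dataclass
class ClinicalPanel:
    """Per-(group, outcome) association results and hit counts."""

    results: dict[tuple[str, str], list[AssociationResult]] = field(default_factory=dict)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def hit_counts(self, fdr: float = 0.05) -> pd.DataFrame:
        rows = []
        for (group, outcome), res in sorted(self.results.items()):
            hits = significant(res, fdr)
            rows.append(
                {
                    "group": group,
                    "outcome": outcome,
                    "n_tested": len(res),
                    "n_significant": len(hits),
                    "n_metabolites": sum(r.omics_label == "metabolite" for r in hits),
                    "n_proteins": sum(r.omics_label == "protein" for r in hits),
                }
            )
        return pd.DataFrame(rows)


def run_clinical_panel(m: OmicsMatrix, samples: pd.DataFrame) -> ClinicalPanel:
    """Associate every molecule with each clinical outcome, per group.

    Four outcomes x two diagnosis groups = eight analyses, each with its
    own BH correction. Analyses with fewer than 3 usable samples or a
    constant outcome are skipped with a logged warning.
    """
    panel = ClinicalPanel()
    for group in ("covid", "bacterial"):
        for outcome in CLINICAL_OUTCOMES:
            try:
                panel.results[(group, outcome)] = fit_association(
                    m, samples, outcome, subset_group=group
                )
            except AnalysisError as exc:
                log.warning("skipping %s/%s: %s", group, outcome, exc)
                panel.skipped.append((group, outcome, str(exc)))
    return panel
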