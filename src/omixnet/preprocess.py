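"""Preprocessing chain: missingness filter -> PQN -> log2 -> kNN imputation
-> duplicate-assay averaging.

Each operation checks the matrix ``scale_state`` so the chain can only be
run in this order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError
from .matrix import OmicsMatrix

log = logging.getLogger(__name__)

#: proteins measured in duplicate on overlapping assay panels
DEFAULT_DUPLICATE_PROTEINS = (
    "CCL3",
    "CXCL1",
    "FGF-21",
    "FGF-23",
    "IL-18",
    "IL-6",
    "MCP-1",
    "OPG",
    "SCF",
    "uPA",
)


def filter_missingness(
    m: OmicsMatrix, max_missing_frac: float = 0.25
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Drop features whose missing fraction strictly exceeds the threshold.

    A feature missing in exactly ``max_missing_frac`` of the samples is
    kept. Returns the filtered matrix (still raw) and a removal report with
    columns ``feature_id`` and ``missing_frac``.
    """
    m.require_state("raw")
    frac = m.missing_fraction()
    keep = frac <= max_missing_frac
    if not keep.any():
        raise AnalysisError("missingness filter removed every feature")
    removed = frac[~keep]
    report = pd.DataFrame(
        {"feature_id": removed.index, "missing_frac": removed.to_numpy()}
    ).reset_index(drop=True)
    return m.with_data(m.data.loc[keep]), report


def pqn_normalize(
    m: OmicsMatrix, max_iter: int = 1000, tol: float = 1e-12
) -> tuple[OmicsMatrix, pd.Series]:
    """Probabilistic quotient normalization against the median spectrum.

    Reference = per-feature median across samples (missing values ignored);
    each sample is divided by the median of its feature-wise quotients
    against the reference. The reference/divide step is iterated to its
    fixed point, so the returned matrix has median quotient exactly 1 for
    every sample and the operation is idempotent. The returned Series holds
    each sample's cumulative scaling factor (its dilution estimate).
    """
    m.require_state("raw")
    vals = m.data.to_numpy(copy=True)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise AnalysisError("PQN requires strictly positive abundances")
    shared = (~np.isnan(vals)).sum(axis=0)
    if np.any(shared < 2):
        bad = m.sample_ids[shared < 2].tolist()
        raise AnalysisError(f"samples with < 2 usable features for PQN: {bad}")

    total = np.ones(m.n_samples)
    with np.errstate(invalid="ignore"):
        for _ in range(max_iter):
            reference = np.nanmedian(vals, axis=1)
            quotients = vals / reference[:, None]
            medians = np.nanmedian(quotients, axis=0)
            vals /= medians
            total *= medians
            if np.max(np.abs(medians - 1.0)) < tol:
                break
        else:  # pragma: no cover - iteration is a fast contraction in practice
            log.warning("PQN did not reach its fixed point in %d iterations", max_iter)

    normalized = pd.DataFrame(vals, index=m.feature_ids, columns=m.sample_ids)
    factors = pd.Series(total, index=m.sample_ids, name="quotient_median")
    return m.with_data(normalized, scale_state="normalized"), factors


def log2_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log2; missing entries stay missing."""
    m.require_state("normalized")
    vals = m.data.to_numpy()
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise AnalysisError("log2 transform requires strictly positive values")
    return m.with_data(np.log2(m.data), scale_state="log2")


def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing entries from the k nearest features.

    Distance between two features = Euclidean distance of their profiles
    over the samples observed in both, divided by sqrt(#shared samples)
    (i.e. root mean squared difference), so features with few shared
    samples are not artificially close. A missing entry (f, s) becomes the
    mean of the values at sample s of the k nearest features observed at s;
    when fewer than k eligible neighbors exist, all of them are used.
    Observed entries are untouched.
    """
    m.require_state("log2")
    if k < 1:
        raise ConfigError("k must be >= 1")
    vals = m.data.to_numpy(copy=True)
    observed = ~np.isnan(vals)
    if not observed.any(axis=1).all():
        bad = m.feature_ids[~observed.any(axis=1)].tolist()
        raise AnalysisError(f"features with no observed values: {bad}")
    if observed.all():
        return m.with_data(m.data.copy(), scale_state="imputed")

    filled = np.where(observed, vals, 0.0)
    obs = observed.astype(float)
    # pairwise scaled distances: d2[i,j] = sum over shared samples of
    # (x_i - x_j)^2, normalized by the shared-sample count
    sq = filled**2
    cross = filled @ filled.T
    sums = (sq @ obs.T) + (obs @ sq.T)
    shared = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (sums - 2.0 * cross) / shared
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)

    out = vals.copy()
    missing_rows = np.where(~observed.all(axis=1))[0]
    for i in missing_rows:
        for s in np.where(~observed[i])[0]:
            eligible = np.where(observed[:, s] & np.isfinite(d2[i]))[0]
            if eligible.size == 0:
                raise AnalysisError(
                    f"no eligible neighbor for feature {m.feature_ids[i]!r} "
                    f"at sample {m.sample_ids[s]!r}"
                )
            order = eligible[np.argsort(d2[i, eligible], kind="stable")]
            neighbors = order[: min(k, order.size)]
            out[i, s] = vals[neighbors, s].mean()

    imputed = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return m.with_data(imputed, scale_state="imputed")


def average_duplicates(
    m: OmicsMatrix, duplicate_groups: dict[str, str] | None = None
) -> OmicsMatrix:
    """Collapse duplicated assays to their canonical feature.

    ``duplicate_groups`` maps duplicate assay ids to canonical feature ids;
    each canonical feature is replaced by the arithmetic mean (in the
    current scale) over itself and its duplicates, and the duplicate rows
    are dropped. With no mapping given, ids matching the default
    twice-measured protein panel names are collapsed.
    """
    if duplicate_groups is None:
        duplicate_groups = _default_duplicate_map(m)
    if not duplicate_groups:
        return m.copy()
    unknown = [f for f in duplicate_groups if f not in m.feature_ids] + [
        c for c in duplicate_groups.values() if c not in m.feature_ids
    ]
    if unknown:
        raise AnalysisError(f"duplicate map references unknown features: {sorted(set(unknown))}")

    groups: dict[str, list[str]] = {}
    for dup, canonical in duplicate_groups.items():
        groups.setdefault(canonical, []).append(dup)

    data = m.data.copy()
    drop: list[str] = []
    for canonical, dups in groups.items():
        members = [canonical] + [d for d in dups if d != canonical]
        data.loc[canonical] = m.data.loc[members].mean(axis=0)
        drop.extend(d for d in members if d != canonical)
    data = data.drop(index=drop)
    return m.with_data(data)


def _default_duplicate_map(m: OmicsMatrix) -> dict[str, str]:
    """Collapse ids like 'IL-6.1' / 'IL-6_2' onto a default-panel protein."""
    mapping: dict[str, str] = {}
    ids = set(map(str, m.feature_ids))
    for name in DEFAULT_DUPLICATE_PROTEINS:
        copies = [f for f in ids if f == name or f.rstrip("0123456789").rstrip("._") == name]
        if name in copies and len(copies) > 1:
            for c in copies:
                if c != name:
                    mapping[c] = name
    return mapping


def run_chain(
    m: OmicsMatrix,
    max_missing_frac: float = 0.25,
    knn_k: int = 10,
    duplicate_groups: dict[str, str] | None = None,
) -> tuple[OmicsMatrix, dict]:
    """Run the full chain in order and collect a QC report."""
    filtered, removed = filter_missingness(m, max_missing_frac)
    normalized, factors = pqn_normalize(filtered)
    logged = log2_transform(normalized)
    imputed = knn_impute(logged, k=knn_k)
    if duplicate_groups:
        present = {
            d: c
            for d, c in duplicate_groups.items()
            if d in imputed.feature_ids and c in imputed.feature_ids
        }
    else:
        present = None
    final = average_duplicates(imputed, present)
    qc = {
        "n_features_in": m.n_features,
        "n_features_removed": len(removed),
        "removed": removed,
        "quotient_medians": factors,
        "n_features_out": final.n_features,
    }
    return final, qc
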