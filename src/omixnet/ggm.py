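"""Shrinkage Gaussian graphical model inference.

Pipeline: standardize features, estimate the sample correlation matrix,
shrink it toward the identity with the analytic intensity

    lambda* = sum_{i<j} Var-hat(r_ij) / sum_{i<j} r_ij^2   (clipped to [0,1]),

invert to partial correlations, and test each pair against the null
density f0(r; kappa) proportional to (1 - r^2)^((kappa-3)/2), with the
effective degrees-of-freedom parameter kappa fitted by maximum likelihood
of a two-component mixture (null f0 + uniform alternative) on the observed
partial correlations. Edges = pairs significant at the requested FDR,
either via BH on the null p-values ("bh") or via empirical tail-area FDR
("efdr").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, special

from .errors import AnalysisError
from .matrix import OmicsMatrix

log = logging.getLogger(__name__)

_KAPPA_BRACKET = (3.0, 1e6)


@dataclass
class ShrinkageEstimate:
    """Shrunk correlation matrix and derived quantities."""

    feature_ids: list[str]
    correlation: np.ndarray  # shrunk correlation R*
    lambda_star: float
    n_samples: int
    partial_cor: np.ndarray | None = None
    kappa: float | None = None


def shrinkage_correlation(m: OmicsMatrix) -> ShrinkageEstimate:
    """Estimate the identity-target shrinkage correlation matrix.

    Requires a fully imputed matrix with at least 3 samples. Features are
    the variables (samples are observations). Raises on zero-variance
    features, naming them.
    """
    m.require_state("imputed")
    X = m.data.to_numpy().T  # n x p
    n, p = X.shape
    if n < 3:
        raise AnalysisError(f"need >= 3 samples, got {n}")
    if np.isnan(X).any():
        raise AnalysisError("matrix contains missing values; impute first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = m.feature_ids[sd == 0].tolist()
        raise AnalysisError(f"zero-variance features: {bad[:5]}")
    Z = (X - X.mean(axis=0)) / sd  # unbiased-sd standardization

    r = (Z.T @ Z) / (n - 1)
    np.fill_diagonal(r, 1.0)

    # Var-hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - w-bar_ij)^2 with
    # w_kij = z_ki * z_kj; computed via matrix products to stay O(p^2 n).
    Z2 = Z**2
    sum_w = Z.T @ Z  # sum_k w_kij = (n-1) r_ij
    sum_w2 = Z2.T @ Z2
    var_r = n / (n - 1.0) ** 3 * (sum_w2 - sum_w**2 / n)

    iu = np.triu_indices(p, k=1)
    denom = float(np.sum(r[iu] ** 2))
    numer = float(np.sum(var_r[iu]))
    lam = 1.0 if denom == 0 else float(np.clip(numer / denom, 0.0, 1.0))

    shrunk = (1.0 - lam) * r
    np.fill_diagonal(shrunk, 1.0)
    return ShrinkageEstimate(
        feature_ids=[str(f) for f in m.feature_ids],
        correlation=shrunk,
        lambda_star=lam,
        n_samples=n,
    )


def partial_correlations(est: ShrinkageEstimate) -> ShrinkageEstimate:
    """Fill ``partial_cor`` by inverting the shrunk correlation matrix."""
    R = est.correlation
    try:
        omega = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError(
            "shrunk correlation matrix is singular; use nonzero shrinkage "
            "(lambda_star == 0 with p >= n cannot be inverted)"
        ) from exc
    if est.lambda_star == 0.0:
        evals = np.linalg.eigvalsh((R + R.T) / 2)
        if evals[0] <= 1e-12:
            raise AnalysisError(
                "correlation matrix is not positive definite; "
                "use nonzero shrinkage"
            )
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2
    np.fill_diagonal(pcor, 1.0)
    est.partial_cor = pcor
    return est


# -- null model for partial correlations ---------------------------------


def _null_logpdf(r: np.ndarray, kappa: float) -> np.ndarray:
    """log f0(r; kappa) with f0(r) = (1-r^2)^((kappa-3)/2) / B(1/2,(kappa-1)/2)."""
    with np.errstate(divide="ignore"):
        core = (kappa - 3.0) / 2.0 * np.log1p(-np.minimum(r**2, 1.0 - 1e-15))
    return core - special.betaln(0.5, (kappa - 1.0) / 2.0)


def null_tail_probability(r: np.ndarray, kappa: float) -> np.ndarray:
    """Two-sided tail P(|R| >= |r|) under f0; equals 1 - I_{r^2}(1/2, (kappa-1)/2)."""
    r2 = np.clip(np.asarray(r, float) ** 2, 0.0, 1.0)
    return 1.0 - special.betainc(0.5, (kappa - 1.0) / 2.0, r2)


def fit_kappa(pcors: np.ndarray) -> tuple[float, float]:
    """Fit (kappa, eta0) of the mixture eta0*f0(r;kappa) + (1-eta0)/2.

    kappa is optimized on a log scale within [3, 1e6]; for each candidate
    kappa the null weight eta0 is profiled out by a bounded scalar search.
    Returns (kappa, eta0). Deterministic.
    """
    r = np.asarray(pcors, float)
    r = r[np.isfinite(r)]
    if r.size < 10:
        raise AnalysisError("too few partial correlations to fit the null")

    def profiled_nll(log10_kappa: float) -> float:
        kappa = 10.0**log10_kappa
        f0 = np.exp(_null_logpdf(r, kappa))

        def nll(eta0: float) -> float:
            dens = eta0 * f0 + (1.0 - eta0) * 0.5
            return -float(np.sum(np.log(np.maximum(dens, 1e-300))))

        inner = optimize.minimize_scalar(
            nll, bounds=(1e-6, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        return inner.fun

    res = optimize.minimize_scalar(
        profiled_nll,
        bounds=(np.log10(_KAPPA_BRACKET[0]), np.log10(_KAPPA_BRACKET[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:  # pragma: no cover
        raise AnalysisError(f"kappa fit failed to converge: {res.message}")
    kappa = float(10.0**res.x)
    f0 = np.exp(_null_logpdf(r, kappa))
    inner = optimize.minimize_scalar(
        lambda e: -float(
            np.sum(np.log(np.maximum(e * f0 + (1 - e) * 0.5, 1e-300)))
        ),
        bounds=(1e-6, 1.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return kappa, float(inner.x)


def _empirical_tail_fdr(pcors: np.ndarray, kappa: float, eta0: float) -> np.ndarray:
    """Tail-area FDR: eta0 * P0(|R| >= |r|) / empirical P(|R| >= |r|)."""
    a = np.abs(pcors)
    order = np.argsort(-a, kind="mergesort")
    m = a.size
    emp_tail = np.arange(1, m + 1) / m  # fraction with |pcor| >= current
    null_tail = null_tail_probability(a[order], kappa)
    fdr_sorted = np.minimum(eta0 * null_tail / emp_tail, 1.0)
    # enforce monotonicity in |r| (smaller |r| cannot have smaller FDR)
    fdr_sorted = np.maximum.accumulate(fdr_sorted)
    out = np.empty(m)
    out[order] = fdr_sorted
    return out


def edge_significance(
    est: ShrinkageEstimate, fdr: float = 0.05, method: str = "bh"
) -> nx.Graph:
    """Select significant edges and return the network.

    ``method="bh"``: BH on the two-sided null p-values; ``method="efdr"``:
    empirical tail-area FDR with the fitted null weight eta0. Nodes carry
    no annotations yet (see :func:`annotate_network`); edges carry
    ``pcor``, ``p`` and ``p_adj``.
    """
    from .differential import bh_adjust

    if est.partial_cor is None:
        raise AnalysisError("call partial_correlations first")
    if method not in ("bh", "efdr"):
        raise AnalysisError(f"unknown edge FDR method {method!r}")
    p_feat = len(est.feature_ids)
    iu = np.triu_indices(p_feat, k=1)
    if iu[0].size < 10:
        raise AnalysisError("need at least 10 feature pairs")
    pcors = est.partial_cor[iu]

    if np.allclose(pcors, 0.0):
        kappa, eta0 = float(_KAPPA_BRACKET[1]), 1.0
        pvals = np.ones_like(pcors)
        est.kappa = kappa
        padj = np.ones_like(pcors)
    else:
        kappa, eta0 = fit_kappa(pcors)
        est.kappa = kappa
        pvals = np.clip(null_tail_probability(pcors, kappa), np.finfo(float).tiny, 1.0)
        if method == "bh":
            padj = bh_adjust(pvals)
        else:
            padj = _empirical_tail_fdr(pcors, kappa, eta0)

    g = nx.Graph()
    g.graph["lambda_star"] = est.lambda_star
    g.graph["kappa"] = kappa
    g.graph["edge_fdr"] = fdr
    g.graph["edge_fdr_method"] = method
    for f in est.feature_ids:
        g.add_node(f)
    keep = padj < fdr
    for idx in np.where(keep)[0]:
        i, j = int(iu[0][idx]), int(iu[1][idx])
        g.add_edge(
            est.feature_ids[i],
            est.feature_ids[j],
            pcor=float(pcors[idx]),
            p=float(pvals[idx]),
            p_adj=float(padj[idx]),
        )
    log.info(
        "GGM: %d nodes, %d edges at %g FDR (%s; lambda*=%.4f, kappa=%.1f)",
        g.number_of_nodes(), g.number_of_edges(), fdr, method, est.lambda_star, kappa,
    )
    return g


def infer_network(
    m: OmicsMatrix, fdr: float = 0.05, method: str = "bh"
) -> tuple[nx.Graph, ShrinkageEstimate]:
    """Full GGM chain: shrinkage correlation -> partial cor -> edges.

    Node attributes ``omics_label`` are attached from the matrix.
    """
    est = partial_correlations(shrinkage_correlation(m))
    g = edge_significance(est, fdr=fdr, method=method)
    labels = {str(f): str(m.omics[f]) for f in m.feature_ids}
    nx.set_node_attributes(g, labels, "omics_label")
    return g, est


def annotate_network(network: nx.Graph, results) -> nx.Graph:
    """Attach each node's signed significance score from association results.

    Topology is unchanged; nodes absent from the results keep no score.
    """
    scores = {r.molecule_id: r.p_score for r in results}
    g = network.copy()
    for node in g.nodes:
        if node in scores:
            g.nodes[node]["p_score"] = float(scores[node])
    return g
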