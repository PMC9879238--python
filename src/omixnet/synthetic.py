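"""Synthetic two-group multi-omic cohorts with planted ground truth.

The generator draws latent log2 abundances from a multivariate normal whose
precision matrix carries a known sparse edge set, shifts group-B means on a
known differential feature subset, plants outcome-associated features,
applies per-sample dilution on the abundance scale, punches MCAR holes, and
appends deliberately over-missing features and duplicated protein assays.
Every downstream stage can therefore be tested against recorded truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import OmicsMatrix

_BASE_MEAN_RANGE = (8.0, 16.0)  # per-feature baseline log2 abundance
_DUP_NOISE_SD = 0.1  # additive log2 noise on duplicated assays
_TARGET_CONDITION = 1e3  # cap on the planted precision matrix's condition number


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort."""

    n_group_a: int = 42
    n_group_b: int = 17
    p_metabolites: int = 60
    p_proteins: int = 40
    frac_differential: float = 0.1
    effect_size_log2: float = 3.0
    edge_density: float = 0.02
    partial_cor_strength: float = 0.3
    dilution_sigma: float = 0.5
    missing_rate: float = 0.05
    n_overfiltered_features: int = 0
    duplicate_protein_pairs: int = 0
    outcome_effect_log2: float = 2.0
    n_outcome_features: int = 5
    missing_mode: str = "mcar"  # or "censor" (missing = lowest quantile)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "p_metabolites": self.p_metabolites,
            "p_proteins": self.p_proteins,
            "n_overfiltered_features": self.n_overfiltered_features,
            "duplicate_protein_pairs": self.duplicate_protein_pairs,
            "n_outcome_features": self.n_outcome_features,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if not 0 <= self.frac_differential <= 1:
            raise ConfigError("frac_differential must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.edge_density > 0 and not 0 < self.edge_density < 1:
            raise ConfigError("edge_density must lie in (0, 1) when positive")
        if self.edge_density > 0 and self.p_metabolites + self.p_proteins < 3:
            raise ConfigError("need at least 3 features when planting edges")
        if self.edge_density > 0 and not 0 < self.partial_cor_strength < 1:
            raise ConfigError("partial_cor_strength must lie in (0, 1)")
        if self.dilution_sigma < 0:
            raise ConfigError("dilution_sigma must be >= 0")
        if self.missing_mode not in ("mcar", "censor"):
            raise ConfigError(f"unknown missing_mode {self.missing_mode!r}")
        if self.n_group_a + self.n_group_b < 4:
            raise ConfigError("cohort too small")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown synthetic spec fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated cohort.

    ``differential_features`` and ``outcome_features`` map feature ids to
    the signed log2 shift planted on them; ``true_edges`` holds unordered
    feature-id pairs with nonzero precision entries; ``duplicate_groups``
    maps each duplicate assay id to its canonical protein id.
    """

    differential_features: dict[str, float]
    true_edges: set[tuple[str, str]]
    dilution_factors: pd.Series
    outcome_features: dict[str, float]
    duplicate_groups: dict[str, str]
    overfiltered_features: list[str] = field(default_factory=list)


def plant_precision_matrix(
    p: int, edge_density: float, strength: float, seed: int
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Build a sparse symmetric positive-definite precision matrix.

    Edges are placed Erdos-Renyi style with probability ``edge_density``;
    planted off-diagonal entries have magnitude ``strength`` and random
    sign. Diagonal loading (strict diagonal dominance, then eigenvalue
    flooring to condition number <= 1e3) guarantees positive definiteness,
    so the implied partial correlation of every non-edge is exactly zero.

    Returns the p x p precision matrix and the set of planted index pairs
    ``(i, j)`` with ``i < j``.
    """
    if p < 2:
        raise ConfigError("p must be >= 2")
    if not 0 < edge_density <= 1:
        raise ConfigError("edge_density must lie in (0, 1]")
    if not 0 < strength < 1:
        raise ConfigError("strength must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < edge_density
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    omega = np.zeros((p, p))
    vals = np.where(present, strength * signs, 0.0)
    omega[iu] = vals
    omega += omega.T
    # strict diagonal dominance => positive definite
    np.fill_diagonal(omega, 1.0 + np.abs(omega).sum(axis=1))
    evals = np.linalg.eigvalsh(omega)
    if evals[0] <= 0:  # pragma: no cover - prevented by dominance
        omega += (abs(evals[0]) + 1e-6) * np.eye(p)
        evals = np.linalg.eigvalsh(omega)
    if evals[-1] / evals[0] > _TARGET_CONDITION:  # pragma: no cover
        omega += (evals[-1] / _TARGET_CONDITION - evals[0]) * np.eye(p)
    edges = {(int(i), int(j)) for i, j in zip(iu[0][present], iu[1][present])}
    return omega, edges


def sample_latent(precision: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` rows from N(0, precision^-1) (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(precision)
    cov = (cov + cov.T) / 2
    return rng.multivariate_normal(np.zeros(len(cov)), cov, size=n, method="cholesky")


def _feature_ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    mets = [f"met_{i:04d}" for i in range(spec.p_metabolites)]
    prots = [f"prot_{i:04d}" for i in range(spec.p_proteins)]
    return mets, prots


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[OmicsMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a raw cohort: abundance matrix, sample table and truth.

    The returned matrix is on the raw abundance scale (positive values,
    ``NaN`` missing) and includes the over-missing decoy features and the
    duplicated protein assays, exactly as a real export would.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mets, prots = _feature_ids(spec)
    features = mets + prots
    p = len(features)
    n = spec.n_group_a + spec.n_group_b
    sample_ids = [f"S{i:03d}" for i in range(n)]
    group = np.array(["covid"] * spec.n_group_a + ["bacterial"] * spec.n_group_b)

    # latent log2 abundances with planted partial-correlation structure
    if spec.edge_density > 0 and p >= 2:
        omega, idx_edges = plant_precision_matrix(
            p, spec.edge_density, spec.partial_cor_strength, spec.seed
        )
        cov = np.linalg.inv(omega)
        cov = (cov + cov.T) / 2
        latent = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
        true_edges = {
            tuple(sorted((features[i], features[j]))) for i, j in idx_edges
        }
    else:
        latent = rng.standard_normal((n, p))
        true_edges = set()

    base = rng.uniform(*_BASE_MEAN_RANGE, size=p)
    log2_vals = latent + base  # n x p

    # group-B mean shifts on a known differential subset
    n_diff = int(round(spec.frac_differential * p))
    diff_idx = rng.choice(p, size=n_diff, replace=False) if n_diff else np.array([], int)
    diff_signs = rng.choice([-1.0, 1.0], size=n_diff)
    b_rows = group == "bacterial"
    differential = {}
    for idx, sign in zip(diff_idx, diff_signs):
        shift = sign * spec.effect_size_log2
        log2_vals[b_rows, idx] -= shift  # => covid - bacterial == shift
        differential[features[int(idx)]] = float(shift)

    # clinical outcomes; mortality carries the planted molecular signal
    mortality = rng.binomial(1, 0.35, size=n).astype(float)
    aki = rng.binomial(1, 0.45, size=n).astype(float)
    platelets = np.clip(rng.normal(220, 60, size=n), 5, None)
    pao2_fio2 = rng.uniform(60, 320, size=n)

    outcome = {}
    if spec.n_outcome_features:
        pool = np.arange(spec.p_metabolites, p) if spec.p_proteins else np.arange(p)
        k = min(spec.n_outcome_features, len(pool))
        out_idx = rng.choice(pool, size=k, replace=False)
        out_signs = rng.choice([-1.0, 1.0], size=k)
        for idx, sign in zip(out_idx, out_signs):
            shift = sign * spec.outcome_effect_log2
            log2_vals[:, idx] += shift * mortality
            outcome[features[int(idx)]] = float(shift)

    # abundance scale + per-sample dilution
    dilution = np.exp(rng.normal(0.0, spec.dilution_sigma, size=n))
    abundance = np.power(2.0, log2_vals) * dilution[:, None]

    values = pd.DataFrame(abundance.T, index=features, columns=sample_ids)
    omics = pd.Series(
        ["metabolite"] * spec.p_metabolites + ["protein"] * spec.p_proteins,
        index=features,
    )

    # missingness on the ordinary features
    if spec.missing_rate > 0:
        if spec.missing_mode == "mcar":
            holes = rng.random(values.shape) < spec.missing_rate
        else:  # left-censoring: lowest quantile of each feature goes missing
            ranks = values.rank(axis=1, pct=True).to_numpy()
            holes = ranks <= spec.missing_rate
        values = values.mask(holes)

    # decoy features built to fail the 25% missingness filter
    overfiltered = []
    if spec.n_overfiltered_features:
        n_miss = max(int(np.floor(0.25 * n)) + 1, int(np.ceil(0.35 * n)))
        for i in range(spec.n_overfiltered_features):
            fid = f"met_of{i:03d}"
            row = np.power(2.0, rng.normal(10, 1, size=n)) * dilution
            miss_at = rng.choice(n, size=n_miss, replace=False)
            row[miss_at] = np.nan
            values.loc[fid] = row
            omics.loc[fid] = "metabolite"
            overfiltered.append(fid)

    # duplicated protein assays: noisy copies sharing the missing pattern
    duplicate_groups: dict[str, str] = {}
    if spec.duplicate_protein_pairs:
        k = min(spec.duplicate_protein_pairs, spec.p_proteins)
        dup_of = rng.choice(prots, size=k, replace=False)
        for pid in dup_of:
            dup_id = f"{pid}__dup"
            noise = np.power(2.0, rng.normal(0.0, _DUP_NOISE_SD, size=n))
            values.loc[dup_id] = values.loc[pid].to_numpy() * noise
            omics.loc[dup_id] = "protein"
            duplicate_groups[dup_id] = str(pid)

    matrix = OmicsMatrix(data=values, omics=omics, scale_state="raw")
    samples = pd.DataFrame(
        {
            "group": group,
            "aki": aki,
            "mortality": mortality,
            "platelet_count": platelets,
            "pao2_fio2": pao2_fio2,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        differential_features=differential,
        true_edges=true_edges,
        dilution_factors=pd.Series(dilution, index=sample_ids, name="dilution"),
        outcome_features=outcome,
        duplicate_groups=duplicate_groups,
        overfiltered_features=overfiltered,
    )
    return matrix, samples, truth


def write_truth(truth: SyntheticTruth, prefix) -> None:
    """Dump the truth sets as TSV files next to ``prefix``."""
    import pathlib

    prefix = pathlib.Path(prefix)
    pd.DataFrame(
        sorted(truth.differential_features.items()),
        columns=["feature_id", "planted_shift"],
    ).to_csv(prefix.with_suffix(".differential.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(truth.true_edges), columns=["source", "target"]).to_csv(
        prefix.with_suffix(".edges.tsv"), sep="\t", index=False
    )
    truth.dilution_factors.rename_axis("sample_id").to_frame().to_csv(
        prefix.with_suffix(".dilution.tsv"), sep="\t"
    )
    pd.DataFrame(
        sorted(truth.outcome_features.items()), columns=["feature_id", "planted_shift"]
    ).to_csv(prefix.with_suffix(".outcome.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.duplicate_groups.items()), columns=["duplicate_id", "canonical_id"]
    ).to_csv(prefix.with_suffix(".duplicates.tsv"), sep="\t", index=False)
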