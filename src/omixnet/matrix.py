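"""Core data containers: feature-by-sample abundance matrix and sample table.

The :class:`OmicsMatrix` is the object flowing through preprocessing. It
wraps a float DataFrame (features as rows, samples as columns, ``NaN`` =
missing) together with a per-feature omics label and a ``scale_state`` tag
that enforces the processing order raw -> normalized -> log2 -> imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, PipelineOrderError

SCALE_STATES = ("raw", "normalized", "log2", "imputed")
OMICS_LABELS = ("metabolite", "protein")

#: columns expected in a sample table besides the index (sample_id)
SAMPLE_COLUMNS = ("group", "aki", "mortality", "platelet_count", "pao2_fio2")
GROUPS = ("covid", "bacterial")


@dataclass
class OmicsMatrix:
    """Feature x sample abundance matrix with omics labels and a scale tag.

    Parameters
    ----------
    data:
        Float DataFrame, features as rows, samples as columns; ``NaN``
        marks a missing measurement.
    omics:
        Series mapping each feature id to ``"metabolite"`` or ``"protein"``,
        aligned with ``data.index``.
    scale_state:
        One of ``raw``, ``normalized``, ``log2``, ``imputed``.
    """

    data: pd.DataFrame
    omics: pd.Series
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise PipelineOrderError(
                f"unknown scale_state {self.scale_state!r}; expected one of {SCALE_STATES}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        self.omics = self.omics.reindex(idx)
        bad = self.omics[~self.omics.isin(OMICS_LABELS)]
        if len(bad):
            raise FormatError(
                f"features without a valid omics label: {bad.index.tolist()[:5]}"
            )
        self.data = self.data.astype(float)
        if self.scale_state in ("raw", "normalized"):
            vals = self.data.to_numpy()
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise FormatError(
                    f"{self.scale_state} matrix contains non-positive values"
                )

    # -- convenience ----------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing values."""
        return self.data.isna().mean(axis=1)

    def with_data(self, data: pd.DataFrame, scale_state: str | None = None) -> "OmicsMatrix":
        """Return a copy with new values (and optionally a new scale tag)."""
        return OmicsMatrix(
            data=data,
            omics=self.omics.reindex(data.index),
            scale_state=scale_state or self.scale_state,
        )

    def require_state(self, *states: str) -> None:
        if self.scale_state not in states:
            raise PipelineOrderError(
                f"operation requires scale_state in {states}, got {self.scale_state!r}"
            )

    def copy(self) -> "OmicsMatrix":
        return replace(self, data=self.data.copy(), omics=self.omics.copy())


def concat_matrices(a: OmicsMatrix, b: OmicsMatrix) -> OmicsMatrix:
    """Stack two matrices (e.g. metabolites + proteins) over shared samples."""
    if a.scale_state != b.scale_state:
        raise PipelineOrderError(
            f"cannot concatenate scale states {a.scale_state!r} and {b.scale_state!r}"
        )
    if not a.sample_ids.equals(b.sample_ids):
        raise FormatError("sample ids differ between matrices")
    overlap = a.feature_ids.intersection(b.feature_ids)
    if len(overlap):
        raise FormatError(f"feature ids shared between matrices: {overlap.tolist()[:5]}")
    return OmicsMatrix(
        data=pd.concat([a.data, b.data]),
        omics=pd.concat([a.omics, b.omics]),
        scale_state=a.scale_state,
    )


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-table schema and return a normalized copy.

    Index = sample_id (unique); ``group`` in {covid, bacterial}; ``aki`` and
    ``mortality`` 0/1 or missing; ``platelet_count`` >= 0; ``pao2_fio2`` > 0.
    """
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in sample table: {dups}")
    out = samples.copy()
    if "group" not in out.columns:
        raise FormatError("sample table lacks a 'group' column")
    bad = out.loc[~out["group"].isin(GROUPS), "group"]
    if len(bad):
        raise FormatError(f"unknown group labels: {sorted(bad.unique())}")
    for col in ("aki", "mortality"):
        if col in out.columns:
            vals = out[col].dropna()
            if not vals.isin([0, 1]).all():
                raise FormatError(f"column {col!r} must be 0/1 or missing")
    if "platelet_count" in out.columns:
        vals = out["platelet_count"].dropna()
        if (vals < 0).any():
            raise FormatError("platelet_count must be >= 0")
    if "pao2_fio2" in out.columns:
        vals = out["pao2_fio2"].dropna()
        if (vals <= 0).any():
            raise FormatError("pao2_fio2 must be > 0")
    return out


def check_samples_match(m: OmicsMatrix, samples: pd.DataFrame) -> None:
    """Every matrix sample must appear exactly once in the sample table."""
    missing = m.sample_ids.difference(samples.index)
    if len(missing):
        raise FormatError(f"samples absent from sample table: {missing.tolist()[:5]}")
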