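"""Pathway-level aggregation of differential results.

Pathways come from an annotation table (molecule_id, pathway_name, source,
kegg_category). Eligible pathways are metabolite sub-pathways whose name
contains "metabolism" (case-insensitive) and KEGG pathways outside the
disease category; a pathway is retained when it also contains at least
``min_significant`` significant molecules.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import AssociationResult
from .errors import AnalysisError

log = logging.getLogger(__name__)

SUBPATHWAY_SOURCE = "metabolon_subpathway"
KEGG_SOURCE = "kegg"
DISEASE_CATEGORY = "human diseases"


def _eligible(row) -> bool:
    if row.source == SUBPATHWAY_SOURCE:
        return "metabolism" in str(row.pathway_name).lower()
    if row.source == KEGG_SOURCE:
        cat = "" if pd.isna(row.kegg_category) else str(row.kegg_category)
        return cat.strip().lower() != DISEASE_CATEGORY
    return False


def annotate_and_filter(
    results: list[AssociationResult],
    annotations: pd.DataFrame,
    min_significant: int = 3,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate association results to pathways and apply the filters.

    Returns the retained-pathway summary (pathway_name, source,
    n_annotated, n_significant, n_up, n_down) sorted by significance count,
    plus the list of tested molecules with no annotation. Annotation rows
    referencing unknown molecules are dropped with a warning.
    """
    if min_significant < 0:
        raise AnalysisError("min_significant must be >= 0")
    required = {"molecule_id", "pathway_name", "source"}
    missing_cols = required - set(annotations.columns)
    if missing_cols:
        raise AnalysisError(f"annotation table lacks columns {sorted(missing_cols)}")
    ann = annotations.copy()
    if "kegg_category" not in ann.columns:
        ann["kegg_category"] = np.nan

    by_molecule = {r.molecule_id: r for r in results}
    unknown = ~ann["molecule_id"].isin(by_molecule)
    if unknown.any():
        log.warning(
            "ignoring %d annotation rows for molecules absent from the results",
            int(unknown.sum()),
        )
        ann = ann[~unknown]

    rows = []
    for (pathway_name, source), grp in ann.groupby(["pathway_name", "source"], sort=True):
        mols = [by_molecule[mid] for mid in grp["molecule_id"].unique()]
        sig = [r for r in mols if r.p_adj < fdr]
        rows.append(
            {
                "pathway_name": pathway_name,
                "source": source,
                "kegg_category": grp["kegg_category"].iloc[0],
                "n_annotated": len(mols),
                "n_significant": len(sig),
                "n_up": sum(r.d > 0 for r in sig),
                "n_down": sum(r.d < 0 for r in sig),
                "significant_molecules": ";".join(sorted(r.molecule_id for r in sig)),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "pathway_name",
            "source",
            "kegg_category",
            "n_annotated",
            "n_significant",
            "n_up",
            "n_down",
            "significant_molecules",
        ],
    )
    if len(summary):
        eligible = summary.apply(_eligible, axis=1)
        retained = summary[eligible & (summary["n_significant"] >= min_significant)]
        retained = retained.sort_values(
            ["n_significant", "pathway_name"], ascending=[False, True]
        ).reset_index(drop=True)
    else:
        retained = summary

    annotated_ids = set(ann["molecule_id"])
    unannotated = sorted(mid for mid in by_molecule if mid not in annotated_ids)
    return retained, unannotated
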