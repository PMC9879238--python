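"""Readers and writers for all tabular and graph artifacts.

Canonical dialect: tab-separated UTF-8 with '.' decimal separator.
Empty cells and the literal string ``NA`` are read as missing; missing
values are written as ``NA``. Matrices are features-as-rows (first column
= feature id, remaining columns = samples); a ``transpose`` flag on read
accepts the samples-as-rows orientation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, OmixnetError
from .matrix import OmicsMatrix, validate_sample_table

NA_VALUES = ["", "NA"]
NA_REP = "NA"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False
    )


def read_matrix(path, omics_label: str, transpose: bool = False) -> OmicsMatrix:
    """Read an abundance TSV into a raw-scale :class:`OmicsMatrix`.

    Parameters
    ----------
    path:
        TSV file with features as rows and samples as columns (or the
        transpose if ``transpose=True``).
    omics_label:
        ``"metabolite"`` or ``"protein"``, applied to every feature.
    """
    df = _read_tsv(path)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value at feature {row!r}, sample {col!r}"
            ) from exc
    omics = pd.Series(omics_label, index=df.index)
    return OmicsMatrix(data=df, omics=omics, scale_state="raw")


def write_matrix(m: OmicsMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep=NA_REP)


def read_sample_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df.index.name = "sample_id"
    return validate_sample_table(df)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    df = samples.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep=NA_REP)


def read_annotations(path) -> pd.DataFrame:
    """Read a molecule -> pathway annotation table.

    Expected columns: molecule_id, pathway_name, source and (for KEGG rows)
    kegg_category.
    """
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    required = {"molecule_id", "pathway_name", "source"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation table lacks columns {sorted(missing)}")
    if "kegg_category" not in df.columns:
        df["kegg_category"] = np.nan
    if df.duplicated(["molecule_id", "pathway_name"]).any():
        raise FormatError(f"{path}: duplicate (molecule_id, pathway_name) rows")
    return df


# -- association results ------------------------------------------------

RESULT_COLUMNS = [
    "molecule_id",
    "omics_label",
    "outcome_name",
    "estimate",
    "t_statistic",
    "p",
    "p_adj",
    "d",
    "p_score",
    "n_used",
]


def write_results(results_frame: pd.DataFrame, path) -> None:
    """Write an association-results table (molecule, estimate, statistic, p,
    p_adj, direction, p_score)."""
    results_frame.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)


# -- networks -----------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "pcor", "p", "p_adj"]


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write a GGM network as GraphML or as an edge TSV.

    GraphML nodes carry ``omics_label`` and ``p_score`` attributes; edges
    carry ``pcor``, ``p`` and ``p_adj``. The edge TSV has the columns
    source, target, pcor, p, p_adj with edges sorted by (source, target).
    """
    if format == "graphml":
        g = nx.Graph()
        for node in sorted(network.nodes):
            attrs = {
                k: v
                for k, v in network.nodes[node].items()
                if v is not None and not (isinstance(v, float) and np.isnan(v))
            }
            g.add_node(node, **attrs)
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            g.add_edge(u, v, **network.edges[u, v])
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = []
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            d = network.edges[u, v]
            rows.append((u, v, d.get("pcor"), d.get("p"), d.get("p_adj")))
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(
            path, sep="\t", index=False, na_rep=NA_REP, float_format="%.10g"
        )
    else:
        raise OmixnetError(f"unknown network format {format!r}")


def read_edge_tsv(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, pcor=row.pcor, p=row.p, p_adj=row.p_adj)
    return g


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
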