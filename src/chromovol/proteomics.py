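"""iBAQ mass-fraction bookkeeping and protein correlation networks.

iBAQ (intensity-based absolute quantification) intensities are
mass-proportional, so the share of a protein set in the summed intensity
of an experiment is its share of the total protein mass. Sub-complexes
are recovered as connected components of the graph whose edges join
protein pairs with correlated abundance profiles across experiments —
e.g. a nucleolar/periphery block and a ribosomal/RNA-associated block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_GROUPS = ("histone", "periphery", "ribosomal", "other")


@dataclass
class ProteinIntensityTable:
    """Proteins x experiments iBAQ matrix with per-protein annotations.

    ``intensities``: DataFrame indexed by protein id, one column per
    experiment, values >= 0. ``groups``: Series mapping protein id to an
    annotation label (histone, periphery/nucleolar, ribosomal/RNA, ...).
    """

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("iBAQ intensities must be non-negative")
        if not self.intensities.index.equals(self.groups.index):
            raise ValueError("groups must be indexed by the same protein ids")

    @staticmethod
    def from_arrays(intensities, protein_ids, groups, experiment_ids) -> "ProteinIntensityTable":
        df = pd.DataFrame(np.asarray(intensities, dtype=float), index=list(protein_ids), columns=list(experiment_ids))
        return ProteinIntensityTable(intensities=df, groups=pd.Series(list(groups), index=df.index))

    @staticmethod
    def read_csv(path, group_column: str = "group") -> "ProteinIntensityTable":
        df = pd.read_csv(path, index_col=0)
        groups = df.pop(group_column)
        return ProteinIntensityTable(intensities=df.astype(float), groups=groups)

    def to_csv(self, path, group_column: str = "group") -> None:
        out = self.intensities.copy()
        out.insert(0, group_column, self.groups)
        out.to_csv(path)

    @property
    def n_experiments(self) -> int:
        return self.intensities.shape[1]

    def drop_all_zero(self) -> "ProteinIntensityTable":
        keep = self.intensities.sum(axis=1) > 0
        if (~keep).any():
            log.info("dropping %d all-zero protein rows", int((~keep).sum()))
        return ProteinIntensityTable(self.intensities.loc[keep], self.groups.loc[keep])


def log_transform(table: ProteinIntensityTable) -> pd.DataFrame:
    """log10 intensities; zeros imputed to half the per-experiment minimum.

    iBAQ values span orders of magnitude, so correlations are computed in
    log space. The imputation is logged per experiment.
    """
    df = table.intensities.copy()
    for col in df.columns:
        nonzero = df[col][df[col] > 0]
        if nonzero.empty:
            raise ValueError(f"experiment {col} has no nonzero intensities")
        fill = nonzero.min() / 2.0
        n_zero = int((df[col] == 0).sum())
        if n_zero:
            log.info("experiment %s: imputing %d zeros to %.3g", col, n_zero, fill)
            df.loc[df[col] == 0, col] = fill
    return np.log10(df)


def correlation_network(
    table: ProteinIntensityTable,
    method: str = "pearson",
    edge_threshold: float = 0.8,
) -> nx.Graph:
    """Threshold graph of between-protein abundance correlations.

    Nodes are proteins (zero-variance profiles are excluded and logged);
    an edge joins proteins whose correlation across experiments is
    >= ``edge_threshold``. Self-edges are excluded. Connected components
    are candidate sub-complexes (see :func:`connected_components`).
    """
    if table.n_experiments < 3:
        raise ValueError("correlation analysis needs at least 3 experiments")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    logs = log_transform(table.drop_all_zero())
    variable = logs.std(axis=1) > 0
    if (~variable).any():
        log.info("excluding %d zero-variance proteins", int((~variable).sum()))
    logs = logs.loc[variable]
    corr = logs.T.corr(method=method)

    graph = nx.Graph()
    graph.add_nodes_from(logs.index)
    nx.set_node_attributes(graph, table.groups.loc[logs.index].to_dict(), "group")
    ids = list(logs.index)
    vals = corr.values
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= edge_threshold:
                graph.add_edge(ids[i], ids[j], weight=float(vals[i, j]))
    return graph


def connected_components(graph: nx.Graph):
    """Components sorted by descending size (then lexicographic)."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), c))


def mass_fraction(table: ProteinIntensityTable, protein_set) -> tuple[float, pd.Series]:
    """Percent of total protein mass carried by ``protein_set``.

    Returns (mean across experiments, per-experiment Series); iBAQ sums
    within each experiment proxy mass.
    """
    proteins = list(protein_set)
    missing = set(proteins) - set(table.intensities.index)
    if missing:
        raise KeyError(f"proteins not in table: {sorted(missing)[:5]} ...")
    if table.intensities.empty:
        raise ValueError("empty intensity table")
    totals = table.intensities.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("an experiment has zero total intensity")
    per_exp = 100.0 * table.intensities.loc[proteins].sum(axis=0) / totals
    return float(per_exp.mean()), per_exp


def mass_fraction_by_group(table: ProteinIntensityTable) -> pd.Series:
    """Percent mass share of each annotation group (sums to 100)."""
    shares = {}
    for g in table.groups.unique():
        shares[g], _ = mass_fraction(table, table.groups.index[table.groups == g])
    return pd.Series(shares).sort_index()


def cluster_annotation_report(
    graph: nx.Graph,
    table: ProteinIntensityTable,
    min_cluster_size: int = 2,
) -> pd.DataFrame:
    """Per-component composition and mass share of a correlation network.

    One row per connected component: size, dominant annotation, the
    fraction of members carrying it, mass share (percent of total), and a
    singleton flag — a large protein sitting alone in the network (the
    Ki-67-like case) is still reported with its own mass share.
    """
    rows = []
    for k, members in enumerate(connected_components(graph)):
        groups = table.groups.loc[members]
        dominant = groups.value_counts().idxmax() if len(groups) else ""
        purity = float((groups == dominant).mean()) if len(groups) else 0.0
        share, _ = mass_fraction(table, members)
        rows.append(
            {
                "cluster": k + 1,
                "size": len(members),
                "dominant_group": dominant,
                "purity": purity,
                "mass_share_pct": share,
                "singleton": len(members) < min_cluster_size,
                "members": ";".join(members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", "size", "dominant_group", "purity", "mass_share_pct", "singleton", "members"],
    )
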