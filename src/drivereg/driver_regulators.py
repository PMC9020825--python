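"""Driver-regulator networks and cross-dataset recurrence.

The integrative step of the pipeline: connect the transcription factors
whose regulons are active in the non-myogenic compartment to the
trajectory driver genes of that compartment. A TF is linked to a driver
gene when the gene is among its regulon targets; TFs with at least
``min_driver_targets`` such links are the dataset's "driver
regulators". Repeating this per dataset and counting in how many
datasets each TF appears yields the recurrence table — TFs recurring in
all datasets are the core regulators of the fate transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

from .regulons import RegulonSet

NODE_REGULON = "Active regulon"
NODE_DRIVER = "driver gene"


def build_driver_network(drivers, active_regulons: RegulonSet) -> nx.DiGraph:
    """Bipartite TF -> driver-gene network for one dataset.

    An edge (TF, g) exists iff g is a target of the TF's regulon AND g
    is in the driver list. Nodes carry ``node_type`` ("Active regulon"
    or "driver gene"); TF nodes also record whether the regulon was an
    ``_extended`` (lower-confidence) one. An empty intersection yields
    an empty network.
    """
    drivers = set(drivers)
    g = nx.DiGraph()
    for tf, targets in active_regulons:
        hits = sorted(drivers & set(targets))
        if not hits:
            continue
        g.add_node(tf, node_type=NODE_REGULON, extended=tf in active_regulons.extended)
        for gene in hits:
            g.add_node(gene, node_type=NODE_DRIVER)
            g.add_edge(tf, gene)
    return g


def identify_driver_regulators(network: nx.DiGraph, min_driver_targets: int = 1) -> set:
    """TFs with at least ``min_driver_targets`` driver-gene edges."""
    return {n for n, d in network.nodes(data=True)
            if d.get("node_type") == NODE_REGULON
            and network.out_degree(n) >= min_driver_targets}


@dataclass
class RecurrenceTable:
    """Presence/absence of each driver regulator across datasets."""

    presence: pd.DataFrame     # TFs x datasets, 0/1
    frequency: pd.Series       # per-TF dataset count, sorted desc then by name

    @property
    def max_frequency(self) -> int:
        return int(self.frequency.max()) if len(self.frequency) else 0

    @property
    def top_regulators(self) -> list:
        """TFs attaining the maximum frequency."""
        if not len(self.frequency):
            return []
        return sorted(self.frequency.index[self.frequency == self.frequency.max()])


def cross_dataset_recurrence(tf_sets) -> RecurrenceTable:
    """Combine per-dataset driver-regulator sets into a recurrence table.

    ``tf_sets`` is a mapping dataset name -> TF collection (or a
    sequence, auto-named). The presence matrix is binary TFs x datasets;
    the frequency is its row sum, sorted by frequency descending then TF
    name — the barplot ordering.
    """
    if not isinstance(tf_sets, dict):
        tf_sets = {f"dataset{i + 1}": s for i, s in enumerate(tf_sets)}
    if not tf_sets:
        raise ValueError("need at least one dataset")
    all_tfs = sorted(set().union(*[set(s) for s in tf_sets.values()]))
    presence = pd.DataFrame(
        {name: [int(tf in set(s)) for tf in all_tfs] for name, s in tf_sets.items()},
        index=pd.Index(all_tfs, name="TF"),
    )
    freq = presence.sum(axis=1)
    freq = freq.iloc[sorted(range(len(freq)),
                            key=lambda i: (-freq.iloc[i], str(freq.index[i])))]
    return RecurrenceTable(presence=presence, frequency=freq.rename("frequency"))


def export_network(network: nx.DiGraph, graphml_path=None, edges_tsv_path=None) -> None:
    """Write the network as GraphML and/or an edge-list TSV with node types."""
    if graphml_path is not None:
        nx.write_graphml(network, graphml_path)
    if edges_tsv_path is not None:
        rows = [{"TF": u, "driver_gene": v,
                 "extended": network.nodes[u].get("extended", False)}
                for u, v in network.edges]
        pd.DataFrame(rows, columns=["TF", "driver_gene", "extended"]).to_csv(
            edges_tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bundled worked-example tables
# ---------------------------------------------------------------------------

def load_published_recurrence_matrix() -> pd.DataFrame:
    """The published presence/absence matrix of non-myogenic driver regulators.

    30 TFs x 4 embryonic-stage datasets (E10.5–E14.5), binary. The
    worked example of the recurrence analysis.
    """
    with resources.files("drivereg.data").joinpath(
            "table2_driver_regulators.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def load_published_driver_lists() -> pd.DataFrame:
    """The published per-dataset top driver-gene columns (100 rows each)."""
    with resources.files("drivereg.data").joinpath("table1_drivers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def recurrence_from_presence(presence: pd.DataFrame) -> RecurrenceTable:
    """Run the recurrence analysis on an explicit presence/absence matrix."""
    tf_sets = {col: presence.index[presence[col].astype(bool)] for col in presence.columns}
    return cross_dataset_recurrence(tf_sets)
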