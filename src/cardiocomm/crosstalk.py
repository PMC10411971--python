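"""Ligand-receptor crosstalk networks between cell clusters.

A directed ligand->receptor database for the target species is built
by ortholog expansion of a human pair table (full one-to-many product;
pairs with an unmapped side are dropped and counted).  A gene counts
as expressed in a (cluster, dataset) group when its normalized
pseudobulk value reaches the group's upper quartile (by default the
75th percentile of the group's nonzero values).  Interaction edges are
enumerated for every database pair whose ligand is expressed in a
sender and receptor in a receiver; comparing the edge sets of two
conditions at a matched timepoint partitions them into
condition-specific and shared pairs.  Networks export to edge CSV,
Cytoscape SIF, and GraphML with interaction counts as edge weights.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import pandas as pd

from .pseudobulk import PseudobulkTable, upper_quartile
from .simulate import parse_dataset_id

__all__ = [
    "InteractionEdge",
    "build_lr_database",
    "load_demo_database",
    "expressed_genes",
    "enumerate_interactions",
    "condition_specific_pairs",
    "summarize_network",
    "write_sif",
    "read_sif",
    "write_graphml",
]

EDGE_KEY = ["sender", "ligand", "receptor", "receiver"]


class InteractionEdge(NamedTuple):
    sender: str
    ligand: str
    receptor: str
    receiver: str
    dataset: str


def build_lr_database(human_pairs: pd.DataFrame,
                      ortho: Mapping[str, Iterable[str]]
                      ) -> tuple[pd.DataFrame, dict]:
    """Ortholog-expand a human ligand-receptor table to the target species.

    ``human_pairs`` needs columns ``ligand`` and ``receptor`` (human
    symbols); ``ortho`` maps human gene -> iterable of target-species
    genes.  Each pair expands to the Cartesian product of its two
    ortholog sets; pairs with an unmapped side are dropped and tallied
    in the report.  The database is deduplicated and sorted.
    """
    if len(human_pairs) == 0:
        raise ValueError("empty human pair table")
    for col in ("ligand", "receptor"):
        if col not in human_pairs.columns:
            raise ValueError(f"human pair table lacks column {col!r}")
        if human_pairs[col].isna().any():
            raise ValueError(f"malformed rows: missing {col}")

    rows, dropped = [], 0
    for _, row in human_pairs.iterrows():
        hl, hr = str(row["ligand"]), str(row["receptor"])
        lig_orth = sorted(set(ortho.get(hl, ())))
        rec_orth = sorted(set(ortho.get(hr, ())))
        if not lig_orth or not rec_orth:
            dropped += 1
            continue
        for zl in lig_orth:
            for zr in rec_orth:
                rows.append((zl, zr, f"{hl}->{hr}"))
    db = pd.DataFrame(rows, columns=["ligand", "receptor", "source_pair"])
    db = (db.groupby(["ligand", "receptor"], as_index=False)
            .agg(source_pair=("source_pair", lambda s: ";".join(sorted(set(s))))))
    db = db.sort_values(["ligand", "receptor"]).reset_index(drop=True)
    report = {
        "n_human_pairs": int(len(human_pairs)),
        "n_dropped_unmapped": int(dropped),
        "n_target_pairs": int(len(db)),
    }
    return db, report


def load_demo_database() -> tuple[pd.DataFrame, dict]:
    """Small curated human pair table + human->zebrafish ortholog demo map."""
    data = Path(__file__).parent / "data"
    pairs = pd.read_csv(data / "lr_pairs_human_demo.tsv", sep="\t")
    orth = pd.read_csv(data / "orthologs_human_zebrafish_demo.tsv", sep="\t")
    ortho_map = (orth.groupby("human_gene")["zebrafish_gene"]
                 .apply(lambda s: sorted(set(s))).to_dict())
    return build_lr_database(pairs, ortho_map)


def expressed_genes(pb: PseudobulkTable, group, quantile: float = 0.75,
                    nonzero: bool = True) -> set[str]:
    """Genes at or above the group's upper-quantile normalized expression.

    The cutoff is the ``quantile`` (linear interpolation) of the group's
    nonzero normalized values; ties at the cutoff count as expressed.
    A group with no nonzero gene yields an empty set with a warning.
    """
    if pb.norm is None:
        raise ValueError("pseudobulk table has no normalized layer")
    if group not in pb.norm.columns:
        raise KeyError(f"group {group!r} not in pseudobulk table")
    values = pb.norm[group]
    try:
        cutoff = upper_quartile(values.to_numpy(), quantile, nonzero=nonzero)
    except ValueError:
        warnings.warn(f"group {group!r} has no nonzero expression", stacklevel=2)
        return set()
    return set(values.index[values.to_numpy() >= cutoff])


def enumerate_interactions(db: pd.DataFrame,
                           expressed: Mapping[str, set[str]],
                           senders: Iterable[str], receivers: Iterable[str],
                           dataset: str) -> pd.DataFrame:
    """All (sender, ligand, receptor, receiver) edges supported by expression.

    ``expressed`` maps cluster -> expressed gene set for this dataset.
    An edge is emitted for every database pair with the ligand expressed
    in the sender and the receptor in the receiver; autocrine edges
    (sender == receiver) are allowed.  Deterministic ordering by
    (sender, receiver, ligand, receptor).
    """
    senders = sorted(set(senders))
    receivers = sorted(set(receivers))
    for c in senders + receivers:
        if c not in expressed:
            raise KeyError(f"cluster {c!r} has no expression call for {dataset!r}")
    rows = []
    for s in senders:
        lig_ok = db["ligand"].isin(expressed[s])
        for r in receivers:
            sub = db[lig_ok & db["receptor"].isin(expressed[r])]
            for lig, rec in zip(sub["ligand"], sub["receptor"]):
                rows.append((s, lig, rec, r, dataset))
    edges = pd.DataFrame(rows, columns=EDGE_KEY[:2] + EDGE_KEY[2:] + ["dataset"])
    return (edges.sort_values(["sender", "receiver", "ligand", "receptor"])
            .reset_index(drop=True))


def _edge_keys(edges: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, edges[EDGE_KEY].itertuples(index=False)))


def _check_timepoints(edges_a: pd.DataFrame, edges_b: pd.DataFrame) -> None:
    def tp(edges):
        tps = set()
        for ds in edges["dataset"].unique():
            try:
                tps.add(parse_dataset_id(ds)[1])
            except ValueError:
                return None
        return tps
    ta, tb = tp(edges_a), tp(edges_b)
    if ta is not None and tb is not None and ta and tb and ta != tb:
        raise ValueError(f"edge lists computed at different timepoints: {ta} vs {tb}")


def condition_specific_pairs(edges_a: pd.DataFrame, edges_b: pd.DataFrame,
                             label_a: str = "PBS", label_b: str = "CL"
                             ) -> pd.DataFrame:
    """Partition the union of two edge sets into A-only / B-only / shared.

    Edges are keyed by (sender, ligand, receptor, receiver); the dataset
    field is excluded from identity, but both lists must come from the
    same timepoint (checked when dataset ids are parseable).  The three
    specificity classes partition the union exactly.
    """
    _check_timepoints(edges_a, edges_b)
    keys_a, keys_b = _edge_keys(edges_a), _edge_keys(edges_b)
    rows = []
    for key in sorted(keys_a | keys_b):
        in_a, in_b = key in keys_a, key in keys_b
        spec = "shared" if (in_a and in_b) else (
            f"{label_a}-only" if in_a else f"{label_b}-only")
        rows.append(key + (spec,))
    return pd.DataFrame(rows, columns=EDGE_KEY + ["specificity"])


def summarize_network(edges: pd.DataFrame) -> pd.DataFrame:
    """Sender x receiver matrix of interaction-event counts."""
    if len(edges) == 0:
        return pd.DataFrame()
    counts = (edges.groupby(["sender", "receiver"], observed=True).size()
              .unstack(fill_value=0))
    return counts.sort_index(axis=0).sort_index(axis=1)


def write_sif(edges: pd.DataFrame, path) -> Path:
    """Cytoscape SIF: one ``sender<TAB>L:R<TAB>receiver`` row per edge."""
    path = Path(path)
    lines = [f"{e.sender}\t{e.ligand}:{e.receptor}\t{e.receiver}"
             for e in edges.itertuples()]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_sif(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        sender, lr, receiver = line.split("\t")
        lig, rec = lr.split(":", 1)
        rows.append((sender, lig, rec, receiver))
    return pd.DataFrame(rows, columns=EDGE_KEY)


def write_graphml(edges: pd.DataFrame, path) -> Path:
    """Cluster-level digraph with interaction counts as edge weights."""
    g = nx.DiGraph()
    counts = summarize_network(edges)
    for sender in counts.index:
        for receiver in counts.columns:
            n = int(counts.loc[sender, receiver])
            if n > 0:
                g.add_edge(sender, receiver, weight=n)
    nx.write_graphml(g, path)
    return Path(path)
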