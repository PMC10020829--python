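"""Observer-identifier bipartite network of a bioblitz event.

Observations made during an event are typically identified (or confirmed) on
the platform by a wider community than the people who attended.  The network
has one node per user, labelled by role — ``observer`` (recorded event
observations), ``identifier`` (identified event records without observing),
or ``both`` — and one weighted edge per (observer, identifier) pair, the
weight counting the identifications that identifier made on that observer's
event records.  Self-identifications are included by default (they are what
creates ``both`` nodes); exclude them to study purely external engagement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["BipartiteNetwork", "build_network", "degree_table"]


@dataclass
class BipartiteNetwork:
    """Node roles, weighted edges and the identifications excluded as
    unresolvable (unknown observation) or by the self-identification policy."""

    nodes: pd.DataFrame   # user_id, role
    edges: pd.DataFrame   # observer_id, identifier_id, weight
    n_records: int        # event observations the network was built from
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["identification_id", "reason"]))

    @property
    def total_weight(self) -> int:
        return int(self.edges["weight"].sum()) if not self.edges.empty else 0

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph (identifier -> observer), role as node attribute,
        suitable for GraphML export."""
        g = nx.DiGraph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["user_id"], role=row["role"])
        for _, row in self.edges.iterrows():
            g.add_edge(row["identifier_id"], row["observer_id"], weight=int(row["weight"]))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_network(event_obs: pd.DataFrame, ids: pd.DataFrame,
                  include_self: bool = True) -> BipartiteNetwork:
    """Build the observer-identifier network of one project-event.

    Parameters
    ----------
    event_obs
        Observations of a single event (e.g. from
        :func:`bioblitz.projects.event_observations`).
    ids
        Identification table; rows referencing observations outside
        ``event_obs`` are excluded and reported.
    include_self
        Count identifications users made on their own records (default);
        when False those rows are excluded and a user identifying only their
        own records is not an identifier.
    """
    obs_map = event_obs[["observation_id", "observer_id"]].drop_duplicates("observation_id")
    linked = ids.merge(obs_map, on="observation_id", how="left")

    excluded_rows = []
    unknown = linked["observer_id"].isna()
    for _, row in linked[unknown].iterrows():
        excluded_rows.append((row["identification_id"], "unknown observation"))
    linked = linked[~unknown]

    if not include_self:
        self_mask = linked["identifier_id"] == linked["observer_id"]
        for _, row in linked[self_mask].iterrows():
            excluded_rows.append((row["identification_id"], "self-identification"))
        linked = linked[~self_mask]

    edges = (linked.groupby(["observer_id", "identifier_id"], sort=True)
             .size().rename("weight").reset_index())

    observers = set(event_obs["observer_id"])
    identifiers = set(linked["identifier_id"])
    users = sorted(observers | identifiers)
    roles = ["both" if u in observers and u in identifiers
             else "observer" if u in observers else "identifier"
             for u in users]
    nodes = pd.DataFrame({"user_id": users, "role": roles})

    excluded = pd.DataFrame(excluded_rows, columns=["identification_id", "reason"])
    return BipartiteNetwork(nodes=nodes, edges=edges,
                            n_records=int(len(event_obs)), excluded=excluded)


def degree_table(net: BipartiteNetwork) -> pd.DataFrame:
    """Per-user engagement table: role, identifications made, event records
    observed.  Sorted by identifications made (descending), ties by user id
    — the ordering behind 'node size proportional to identifications'."""
    made = (net.edges.groupby("identifier_id")["weight"].sum()
            if not net.edges.empty else pd.Series(dtype=int))
    table = net.nodes.copy()
    table["n_identifications_made"] = (
        table["user_id"].map(made).fillna(0).astype(int))
    table["n_records_observed"] = 0
    return (table.sort_values(["n_identifications_made", "user_id"],
                              ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))


def degree_table_with_records(net: BipartiteNetwork,
                              event_obs: pd.DataFrame) -> pd.DataFrame:
    """:func:`degree_table` with the observed-record counts filled in."""
    table = degree_table(net)
    counts = event_obs.groupby("observer_id").size()
    table["n_records_observed"] = table["user_id"].map(counts).fillna(0).astype(int)
    return table
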