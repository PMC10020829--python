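#!/usr/bin/env python
"""Build the observer-identifier network of the busiest simulated event.

Event records are typically identified by a community wider than the event's
attendees: nodes are users (observer / identifier / both), edges weight the
identifications an identifier made on an observer's event records.

Run analysis/01_simulate.py first.
"""

from pathlib import Path

from bioblitz import eventlog, network, projects

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def main() -> None:
    obs = eventlog.read_observations(DATA / "observations.csv").table
    ids = eventlog.read_identifications(DATA / "identifications.csv").table
    projs = eventlog.read_projects(DATA / "projects.csv").table

    busiest = max(projs.itertuples(index=False),
                  key=lambda p: (obs["project_id"] == p.project_id).sum())
    focal = projs[projs["project_id"] == busiest.project_id].iloc[0]
    ev_obs, _ = projects.event_observations(focal, obs)
    net = network.build_network(ev_obs, ids)

    net.nodes.to_csv(OUT / "network_nodes.csv", index=False)
    net.edges.to_csv(OUT / "network_edges.csv", index=False)
    degrees = network.degree_table_with_records(net, ev_obs)
    degrees.to_csv(OUT / "network_degrees.csv", index=False)
    net.write_graphml(OUT / "network.graphml")

    roles = net.nodes["role"].value_counts()
    print(f"event {focal['project_id']}: {len(ev_obs)} records, "
          f"{len(net.nodes)} users in the network "
          f"({roles.get('observer', 0)} observer-only, "
          f"{roles.get('identifier', 0)} identifier-only, "
          f"{roles.get('both', 0)} both)")
    top = degrees.iloc[0]
    print(f"busiest identifier: {top['user_id']} with "
          f"{top['n_identifications_made']} identifications")


if __name__ == "__main__":
    main()
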