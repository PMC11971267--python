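"""Centrality and bridge centrality of the estimated skill network.

Strength sums absolute edge weights; closeness and betweenness use
Dijkstra shortest paths on lengths 1/|weight|; the bridge variants
restrict each statistic to the locomotor / ball-skill community boundary.
The designated hub skills (running, two-hand catching) should dominate
bridge strength.
"""
import skillnet as sn

spec = sn.default_skill_spec()
panel = sn.sample_panel(spec, 5000, seed=1)
fit = sn.select_network(panel)

G = sn.NetworkGraph(W=fit.W, labels=fit.labels,
                    community_of=dict(panel.community_of))
table = sn.centrality_table(G)
print(table.round(3).to_string())

top = table["bridge_strength"].nlargest(2)
print(f"\ntop bridge strength: {list(top.index)} (designated hubs: "
      f"{list(spec.hub_nodes)})")
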