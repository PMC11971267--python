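"""Readers and writers for all pipeline artifacts (UTF-8 text formats).

Panels are CSV (``id,age_group,sex,<skill columns>``); networks are TSV
edge lists (nonzero edges, i < j) and GraphML with signed ``weight`` edge
attributes and a ``community`` node attribute; statistic, stability and
comparison tables are TSV.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import NetworkGraph
from .simulate import (
    DEFAULT_COMMUNITIES,
    DEFAULT_SCORE_MAX,
    SKILL_LABELS,
    PrecisionSpec,
    SkillPanel,
)

__all__ = [
    "PanelSchema",
    "read_panel",
    "write_panel",
    "write_edge_list",
    "write_true_edges",
    "write_graphml",
    "write_centrality",
    "write_bootstrap_tables",
    "write_stability",
    "write_cs",
    "write_comparison",
    "write_manifest",
]


class PanelSchema:
    """Column labels, community map and per-skill maxima for panel CSVs."""

    def __init__(self, labels=SKILL_LABELS, community_of=None, score_max=None):
        self.labels = tuple(labels)
        self.community_of = dict(community_of or DEFAULT_COMMUNITIES)
        self.score_max = dict(score_max or DEFAULT_SCORE_MAX)
        for lab in self.labels:
            if lab not in self.community_of or lab not in self.score_max:
                raise ValidationError(f"schema incomplete for column {lab!r}")


def write_panel(panel: SkillPanel, path) -> None:
    df = pd.DataFrame({"id": np.arange(panel.n)})
    df["age_group"] = panel.age_group if panel.age_group is not None else ""
    df["sex"] = panel.sex if panel.sex is not None else ""
    for j, lab in enumerate(panel.labels):
        df[lab] = panel.scores[:, j]
    df.to_csv(path, index=False)


def read_panel(path, schema: PanelSchema | None = None) -> SkillPanel:
    """Read and validate a panel CSV; reject offending rows by number."""
    schema = schema or PanelSchema()
    df = pd.read_csv(path, dtype={"age_group": str, "sex": str})
    unknown = [c for c in df.columns if c not in ("id", "age_group", "sex") and c not in schema.labels]
    if unknown:
        raise ValidationError(f"unknown column(s) in panel file: {unknown}")
    missing = [c for c in schema.labels if c not in df.columns]
    if missing:
        raise ValidationError(f"panel file lacks skill column(s): {missing}")
    bad: list[str] = []
    scores = np.zeros((len(df), len(schema.labels)), dtype=np.int64)
    for j, lab in enumerate(schema.labels):
        col = df[lab]
        if col.isna().any():
            rows = list(df.index[col.isna()])
            bad.append(f"missing values in {lab!r} at rows {rows[:10]}")
            continue
        vals = col.to_numpy()
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            rows = list(df.index[np.mod(vals, 1) != 0])
            bad.append(f"non-integer scores in {lab!r} at rows {rows[:10]}")
            continue
        vals = vals.astype(np.int64)
        out = (vals < 0) | (vals > schema.score_max[lab])
        if out.any():
            rows = list(df.index[out])
            bad.append(
                f"scores outside [0, {schema.score_max[lab]}] in {lab!r} at rows {rows[:10]}"
            )
            continue
        scores[:, j] = vals
    if bad:
        raise ValidationError("invalid panel file: " + "; ".join(bad))
    age = df["age_group"].to_numpy(dtype=object) if "age_group" in df else None
    sex = df["sex"].to_numpy(dtype=object) if "sex" in df else None
    if age is not None and pd.isna(age).all():
        age = None
    if sex is not None and pd.isna(sex).all():
        sex = None
    panel = SkillPanel(
        scores=scores,
        labels=schema.labels,
        community_of=dict(schema.community_of),
        score_max=dict(schema.score_max),
        age_group=age,
        sex=sex,
    )
    panel.validate()
    return panel


def write_edge_list(W: np.ndarray, labels, path) -> None:
    """Nonzero edges, i < j, as ``node_i<TAB>node_j<TAB>pcor``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_i\tnode_j\tpcor\n")
        p = len(labels)
        for i in range(p):
            for j in range(i + 1, p):
                if W[i, j] != 0.0:
                    fh.write(f"{labels[i]}\t{labels[j]}\t{W[i, j]:.10g}\n")


def write_true_edges(spec: PrecisionSpec, path) -> None:
    P = spec.true_pcor
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_i\tnode_j\ttrue_pcor\n")
        for i in range(spec.p):
            for j in range(i + 1, spec.p):
                if abs(P[i, j]) > 1e-12:
                    fh.write(f"{spec.labels[i]}\t{spec.labels[j]}\t{P[i, j]:.10g}\n")


def write_graphml(G: NetworkGraph, path) -> None:
    g = nx.Graph()
    for lab in G.labels:
        g.add_node(lab, community=G.community_of[lab])
    for i in range(G.p):
        for j in range(i + 1, G.p):
            if G.W[i, j] != 0.0:
                g.add_edge(G.labels[i], G.labels[j], weight=float(G.W[i, j]))
    nx.write_graphml(g, path)


def write_centrality(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def write_bootstrap_tables(summary, stat_path, edge_path) -> None:
    summary.stat_table().to_csv(stat_path, sep="\t", index=False, float_format="%.10g")
    summary.edge_table().to_csv(edge_path, sep="\t", index=False, float_format="%.10g")


def write_stability(profile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cs(cs: dict, path, acceptability: float = 0.25) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("statistic\tcs\tacceptable\n")
        for stat, v in cs.items():
            fh.write(f"{stat}\t{v:g}\t{str(v > acceptability).lower()}\n")


def write_comparison(comp, path) -> None:
    df = comp.table.copy()
    df.insert(0, "marker", np.where(df["differs"], comp.marker, ""))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, config_dict: dict, stages: dict, version: str) -> Path:
    """JSON manifest: config, seed, version, stage status, file hashes."""
    outdir = Path(outdir)
    files = sorted(
        str(f.relative_to(outdir))
        for f in outdir.rglob("*")
        if f.is_file() and f.name != "manifest.json"
    )
    manifest = {
        "package": "skillnet",
        "version": version,
        "config": config_dict,
        "stages": stages,
        "files": {f: _sha256(outdir / f) for f in files},
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
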