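"""Stratified end-to-end pipeline: estimate, describe, bootstrap, compare.

For the pooled sample and each stratum (age groups, optionally sexes) the
pipeline runs: network selection (EBIC glasso) -> centrality table ->
nonparametric bootstrap -> case-dropping stability with CS coefficients;
then compares age strata by CI overlap.  All artifacts are written to the
output directory and listed, content-hashed, in a JSON manifest; a rerun
with the same config and seed reproduces the outputs byte for byte (the
manifest records no wall-clock values).
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import compare_all
from .errors import ValidationError
from .ggm import select_network
from .io import (
    PanelSchema,
    read_panel,
    write_bootstrap_tables,
    write_centrality,
    write_comparison,
    write_cs,
    write_edge_list,
    write_graphml,
    write_manifest,
    write_panel,
    write_stability,
    write_true_edges,
)
from .metrics import NetworkGraph, centrality_table
from .resampling import (
    DEFAULT_DROP_PROPORTIONS,
    case_drop_bootstrap,
    nonparametric_bootstrap,
)
from .simulate import (
    AGE_GROUPS,
    DEFAULT_CONNECTIVITY_SCALES,
    DEFAULT_GROUP_SIZES,
    concat_panels,
    default_skill_spec,
    make_study_panels,
)

log = logging.getLogger("skillnet")

_CONFIG_KEYS = {
    "input",
    "synthetic",
    "stratify_by",
    "gamma",
    "nlambda",
    "min_ratio",
    "B",
    "B_per_level",
    "drop_proportions",
    "ci_level",
    "cs_threshold",
    "cs_confidence",
    "seed",
    "outdir",
}
_SYNTH_KEYS = {"group_sizes", "connectivity_scales", "sex_split", "spec_seed"}


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int
    outdir: str
    input: str | None = None  # panel CSV; None -> synthetic study
    synthetic: dict = field(default_factory=dict)
    stratify_by: tuple[str, ...] = ("age_group",)
    gamma: float = 0.25
    nlambda: int = 100
    min_ratio: float = 0.01
    B: int = 1000
    B_per_level: int = 250
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    ci_level: float = 0.95
    cs_threshold: float = 0.70
    cs_confidence: float = 0.95

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory (no wall-clock default)")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must be in (0, 1)")
        unknown = set(self.synthetic) - _SYNTH_KEYS
        if unknown:
            raise ValidationError(f"unknown synthetic config key(s): {sorted(unknown)}")
        bad = [s for s in self.stratify_by if s not in ("age_group", "sex")]
        if bad:
            raise ValidationError(f"cannot stratify by {bad}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update(overrides)
        if "stratify_by" in raw and raw["stratify_by"] is not None:
            raw["stratify_by"] = tuple(raw["stratify_by"])
        if "drop_proportions" in raw and raw["drop_proportions"] is not None:
            raw["drop_proportions"] = tuple(float(q) for q in raw["drop_proportions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stratify_by"] = list(self.stratify_by)
        d["drop_proportions"] = [float(q) for q in self.drop_proportions]
        # the manifest lives inside outdir; recording the absolute path
        # would make otherwise-identical runs differ byte-wise
        d.pop("outdir")
        return d


def _child_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=master, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def _load_panels(config: RunConfig, outdir: Path):
    """Pooled panel plus strata panels, from file or the synthetic study."""
    if config.input is not None:
        pooled = read_panel(config.input)
        spec = None
    else:
        synth = config.synthetic
        spec = default_skill_spec(seed=int(synth.get("spec_seed", 7)))
        panels = make_study_panels(
            spec,
            group_sizes=synth.get("group_sizes"),
            connectivity_scales=synth.get("connectivity_scales"),
            sex_split=float(synth.get("sex_split", 0.51)),
            seed=_child_seed(config.seed, 0),
        )
        pooled = concat_panels(panels.values())
        write_panel(pooled, outdir / "panel.csv")
        write_true_edges(spec, outdir / "true_edges.tsv")
    strata = {"all": pooled}
    if "age_group" in config.stratify_by and pooled.age_group is not None:
        for g in sorted(set(pooled.age_group)):
            if g:
                strata[str(g)] = pooled.subset(pooled.age_group == g)
    if "sex" in config.stratify_by and pooled.sex is not None:
        for s in sorted(set(pooled.sex)):
            if s:
                strata[f"sex_{s}"] = pooled.subset(pooled.sex == s)
    return spec, strata


def run_pipeline(config: RunConfig) -> dict:
    """Run the full stratified analysis; returns the run report (manifest)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    t_start = time.perf_counter()
    spec, strata = _load_panels(config, outdir)
    stages["load"] = "ok"
    summaries = {}
    results = {}
    for k, (name, panel) in enumerate(strata.items(), start=1):
        t0 = time.perf_counter()
        if panel.n <= panel.p:
            log.warning("stratum=%s n=%d <= p=%d; skipped", name, panel.n, panel.p)
            stages[f"stratum:{name}"] = "skipped (n <= p)"
            continue
        sdir = outdir / name
        sdir.mkdir(exist_ok=True)
        fit = select_network(
            panel, gamma=config.gamma, nlambda=config.nlambda, min_ratio=config.min_ratio
        )
        G = NetworkGraph(W=fit.W, labels=fit.labels, community_of=dict(panel.community_of))
        table = centrality_table(G)
        write_edge_list(fit.W, fit.labels, sdir / "network_edges.tsv")
        write_graphml(G, sdir / "network.graphml")
        write_centrality(table, sdir / "centrality.tsv")
        log.info("stage=fit stratum=%s n=%d edges=%d elapsed=%.2fs",
                 name, panel.n, fit.edge_count, time.perf_counter() - t0)

        t0 = time.perf_counter()
        boot = nonparametric_bootstrap(
            panel,
            B=config.B,
            gamma=config.gamma,
            level=config.ci_level,
            seed=_child_seed(config.seed, 10 + k),
            nlambda=config.nlambda,
            min_ratio=config.min_ratio,
        )
        write_bootstrap_tables(boot, sdir / "bootstrap_stats.tsv", sdir / "bootstrap_edges.tsv")
        summaries[name] = boot
        log.info("stage=bootstrap stratum=%s B=%d failed=%d elapsed=%.2fs",
                 name, config.B, boot.n_failed, time.perf_counter() - t0)

        t0 = time.perf_counter()
        profile = case_drop_bootstrap(
            panel,
            drop_proportions=config.drop_proportions,
            B_per_level=config.B_per_level,
            gamma=config.gamma,
            seed=_child_seed(config.seed, 100 + k),
            nlambda=config.nlambda,
            min_ratio=config.min_ratio,
            threshold=config.cs_threshold,
            confidence=config.cs_confidence,
        )
        cs = profile.cs()
        write_stability(profile, sdir / "stability.tsv")
        write_cs(cs, sdir / "cs.tsv")
        results[name] = {"fit": fit, "centrality": table, "bootstrap": boot,
                         "stability": profile, "cs": cs}
        log.info("stage=stability stratum=%s elapsed=%.2fs", name, time.perf_counter() - t0)
        stages[f"stratum:{name}"] = "ok"

    age_strata = {k: v for k, v in summaries.items() if k in AGE_GROUPS}
    comparisons = compare_all(age_strata) if len(age_strata) >= 2 else []
    sex_strata = {k.removeprefix("sex_"): v for k, v in summaries.items() if k.startswith("sex_")}
    if len(sex_strata) == 2:
        names = sorted(sex_strata)
        comparisons += compare_all(sex_strata, pairs=[(names[0], names[1])])
    for comp in comparisons:
        write_comparison(
            comp, outdir / f"compare_{comp.group_a}_vs_{comp.group_b}.tsv".replace("/", "-")
        )
    stages["compare"] = f"ok ({len(comparisons)} pairs)"
    log.info("stage=compare pairs=%d elapsed_total=%.2fs",
             len(comparisons), time.perf_counter() - t_start)

    write_manifest(outdir, config.to_dict(), stages, __version__)
    return {"stages": stages, "strata": results, "comparisons": comparisons,
            "outdir": str(outdir)}
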