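"""Bootstrap accuracy and case-dropping stability of network statistics.

Accuracy: nonparametric bootstrap — resample rows with replacement,
re-estimate the whole network (EBIC glasso) and all centralities, and
summarize each edge weight and each (statistic, node) cell by its
replicate mean and percentile confidence interval.

Stability: case-dropping subset bootstrap — for an increasing grid of
drop proportions, repeatedly re-estimate on row subsets drawn without
replacement and correlate each subsample's per-node statistic vector with
the full-sample vector.  The correlation stability coefficient
CS(cor = 0.70) is the largest drop proportion at which the empirical 5th
percentile of those correlations still reaches 0.70 (qualification is
monotone: every smaller tabulated proportion must also pass).  CS above
0.25 is conventionally read as acceptable stability.

Replicate r always uses a deterministic child seed derived from
(seed, r), so results are identical regardless of execution order.
Replicates whose estimation fails are recorded and excluded; more than
10% failures aborts with a diagnostic.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BootstrapError, SkillnetError, ValidationError
from .ggm import select_network
from .metrics import STATISTICS, NetworkGraph, centrality_table
from .simulate import SkillPanel

__all__ = [
    "BootstrapSummary",
    "StabilityProfile",
    "nonparametric_bootstrap",
    "percentile_interval",
    "case_drop_bootstrap",
    "cs_coefficient",
    "DEFAULT_DROP_PROPORTIONS",
]

DEFAULT_DROP_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))
MAX_FAILURE_FRACTION = 0.10


def _child_rng(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))


def percentile_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Linear-interpolation percentile CI at the given coverage level."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValidationError("percentile interval of an empty sample")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [a, 1.0 - a], method="linear")
    return float(lo), float(hi)


@dataclass
class BootstrapSummary:
    """Replicate-level bootstrap record for one panel's network."""

    B: int
    level: float
    seed: int
    labels: tuple[str, ...]
    community_of: dict[str, str]
    stat_samples: dict[str, np.ndarray]  # statistic -> (B_ok, p)
    edge_samples: np.ndarray  # (B_ok, p*(p-1)/2), upper-triangle order
    sample_stats: pd.DataFrame  # statistics of the original (non-bootstrap) sample
    sample_W: np.ndarray
    n_failed: int = 0

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def edge_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.labels[i], self.labels[j])
            for i in range(self.p)
            for j in range(i + 1, self.p)
        ]

    def stat_table(self) -> pd.DataFrame:
        """Per (statistic, node): replicate mean and percentile CI."""
        rows = []
        for stat in self.stat_samples:
            vals = self.stat_samples[stat]
            for j, lab in enumerate(self.labels):
                lo, hi = percentile_interval(vals[:, j], self.level)
                rows.append(
                    {
                        "statistic": stat,
                        "node": lab,
                        "sample_value": float(self.sample_stats.loc[lab, stat]),
                        "boot_mean": float(vals[:, j].mean()),
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        """Per edge (i < j): replicate mean and percentile CI of the weight."""
        iu = np.triu_indices(self.p, 1)
        rows = []
        for e, (a, b) in enumerate(self.edge_pairs):
            vals = self.edge_samples[:, e]
            lo, hi = percentile_interval(vals, self.level)
            rows.append(
                {
                    "node_i": a,
                    "node_j": b,
                    "sample_value": float(self.sample_W[iu][e]),
                    "boot_mean": float(vals.mean()),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _estimate_all(panel: SkillPanel, gamma: float, nlambda: int, min_ratio: float):
    fit = select_network(panel, gamma=gamma, nlambda=nlambda, min_ratio=min_ratio)
    G = NetworkGraph(W=fit.W, labels=fit.labels, community_of=dict(panel.community_of))
    return fit, centrality_table(G)


def nonparametric_bootstrap(
    panel: SkillPanel,
    B: int = 1000,
    gamma: float = 0.25,
    level: float = 0.95,
    seed: int = 0,
    nlambda: int = 100,
    min_ratio: float = 0.01,
) -> BootstrapSummary:
    """Row-resampling bootstrap of the full estimation pipeline."""
    if B < 2:
        raise ValidationError("B must be >= 2")
    panel.validate()
    fit, table = _estimate_all(panel, gamma, nlambda, min_ratio)
    p = panel.p
    iu = np.triu_indices(p, 1)
    stat_reps: dict[str, list[np.ndarray]] = {s: [] for s in STATISTICS}
    edge_reps: list[np.ndarray] = []
    n_failed = 0
    max_failed = int(math.floor(MAX_FAILURE_FRACTION * B))
    for r in range(B):
        rng = _child_rng(seed, r)
        idx = rng.integers(0, panel.n, size=panel.n)
        try:
            fit_r, table_r = _estimate_all(panel.subset(idx), gamma, nlambda, min_ratio)
        except SkillnetError:
            n_failed += 1
            if n_failed > max_failed:
                raise BootstrapError(
                    f"{n_failed}/{r + 1} bootstrap replicates failed estimation "
                    f"(ceiling {MAX_FAILURE_FRACTION:.0%} of B={B}); "
                    "the panel is too small or too degenerate to resample"
                )
            continue
        edge_reps.append(fit_r.W[iu])
        for s in STATISTICS:
            stat_reps[s].append(table_r[s].to_numpy())
    return BootstrapSummary(
        B=B,
        level=level,
        seed=seed,
        labels=panel.labels,
        community_of=dict(panel.community_of),
        stat_samples={s: np.vstack(stat_reps[s]) for s in STATISTICS},
        edge_samples=np.vstack(edge_reps),
        sample_stats=table,
        sample_W=fit.W,
        n_failed=n_failed,
    )


@dataclass
class StabilityProfile:
    """Case-drop subsample correlations with the full-sample statistics."""

    drop_proportions: tuple[float, ...]
    correlations: dict[str, np.ndarray]  # statistic -> (n_props, B) with NaN = failed
    threshold: float = 0.70
    confidence: float = 0.95
    seed: int = 0

    @property
    def statistics(self) -> tuple[str, ...]:
        return tuple(self.correlations)

    def quantile_by_proportion(self, stat: str) -> np.ndarray:
        """Empirical (1 - confidence) quantile of correlations per proportion."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return np.nanquantile(
                self.correlations[stat], 1.0 - self.confidence, axis=1
            )

    def cs(self) -> dict[str, float]:
        return cs_coefficient(self, self.threshold, self.confidence)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stat in self.statistics:
            q = self.quantile_by_proportion(stat)
            for prop, qv in zip(self.drop_proportions, q):
                rows.append(
                    {"statistic": stat, "proportion": prop, "q05_correlation": qv}
                )
        return pd.DataFrame(rows)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def case_drop_bootstrap(
    panel: SkillPanel,
    drop_proportions=DEFAULT_DROP_PROPORTIONS,
    B_per_level: int = 250,
    gamma: float = 0.25,
    seed: int = 0,
    nlambda: int = 100,
    min_ratio: float = 0.01,
    threshold: float = 0.70,
    confidence: float = 0.95,
    statistics=STATISTICS,
) -> StabilityProfile:
    """Case-dropping subset bootstrap across a grid of drop proportions.

    Proportions whose retained subsample would have <= p rows are skipped
    with a warning.  Failed or degenerate (zero-variance) replicates are
    recorded as NaN correlations and ignored by the CS quantiles.
    """
    panel.validate()
    drop_proportions = tuple(float(q) for q in drop_proportions)
    if any(q < 0 or q >= 1 for q in drop_proportions):
        raise ValidationError("drop proportions must lie in [0, 1)")
    _, full = _estimate_all(panel, gamma, nlambda, min_ratio)
    full_vec = {s: full[s].to_numpy() for s in statistics}
    kept_props = []
    corr: dict[str, list[list[float]]] = {s: [] for s in statistics}
    rep = 0  # global replicate counter -> deterministic child seeds
    for q in drop_proportions:
        m = int(round(panel.n * (1.0 - q)))
        if m <= panel.p:
            warnings.warn(
                f"drop proportion {q:g} retains only {m} rows (<= p={panel.p}); skipped"
            )
            rep += B_per_level
            continue
        kept_props.append(q)
        rows = {s: [] for s in statistics}
        for _ in range(B_per_level):
            rng = _child_rng(seed, rep)
            rep += 1
            idx = rng.choice(panel.n, size=m, replace=False)
            try:
                _, table_r = _estimate_all(panel.subset(idx), gamma, nlambda, min_ratio)
            except SkillnetError:
                for s in statistics:
                    rows[s].append(np.nan)
                continue
            for s in statistics:
                rows[s].append(_safe_corr(table_r[s].to_numpy(), full_vec[s]))
        for s in statistics:
            corr[s].append(rows[s])
    return StabilityProfile(
        drop_proportions=tuple(kept_props),
        correlations={s: np.asarray(corr[s], dtype=float) for s in statistics},
        threshold=threshold,
        confidence=confidence,
        seed=seed,
    )


def cs_coefficient(
    profile: StabilityProfile, threshold: float = 0.70, confidence: float = 0.95
) -> dict[str, float]:
    """Correlation stability coefficient per statistic.

    CS is the largest tabulated drop proportion q such that q and every
    smaller tabulated proportion have their (1 - confidence) correlation
    quantile at or above the threshold; 0 if no proportion qualifies.
    """
    out: dict[str, float] = {}
    props = np.asarray(profile.drop_proportions)
    order = np.argsort(props)
    for stat in profile.statistics:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanquantile(profile.correlations[stat], 1.0 - confidence, axis=1)
        cs = 0.0
        for k in order:
            if np.isnan(q[k]) or q[k] < threshold:
                break
            cs = float(props[k])
        out[stat] = cs
    return out
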