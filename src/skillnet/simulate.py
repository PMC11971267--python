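"""Synthetic TGMD-3-like skill panels with known partial-correlation structure.

The study data this package targets — subject-by-skill integer score
panels from the Test of Gross Motor Development (3rd ed.) — is not openly
available, so every downstream stage (network estimation, centrality,
bootstrap stability, group comparison) is exercised on panels simulated
from a known sparse precision matrix.  The generator encodes the
instrument's structure: 13 skills in two communities (6 Locomotor, 7 Ball
skills), bounded integer scores whose subscale maxima sum to 46 and 54,
cross-community hub skills (running and two-hand catching), age-stratified
samples of realistic size, and network connectivity that weakens with age.

Latent scores are multivariate normal with the specified precision matrix;
observed scores discretize each latent variable into equal-probability
bins on the standard-normal scale, a rank-preserving map so that Pearson
correlations of scores approximate the latent correlations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConstructionError, ValidationError

__all__ = [
    "LOCOMOTOR_SKILLS",
    "BALL_SKILLS",
    "SKILL_LABELS",
    "DEFAULT_SCORE_MAX",
    "DEFAULT_COMMUNITIES",
    "AGE_GROUPS",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_CONNECTIVITY_SCALES",
    "PrecisionSpec",
    "SkillPanel",
    "build_precision_spec",
    "default_skill_spec",
    "sample_panel",
    "make_study_panels",
]

# Canonical node order (the order used in all tabulated outputs):
# six locomotor skills followed by seven ball skills.
LOCOMOTOR_SKILLS = ("run", "gallop", "hop", "skip", "horizontal_jump", "slide")
BALL_SKILLS = (
    "two_hand_strike",
    "forehand_strike",
    "one_hand_dribble",
    "two_hand_catch",
    "kick_stationary_ball",
    "overhand_throw",
    "underhand_throw",
)
SKILL_LABELS = LOCOMOTOR_SKILLS + BALL_SKILLS

# Per-skill maxima; only the subscale totals (46 locomotor, 54 ball) are
# fixed by the instrument, the split across skills is configurable.
DEFAULT_SCORE_MAX = {
    "run": 8, "gallop": 8, "hop": 8, "skip": 8, "horizontal_jump": 6, "slide": 8,
    "two_hand_strike": 10, "forehand_strike": 8, "one_hand_dribble": 8,
    "two_hand_catch": 6, "kick_stationary_ball": 8, "overhand_throw": 8,
    "underhand_throw": 6,
}
DEFAULT_COMMUNITIES = {s: ("Ls" if s in LOCOMOTOR_SKILLS else "Bs") for s in SKILL_LABELS}

AGE_GROUPS = ("3-5", "6-8", "9-11")
DEFAULT_GROUP_SIZES = {"3-5": 3525, "6-8": 7882, "9-11": 5582}
# Connectivity weakens with age: older children's skills decouple as they
# specialize, mirroring the developmental trend in network strength.
DEFAULT_CONNECTIVITY_SCALES = {"3-5": 1.0, "6-8": 0.7, "9-11": 0.5}
DEFAULT_SEX_SPLIT = 0.51  # fraction female

_EIG_FLOOR = 0.05
_LOAD_STEP = 0.05
_MAX_LOAD_STEPS = 100


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PrecisionSpec:
    """Ground-truth precision matrix with community and hub annotations."""

    labels: tuple[str, ...]
    community_of: dict[str, str]
    theta: np.ndarray
    hub_nodes: tuple[str, ...] = ()
    connectivity_scale: float = 1.0

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def true_pcor(self) -> np.ndarray:
        """Implied partial correlations; unit diagonal by convention."""
        d = np.sqrt(np.diag(self.theta))
        P = -self.theta / np.outer(d, d)
        np.fill_diagonal(P, 1.0)
        return P

    def true_edges(self, tol: float = 1e-12) -> set[frozenset[str]]:
        """Unordered label pairs with a nonzero true partial correlation."""
        P = self.true_pcor
        out = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(P[i, j]) > tol:
                    out.add(frozenset((self.labels[i], self.labels[j])))
        return out

    def validate(self) -> None:
        th = self.theta
        p = self.p
        if th.shape != (p, p):
            raise ValidationError(f"theta shape {th.shape} does not match {p} labels")
        if not np.allclose(th, th.T, atol=1e-10):
            raise ValidationError("theta is not symmetric within 1e-10")
        if np.linalg.eigvalsh(th).min() <= 0:
            raise ValidationError("theta is not positive definite")
        missing = [l for l in self.labels if l not in self.community_of]
        if missing:
            raise ValidationError(f"labels without community: {missing}")
        for hub in self.hub_nodes:
            if hub not in self.labels:
                raise ValidationError(f"hub node {hub!r} not among labels")
            i = self.labels.index(hub)
            cross = [
                j for j, l in enumerate(self.labels)
                if self.community_of[l] != self.community_of[hub] and abs(th[i, j]) > 1e-12
            ]
            if not cross:
                raise ValidationError(f"hub node {hub!r} has no cross-community edge")


@dataclass
class SkillPanel:
    """Subject-by-skill integer score matrix with optional strata labels."""

    scores: np.ndarray
    labels: tuple[str, ...]
    community_of: dict[str, str]
    score_max: dict[str, int]
    age_group: np.ndarray | None = None
    sex: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        if self.scores.shape != (self.n, self.p):
            raise ValidationError("scores shape does not match labels")
        if not np.issubdtype(self.scores.dtype, np.integer):
            raise ValidationError("scores must be integers")
        if self.scores.min(initial=0) < 0:
            raise ValidationError("negative score found")
        for j, lab in enumerate(self.labels):
            m = self.score_max[lab]
            if self.scores[:, j].max(initial=0) > m:
                raise ValidationError(f"score above maximum {m} in column {lab!r}")
        for arr, name in ((self.age_group, "age_group"), (self.sex, "sex")):
            if arr is not None and len(arr) != self.n:
                raise ValidationError(f"{name} length does not match n")

    def subset(self, mask: np.ndarray) -> "SkillPanel":
        """Row subset (boolean mask or integer index array)."""
        return SkillPanel(
            scores=self.scores[mask],
            labels=self.labels,
            community_of=self.community_of,
            score_max=self.score_max,
            age_group=None if self.age_group is None else self.age_group[mask],
            sex=None if self.sex is None else self.sex[mask],
        )

    def to_dataframe(self):
        import pandas as pd

        data = {}
        if self.age_group is not None:
            data["age_group"] = self.age_group
        if self.sex is not None:
            data["sex"] = self.sex
        for j, lab in enumerate(self.labels):
            data[lab] = self.scores[:, j]
        return pd.DataFrame(data)


def _load_to_pd(theta: np.ndarray) -> np.ndarray:
    """Add to the diagonal in fixed steps until min eigenvalue >= floor."""
    th = theta.copy()
    for _ in range(_MAX_LOAD_STEPS):
        if np.linalg.eigvalsh(th).min() >= _EIG_FLOOR:
            return th
        th[np.diag_indices_from(th)] += _LOAD_STEP
    raise ConstructionError(
        f"could not reach positive definiteness in {_MAX_LOAD_STEPS} loading steps"
    )


def build_precision_spec(
    p: int,
    community_sizes: tuple[int, int],
    within_density: float,
    cross_edges: list[tuple] = (),
    hub_nodes: set[str] | tuple[str, ...] = (),
    weight_range: tuple[float, float] = (0.15, 0.30),
    connectivity_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    labels: tuple[str, ...] | None = None,
    community_names: tuple[str, str] = ("Ls", "Bs"),
    neg_prob: float = 0.1,
) -> PrecisionSpec:
    """Construct a sparse two-community precision matrix.

    Within-community edges are placed independently with probability
    ``within_density``; cross-community edges are placed exactly at the
    requested pairs (each either ``(a, b)``, drawing its weight, or
    ``(a, b, w)`` with an explicit signed weight).  Edge "weights" here are
    the magnitudes of the off-diagonal precision entries before diagonal
    loading; loading to min eigenvalue >= 0.05 shrinks the implied partial
    correlations uniformly.  Every hub node is guaranteed at least two
    cross-community partners (randomly added if the requested cross edges
    provide fewer).
    """
    if sum(community_sizes) != p:
        raise ValidationError("community sizes must sum to p")
    if not (0.0 <= within_density <= 1.0):
        raise ValidationError("within_density must be in [0, 1]")
    lo, hi = weight_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValidationError("weight_range must lie within (0, 1)")
    if connectivity_scale <= 0:
        raise ValidationError("connectivity_scale must be positive")
    rng = _as_rng(seed)

    if labels is None:
        labels = tuple(
            f"{community_names[0]}{i + 1}" for i in range(community_sizes[0])
        ) + tuple(f"{community_names[1]}{i + 1}" for i in range(community_sizes[1]))
    if len(labels) != p:
        raise ValidationError("labels length must equal p")
    community_of = {
        lab: (community_names[0] if i < community_sizes[0] else community_names[1])
        for i, lab in enumerate(labels)
    }
    idx = {lab: i for i, lab in enumerate(labels)}
    hub_nodes = tuple(hub_nodes)
    for hub in hub_nodes:
        if hub not in idx:
            raise ValidationError(f"hub node {hub!r} not among labels")

    def draw_weight():
        w = rng.uniform(lo, hi)
        if rng.random() < neg_prob:
            w = -w
        return w

    O = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if community_of[labels[i]] == community_of[labels[j]]:
                if rng.random() < within_density:
                    O[i, j] = O[j, i] = draw_weight()
    for edge in cross_edges:
        a, b = edge[0], edge[1]
        if a not in idx or b not in idx:
            raise ValidationError(f"cross edge ({a!r}, {b!r}) names unknown nodes")
        w = edge[2] if len(edge) > 2 else draw_weight()
        O[idx[a], idx[b]] = O[idx[b], idx[a]] = w

    # guarantee hubs >= 2 cross-community partners
    for hub in hub_nodes:
        i = idx[hub]
        others = [
            j for j, l in enumerate(labels) if community_of[l] != community_of[hub]
        ]
        existing = [j for j in others if O[i, j] != 0.0]
        need = 2 - len(existing)
        if need > 0:
            free = [j for j in others if O[i, j] == 0.0]
            for j in rng.choice(free, size=need, replace=False):
                O[i, j] = O[j, i] = abs(draw_weight())

    theta = _load_to_pd(np.eye(p) - connectivity_scale * O)
    spec = PrecisionSpec(
        labels=labels,
        community_of=community_of,
        theta=theta,
        hub_nodes=hub_nodes,
        connectivity_scale=float(connectivity_scale),
    )
    spec.validate()
    return spec


# Hand-designed cross-community edges for the canonical 13-skill spec.
# Running and two-hand catching are the designated bridges between the
# locomotor and ball-skill communities, so they carry the largest
# cross-community weight totals by construction.
_DEFAULT_CROSS_EDGES = [
    ("run", "two_hand_catch", 0.22),
    ("run", "two_hand_strike", 0.18),
    ("run", "one_hand_dribble", 0.16),
    ("two_hand_catch", "gallop", 0.18),
    ("two_hand_catch", "hop", 0.16),
    ("slide", "underhand_throw", 0.15),
]


def default_skill_spec(seed: int = 7) -> PrecisionSpec:
    """The canonical 13-skill two-community spec used throughout.

    Within-community density 0.4, true-edge magnitudes >= 0.1 after
    loading, hubs run / two-hand catch dominating cross-community
    strength.  The seed fixes the randomly placed within-community edges;
    the cross-community backbone is fixed by design.
    """
    spec = build_precision_spec(
        p=13,
        community_sizes=(6, 7),
        within_density=0.4,
        cross_edges=_DEFAULT_CROSS_EDGES,
        hub_nodes=("run", "two_hand_catch"),
        weight_range=(0.15, 0.30),
        seed=seed,
        labels=SKILL_LABELS,
    )
    P = spec.true_pcor.copy()
    np.fill_diagonal(P, 0.0)
    min_edge = np.abs(P[np.abs(P) > 1e-12]).min()
    if min_edge < 0.1:
        raise ConstructionError(
            f"default spec edge magnitude {min_edge:.3f} below 0.1; adjust seed/design"
        )
    return spec


def sample_panel(
    spec: PrecisionSpec,
    n: int,
    score_max: dict[str, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> SkillPanel:
    """Draw an integer score panel from the spec's Gaussian model.

    Latents are zero-mean Gaussian with precision ``spec.theta``; each
    column is standardized and cut into ``score_max + 1`` equal-probability
    bins of the standard normal, a monotone map onto 0..score_max.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if score_max is None:
        score_max = (
            dict(DEFAULT_SCORE_MAX)
            if set(spec.labels) == set(SKILL_LABELS)
            else {lab: 8 for lab in spec.labels}
        )
    for lab in spec.labels:
        m = score_max.get(lab)
        if m is None or int(m) < 1:
            raise ValidationError(f"score_max for {lab!r} must be a positive integer")
    rng = _as_rng(seed)
    sigma = np.linalg.inv(spec.theta)
    L = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, spec.p)) @ L.T
    z /= np.sqrt(np.diag(sigma))
    scores = np.empty((n, spec.p), dtype=np.int64)
    for j, lab in enumerate(spec.labels):
        m = int(score_max[lab])
        cuts = stats.norm.ppf(np.arange(1, m + 1) / (m + 1))
        scores[:, j] = np.searchsorted(cuts, z[:, j])
    panel = SkillPanel(
        scores=scores,
        labels=spec.labels,
        community_of=dict(spec.community_of),
        score_max={lab: int(score_max[lab]) for lab in spec.labels},
    )
    panel.validate()
    return panel


def scale_spec(spec: PrecisionSpec, scale: float) -> PrecisionSpec:
    """Multiply off-diagonal precision structure by ``scale`` (re-loaded to PD)."""
    if scale <= 0:
        raise ValidationError("connectivity scale must be positive")
    th = spec.theta.copy()
    d = np.diag(th).copy()
    th *= scale
    th[np.diag_indices_from(th)] = d
    th = _load_to_pd(th)
    return PrecisionSpec(
        labels=spec.labels,
        community_of=dict(spec.community_of),
        theta=th,
        hub_nodes=spec.hub_nodes,
        connectivity_scale=spec.connectivity_scale * scale,
    )


def make_study_panels(
    base_spec: PrecisionSpec,
    group_sizes: dict[str, int] | None = None,
    connectivity_scales: dict[str, float] | None = None,
    sex_split: float = DEFAULT_SEX_SPLIT,
    seed: int = 0,
    score_max: dict[str, int] | None = None,
) -> dict[str, SkillPanel]:
    """One panel per age group, sharing structure but weakening with age.

    Off-diagonal precision entries are multiplied by the group's
    connectivity scale (default 1.0 / 0.7 / 0.5 for ages 3-5 / 6-8 / 9-11),
    so estimated network strength declines across strata.  Rows carry
    ``age_group`` and a Bernoulli(``sex_split``) female indicator.  Each
    group consumes an independent child stream of the master seed, so
    group panels are reproducible independently of one another.
    """
    if group_sizes is None:
        group_sizes = dict(DEFAULT_GROUP_SIZES)
    if connectivity_scales is None:
        connectivity_scales = dict(DEFAULT_CONNECTIVITY_SCALES)
    if not (0.0 < sex_split < 1.0):
        raise ValidationError("sex_split must be in (0, 1)")
    for g in group_sizes:
        if g not in connectivity_scales:
            raise ValidationError(f"no connectivity scale for age group {g!r}")
    for g, s in connectivity_scales.items():
        if g not in group_sizes and g not in AGE_GROUPS:
            raise ValidationError(f"unknown age group {g!r}")
        if s <= 0:
            raise ValidationError("connectivity scales must be positive")

    groups = list(group_sizes)
    children = np.random.SeedSequence(seed).spawn(len(groups))
    panels: dict[str, SkillPanel] = {}
    for g, child in zip(groups, children):
        rng = np.random.default_rng(child)
        spec_g = scale_spec(base_spec, float(connectivity_scales[g]))
        panel = sample_panel(spec_g, int(group_sizes[g]), score_max=score_max, seed=rng)
        panel.age_group = np.full(panel.n, g, dtype=object)
        panel.sex = np.where(rng.random(panel.n) < sex_split, "F", "M").astype(object)
        panels[g] = panel
    return panels


def concat_panels(panels) -> SkillPanel:
    """Stack panels (same labels/schema) into one pooled panel."""
    panels = list(panels)
    first = panels[0]
    for pnl in panels[1:]:
        if pnl.labels != first.labels:
            raise ValidationError("panels have different labels")
    return SkillPanel(
        scores=np.vstack([pnl.scores for pnl in panels]),
        labels=first.labels,
        community_of=dict(first.community_of),
        score_max=dict(first.score_max),
        age_group=np.concatenate([
            pnl.age_group if pnl.age_group is not None else np.full(pnl.n, "", dtype=object)
            for pnl in panels
        ]),
        sex=np.concatenate([
            pnl.sex if pnl.sex is not None else np.full(pnl.n, "", dtype=object)
            for pnl in panels
        ]),
    )
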