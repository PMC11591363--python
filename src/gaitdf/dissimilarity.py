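"""Dissimilarity factor (DF) between normalized step curves and group stats.

For two normalized curves a and b with bins i = 1..n (n = 100 by default),

    DF(a, b) = (1/2n) * [ sum_i (x_a(i) - x_b(i))^2 + sum_i (y_a(i) - y_b(i))^2 ]

i.e. the mean squared per-bin difference pooled over the horizontal and
vertical components (the 1/200 prefactor for 100 bins x 2 axes).  DF is
symmetric, non-negative, and zero iff the curves coincide on every bin.
``metric="rmsd"`` returns the square root for users who prefer a distance
in cm.

Group comparison follows a fixed pairing scheme: every experimental step
curve is paired with every control step curve of the same (side, joint,
day) stratum; the control group's own reference distribution pairs control
curves across distinct animals only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    ShapeError,
    StratificationError,
    UnitError,
)
from .normalize import NormalizedStepCurve

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance annotation for an (adjusted) p-value."""
    for thr, s in STAR_THRESHOLDS:
        if p <= thr:
            return s
    return ""


@dataclass(frozen=True)
class DFValue:
    df: float
    curve_a: tuple
    curve_b: tuple


@dataclass
class DFMatrix:
    """All pairwise DF values between two curve collections."""

    group_a: str
    group_b: str
    values: list[DFValue]
    scheme: str  # "cross_group" | "control_baseline"

    def df_array(self) -> np.ndarray:
        return np.array([v.df for v in self.values], dtype=np.float64)

    @property
    def mean(self) -> float:
        return float(self.df_array().mean()) if self.values else float("nan")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str


@dataclass
class GroupStatsResult:
    method: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def _check_pairable(a: NormalizedStepCurve, b: NormalizedStepCurve) -> None:
    if a.n_bins != b.n_bins:
        raise ShapeError(f"bin count mismatch: {a.n_bins} vs {b.n_bins}")
    if a.units != b.units:
        raise UnitError(f"unit mismatch: {a.units!r} vs {b.units!r}")


def df_pair(
    a: NormalizedStepCurve, b: NormalizedStepCurve, metric: str = "squared"
) -> DFValue:
    """DF between two curves; symmetric in its arguments."""
    _check_pairable(a, b)
    n = a.n_bins
    val = (np.sum((a.x - b.x) ** 2) + np.sum((a.y - b.y) ** 2)) / (2.0 * n)
    if metric == "rmsd":
        val = np.sqrt(val)
    elif metric != "squared":
        raise ValueError(f"unknown metric {metric!r}")
    return DFValue(df=float(val), curve_a=a.keys, curve_b=b.keys)


def _df_block(
    ax: np.ndarray, ay: np.ndarray, bx: np.ndarray, by: np.ndarray, metric: str
) -> np.ndarray:
    """Vectorized DF for all pairs of stacked curves: (na, nb) result."""
    n = ax.shape[1]
    dx = ax[:, None, :] - bx[None, :, :]
    dy = ay[:, None, :] - by[None, :, :]
    out = (np.einsum("abi,abi->ab", dx, dx) + np.einsum("abi,abi->ab", dy, dy)) / (2.0 * n)
    if metric == "rmsd":
        out = np.sqrt(out)
    return out


def _stack(curves: Sequence[NormalizedStepCurve]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.stack([c.x for c in curves]),
        np.stack([c.y for c in curves]),
    )


def _check_stratum(curves: Sequence[NormalizedStepCurve], label: str) -> tuple:
    strata = {c.stratum for c in curves}
    if len(strata) > 1:
        raise StratificationError(
            f"{label} curves span multiple (side, joint, day) strata: {sorted(strata)}"
        )
    return next(iter(strata))


def df_cross_group(
    exp_curves: Sequence[NormalizedStepCurve],
    ctrl_curves: Sequence[NormalizedStepCurve],
    metric: str = "squared",
) -> DFMatrix:
    """Pair every experimental curve with every control curve of one stratum."""
    if not exp_curves or not ctrl_curves:
        logger.warning("empty stratum in cross-group DF; returning empty matrix")
        ga = exp_curves[0].group if exp_curves else "?"
        gb = ctrl_curves[0].group if ctrl_curves else "?"
        return DFMatrix(group_a=ga, group_b=gb, values=[], scheme="cross_group")
    sa = _check_stratum(exp_curves, "experimental")
    sb = _check_stratum(ctrl_curves, "control")
    if sa != sb:
        raise StratificationError(f"cross-stratum pairing requested: {sa} vs {sb}")
    for c in ctrl_curves:
        _check_pairable(exp_curves[0], c)
    ax, ay = _stack(exp_curves)
    bx, by = _stack(ctrl_curves)
    block = _df_block(ax, ay, bx, by, metric)
    values = [
        DFValue(df=float(block[i, j]), curve_a=a.keys, curve_b=b.keys)
        for i, a in enumerate(exp_curves)
        for j, b in enumerate(ctrl_curves)
    ]
    return DFMatrix(
        group_a=exp_curves[0].group,
        group_b=ctrl_curves[0].group,
        values=values,
        scheme="cross_group",
    )


def df_baseline(
    ctrl_curves: Sequence[NormalizedStepCurve], metric: str = "squared"
) -> DFMatrix:
    """Control reference distribution: pairs across distinct animals only.

    Each unordered pair of curves from two different control animals is
    counted once; same-animal and self pairs are excluded.
    """
    by_animal: dict[str, list[NormalizedStepCurve]] = {}
    for c in ctrl_curves:
        by_animal.setdefault(c.animal_id, []).append(c)
    if len(by_animal) < 2:
        raise InsufficientDataError(
            f"baseline DF needs >= 2 control animals, got {len(by_animal)}"
        )
    _check_stratum(ctrl_curves, "control")
    values: list[DFValue] = []
    animals = sorted(by_animal)
    for a1, a2 in combinations(animals, 2):
        ax, ay = _stack(by_animal[a1])
        bx, by_ = _stack(by_animal[a2])
        block = _df_block(ax, ay, bx, by_, metric)
        values.extend(
            DFValue(df=float(block[i, j]), curve_a=ca.keys, curve_b=cb.keys)
            for i, ca in enumerate(by_animal[a1])
            for j, cb in enumerate(by_animal[a2])
        )
    group = ctrl_curves[0].group
    return DFMatrix(group_a=group, group_b=group, values=values, scheme="control_baseline")


def animal_mean_df(mat: DFMatrix) -> dict[str, float]:
    """Mean DF per first-argument animal — the animal-level statistical unit.

    Pair-level DF values that share curves are not independent; averaging
    within animal yields one value per animal, the unit under which group
    tests hold their nominal level.
    """
    per_animal: dict[str, list[float]] = {}
    for v in mat.values:
        per_animal.setdefault(str(v.curve_a[0]), []).append(v.df)
    return {a: float(np.mean(vals)) for a, vals in sorted(per_animal.items())}


def percent_difference(
    mean_exp: float, mean_ref: float, denominator: str = "experimental"
) -> float:
    """Percent by which the reference mean falls below the experimental mean.

    With the default denominator, "group E differs d% from group R" means
    the reference mean is d% below the experimental mean:
    100 * (mean_exp - mean_ref) / mean_exp.  ``denominator="reference"``
    uses mean_ref instead.
    """
    if denominator == "experimental":
        denom = mean_exp
    elif denominator == "reference":
        denom = mean_ref
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise InsufficientDataError(f"percent difference needs a positive denominator, got {denom}")
    return 100.0 * (mean_exp - mean_ref) / denom


def _dunn_pairwise(groups: Mapping[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based post hoc z-tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum over tie groups of (t^3 - t); two-sided normal p-values.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    pos = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = float(ranks[pos : pos + n].mean())
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out = []
    for g1, g2 in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((g1, g2, float(z), float(p)))
    return out


def group_stats(
    df_by_group: Mapping[str, Sequence[float] | np.ndarray],
    method: str = "anova_bonferroni",
    restrict_pairs: Iterable[tuple[str, str]] | None = None,
) -> GroupStatsResult:
    """Omnibus test plus Bonferroni-adjusted pairwise comparisons.

    ``anova_bonferroni``: one-way ANOVA, then two-sample t-tests;
    ``kruskal_dunn``: Kruskal-Wallis, then Dunn's rank z-tests.  The
    Bonferroni family is the set of pairwise comparisons actually run.
    """
    groups = {g: np.asarray(v, dtype=np.float64) for g, v in df_by_group.items()}
    if len(groups) < 2:
        raise InsufficientDataError(f"need >= 2 groups, got {len(groups)}")
    for g, v in groups.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {g!r} has {v.size} values; need >= 2")

    means = {g: float(v.mean()) for g, v in groups.items()}
    sems = {g: float(sps.sem(v)) for g, v in groups.items()}
    ns = {g: int(v.size) for g, v in groups.items()}

    if restrict_pairs is None:
        pairs = list(combinations(groups, 2))
    else:
        pairs = [tuple(p) for p in restrict_pairs]
    m = len(pairs)

    if method == "anova_bonferroni":
        stat, p_omni = sps.f_oneway(*groups.values())
        pairwise = []
        for g1, g2 in pairs:
            t, p = sps.ttest_ind(groups[g1], groups[g2], equal_var=True)
            p_adj = min(1.0, float(p) * m)
            pairwise.append(
                PairwiseComparison(g1, g2, float(t), float(p), p_adj, stars(p_adj))
            )
    elif method == "kruskal_dunn":
        stat, p_omni = sps.kruskal(*groups.values())
        wanted = set(pairs)
        pairwise = []
        for g1, g2, z, p in _dunn_pairwise(groups):
            if (g1, g2) not in wanted and (g2, g1) not in wanted:
                continue
            p_adj = min(1.0, p * m)
            pairwise.append(PairwiseComparison(g1, g2, z, p, p_adj, stars(p_adj)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return GroupStatsResult(
        method=method,
        group_means=means,
        group_sems=sems,
        group_ns=ns,
        omnibus_statistic=float(stat),
        omnibus_p=float(p_omni),
        pairwise=pairwise,
    )
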