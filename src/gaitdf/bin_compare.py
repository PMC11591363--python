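"""Per-bin comparison of displacement curves between groups.

This is one-dimensional statistical parametric mapping in its simplest
form: an independent two-sample t-test at each of the 100 cycle bins,
flagged where p <= alpha.  No correction is applied across bins by default
(``correction="bonferroni"`` or ``"fdr"`` are available); the percent of
flagged bins is the "% of the step cycle differing" reporting unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ShapeError
from .normalize import NormalizedStepCurve

COMPONENTS = ("VD", "HD")


def component_matrix(
    curves: Sequence[NormalizedStepCurve], component: str
) -> np.ndarray:
    """Stack one displacement component of many curves into (n_curves, n_bins)."""
    if component == "VD":
        return np.stack([c.y for c in curves])
    if component == "HD":
        return np.stack([c.x for c in curves])
    raise ValueError(f"unknown component {component!r}; expected VD or HD")


def animal_mean_matrix(
    curves: Sequence[NormalizedStepCurve], component: str
) -> np.ndarray:
    """Per-animal mean curves stacked into (n_animals, n_bins).

    Step curves of one animal are correlated (shared animal-level gait);
    averaging within animal before a between-group test removes the
    pseudo-replication that curve-level testing incurs.
    """
    mat = component_matrix(curves, component)
    animals = sorted({c.animal_id for c in curves})
    idx = {a: i for i, a in enumerate(animals)}
    out = np.zeros((len(animals), mat.shape[1]))
    counts = np.zeros(len(animals))
    for row, c in zip(mat, curves):
        out[idx[c.animal_id]] += row
        counts[idx[c.animal_id]] += 1
    return out / counts[:, None]


def _as_matrix(curves, component: str | None) -> np.ndarray:
    if isinstance(curves, np.ndarray):
        return np.atleast_2d(curves)
    if component is None:
        raise ValueError("component must be given when passing curve objects")
    return component_matrix(curves, component)


@dataclass
class MeanCurve:
    """Per-bin mean and SEM of one group's curves for one component."""

    group: str
    component: str
    stratum: tuple
    mean: np.ndarray
    sem: np.ndarray
    n: int


@dataclass
class BinComparison:
    """Per-bin test results between two groups for one component/stratum."""

    group_a: str
    group_b: str
    component: str
    stratum: tuple
    t: np.ndarray  # (n_bins,)
    p: np.ndarray  # (n_bins,) raw p-values
    flags: np.ndarray  # (n_bins,) bool, significant at alpha (after correction)
    alpha: float

    @property
    def significant_fraction(self) -> float:
        """Percent of cycle bins with a significant between-group difference."""
        return 100.0 * float(self.flags.sum()) / self.flags.size


def mean_curves(
    curves: Sequence[NormalizedStepCurve], component: str
) -> MeanCurve:
    """Arithmetic per-bin mean and SEM over >= 2 curves of one group."""
    if len(curves) < 2:
        raise InsufficientDataError(f"need >= 2 curves to average, got {len(curves)}")
    mat = component_matrix(curves, component)
    return MeanCurve(
        group=curves[0].group,
        component=component,
        stratum=curves[0].stratum,
        mean=mat.mean(axis=0),
        sem=mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]),
        n=mat.shape[0],
    )


def per_bin_ttest(
    group_a,
    group_b,
    alpha: float = 0.05,
    *,
    component: str | None = None,
    variant: str = "student",
    correction: str = "none",
) -> BinComparison:
    """Independent two-sample t-test at every cycle bin.

    Accepts either lists of :class:`NormalizedStepCurve` (with
    ``component``) or pre-stacked (n_curves, n_bins) arrays.  The pooled
    variance Student's t is the default; ``variant="welch"`` drops the
    equal-variance assumption.  Bins where both groups are constant and
    equal get t = 0, p = 1 (no difference, not an error).
    """
    a = _as_matrix(group_a, component)
    b = _as_matrix(group_b, component)
    if a.shape[1] != b.shape[1]:
        raise ShapeError(f"bin count mismatch: {a.shape[1]} vs {b.shape[1]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("each group needs >= 2 curves per bin test")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant bins trigger scipy's catastrophic-cancellation warning;
        # those bins are mapped to t = 0, p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=(variant == "student"))
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0

    if correction == "none":
        p_eff = p
    elif correction == "bonferroni":
        p_eff = np.minimum(1.0, p * p.size)
    elif correction == "fdr":
        p_eff = sps.false_discovery_control(p)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    flags = p_eff <= alpha

    ga = group_a[0].group if not isinstance(group_a, np.ndarray) else "a"
    gb = group_b[0].group if not isinstance(group_b, np.ndarray) else "b"
    stratum = (
        group_a[0].stratum if not isinstance(group_a, np.ndarray) else ()
    )
    return BinComparison(
        group_a=ga,
        group_b=gb,
        component=component or "",
        stratum=stratum,
        t=t,
        p=p,
        flags=flags,
        alpha=alpha,
    )


def significant_fraction_summary(comparisons: Sequence[BinComparison]) -> pd.DataFrame:
    """Tabulate the percent of the step cycle differing, per comparison."""
    rows = []
    for c in comparisons:
        side, joint, day = c.stratum if len(c.stratum) == 3 else ("", "", "")
        rows.append(
            {
                "side": side,
                "joint": joint,
                "day": day,
                "component": c.component,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "significant_fraction_pct": c.significant_fraction,
                "n_flagged_bins": int(c.flags.sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "side",
            "joint",
            "day",
            "component",
            "group_a",
            "group_b",
            "significant_fraction_pct",
            "n_flagged_bins",
        ],
    )


def endpoint_y_average(curves: Sequence[NormalizedStepCurve]) -> tuple[float, float]:
    """Group mean of the vertical component at the first and last cycle bin."""
    if not curves:
        raise InsufficientDataError("endpoint average needs >= 1 curve")
    ys = np.stack([c.y for c in curves])
    return float(ys[:, 0].mean()), float(ys[:, -1].mean())


def flag_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of flagged bins as 1-based inclusive (start, end) pairs."""
    runs = []
    in_run = False
    start = 0
    for i, f in enumerate(flags):
        if f and not in_run:
            in_run, start = True, i
        elif not f and in_run:
            in_run = False
            runs.append((start + 1, i))
    if in_run:
        runs.append((start + 1, len(flags)))
    return runs
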