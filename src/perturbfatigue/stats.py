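"""Within-subject inference, implemented from first principles.

The experimental design is fully within-subjects: every subject is measured
under every combination of one to three crossed factors (e.g. time T1-T4 x
protocol FAT/CON, optionally x reflex phase). For such balanced designs the
repeated-measures ANOVA decomposes the data tensor orthogonally: the sum of
squares of an effect is the squared norm of its mean-difference (Moebius)
term, and each effect is tested against its own interaction with subjects.

Sphericity of an effect's contrast covariance is assessed with Mauchly's W
(chi-square approximation); when it is rejected at alpha = 0.05 the
Greenhouse-Geisser estimate eps of Box's epsilon rescales both degrees of
freedom. When the contrast covariance is singular (too few subjects for the
test) Mauchly is skipped and the correction applied unconditionally.

Also here: Bonferroni multiplication, two-tailed Pearson correlation with
the t-distribution p-value, and the Benjamini-Hochberg-Yekutieli step-up
procedure with the harmonic-sum factor c(m) valid under arbitrary
dependence. All procedures are pure functions of their inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sst

__all__ = [
    "WithinDesignCube",
    "AnovaEffect",
    "CorrelationResult",
    "rm_anova",
    "gg_epsilon",
    "mauchly",
    "bonferroni",
    "pearson",
    "bhy_fdr",
]

MAUCHLY_ALPHA = 0.05


@dataclass
class WithinDesignCube:
    """Subject x factor-level data for a fully crossed within design.

    ``values`` has shape (n_subjects, l_1, ..., l_k) for k factors. Only
    complete cases enter a cube; :meth:`from_long` applies casewise deletion
    (a subject missing any cell is dropped).
    """

    values: np.ndarray
    factor_names: tuple[str, ...]
    level_labels: tuple[tuple, ...]
    subjects: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.factor_names)
        if not 1 <= k <= 3:
            raise ValueError("1 to 3 within-subject factors supported")
        if self.values.ndim != k + 1:
            raise ValueError(
                f"values must have shape (subjects, {k} factor dims), got {self.values.shape}"
            )
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 complete subjects")
        if any(self.values.shape[i + 1] != len(self.level_labels[i]) for i in range(k)):
            raise ValueError("level_labels inconsistent with values shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values (apply casewise deletion first)")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject: str,
        factors: Sequence[str],
        value: str,
    ) -> "WithinDesignCube":
        wide = df.pivot_table(index=subject, columns=list(factors), values=value, aggfunc="mean")
        levels = tuple(tuple(lv) for lv in (wide.columns.levels if len(factors) > 1 else [wide.columns]))
        wide = wide.dropna(axis=0, how="any")  # casewise deletion
        if wide.empty:
            raise ValueError("no complete subjects after casewise deletion")
        shape = (len(wide),) + tuple(len(lv) for lv in levels)
        return cls(
            wide.to_numpy().reshape(shape),
            tuple(factors),
            levels,
            tuple(wide.index),
        )


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    error_ss: float
    error_df: int
    error_ms: float
    F: float
    p_uncorrected: float
    epsilon_gg: float
    p_gg: float
    mauchly_w: float
    mauchly_p: float
    sphericity_applied: bool

    @property
    def p(self) -> float:
        """The reported p-value: Greenhouse-Geisser when applied, else raw."""
        return self.p_gg if self.sphericity_applied else self.p_uncorrected


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float
    fdr_adjusted_p: Optional[float] = None


def _mean_keep(values: np.ndarray, keep: frozenset[int]) -> np.ndarray:
    """Mean over every axis not in ``keep``, with dims kept for broadcasting."""
    axes = tuple(ax for ax in range(values.ndim) if ax not in keep)
    return values.mean(axis=axes, keepdims=True) if axes else values


def _moebius_ss(values: np.ndarray, dims: frozenset[int]) -> float:
    """Sum of squares of the pure interaction term for the axes ``dims``.

    The effect estimate at each cell is the alternating (Moebius) sum of
    marginal means over subsets of ``dims``; its squared norm, weighted by
    the number of observations collapsed into each cell, is the SS.
    """
    term = np.zeros((1,) * values.ndim)
    for r in range(len(dims) + 1):
        for sub in itertools.combinations(sorted(dims), r):
            sign = (-1) ** (len(dims) - r)
            term = term + sign * _mean_keep(values, frozenset(sub))
    weight = np.prod([values.shape[ax] for ax in range(values.ndim) if ax not in dims])
    return float(weight * np.sum(term**2))


def _contrast_scores(values: np.ndarray, effect_axes: tuple[int, ...]) -> np.ndarray:
    """Subject x df matrix of orthonormal-contrast scores for one effect."""
    m = values
    # average out factors not involved in the effect
    drop = [ax for ax in range(1, m.ndim) if ax not in effect_axes]
    m = m.mean(axis=tuple(drop), keepdims=False) if drop else m
    # apply an orthonormal contrast basis along each involved factor
    for pos in range(1, m.ndim):
        l = m.shape[pos]
        C = sla.helmert(l, full=False)  # (l-1, l), orthonormal, orthogonal to 1
        m = np.moveaxis(np.tensordot(m, C.T, axes=([pos], [0])), -1, pos)
    return m.reshape(m.shape[0], -1)


def gg_epsilon(cube: WithinDesignCube | np.ndarray, effect: str | Sequence[str]) -> float:
    """Greenhouse-Geisser estimate of Box's epsilon for one effect.

    Computed from the sample covariance of the subject-level orthonormal
    contrast scores: eps = tr(S)^2 / (p * tr(S^2)), bounded to [1/p, 1].
    A 2-level effect has a single contrast and epsilon exactly 1.
    """
    values, axes, _ = _resolve_effect(cube, effect)
    M = _contrast_scores(values, axes)
    p = M.shape[1]
    if p == 0:
        raise ValueError("effect has fewer than 2 levels")
    if p == 1:
        return 1.0
    S = np.cov(M, rowvar=False)
    eps = np.trace(S) ** 2 / (p * np.sum(S * S))
    return float(min(1.0, max(1.0 / p, eps)))


def mauchly(cube: WithinDesignCube | np.ndarray, effect: str | Sequence[str]) -> tuple[float, float]:
    """Mauchly's sphericity test for one effect: (W, p).

    W compares the determinant and trace of the contrast covariance; the
    p-value uses the standard chi-square approximation. For a 2-level effect
    the test is vacuous (W = 1, p = 1). Returns (nan, nan) when the contrast
    covariance is singular (n - 1 <= df), in which case callers apply the
    Greenhouse-Geisser correction unconditionally.
    """
    values, axes, _ = _resolve_effect(cube, effect)
    M = _contrast_scores(values, axes)
    n, p = M.shape
    if p == 1:
        return 1.0, 1.0
    if n - 1 <= p:
        return float("nan"), float("nan")
    S = np.cov(M, rowvar=False)
    det = np.linalg.det(S)
    if det <= 0:
        return float("nan"), float("nan")
    W = det / (np.trace(S) / p) ** p
    d = 1.0 - (2 * p * p + p + 2) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * d * np.log(W)
    dof = p * (p + 1) // 2 - 1
    return float(W), float(sst.chi2.sf(chi2, dof))


def _resolve_effect(
    cube: WithinDesignCube | np.ndarray, effect: str | Sequence[str]
) -> tuple[np.ndarray, tuple[int, ...], str]:
    if isinstance(cube, WithinDesignCube):
        values, names = cube.values, cube.factor_names
    else:
        values = np.asarray(cube, dtype=float)
        names = tuple(f"f{i}" for i in range(1, values.ndim))
    parts = effect.split(":") if isinstance(effect, str) else list(effect)
    axes = tuple(names.index(p) + 1 for p in parts)
    if len(set(axes)) != len(axes) or not axes:
        raise ValueError(f"bad effect specification {effect!r}")
    return values, axes, ":".join(parts)


def rm_anova(
    cube: WithinDesignCube | np.ndarray,
    mauchly_alpha: float = MAUCHLY_ALPHA,
) -> list[AnovaEffect]:
    """Fully within-subjects repeated-measures ANOVA (1-3 factors).

    Every main effect and interaction is tested against its interaction with
    subjects. Returns one :class:`AnovaEffect` per effect, carrying raw and
    Greenhouse-Geisser-corrected p-values, the epsilon estimate, Mauchly's
    test, and whether the correction was applied (Mauchly p < alpha, or the
    Mauchly test unavailable).
    """
    if isinstance(cube, WithinDesignCube):
        values, names = cube.values, cube.factor_names
    else:
        values = np.asarray(cube, dtype=float)
        names = tuple(f"f{i}" for i in range(1, values.ndim))
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    k = values.ndim - 1
    # numerically-zero SS floor (an effect whose SS is pure rounding noise
    # relative to the total variation is a null effect, F = 0)
    ss_floor = 1e-12 * float(np.sum((values - values.mean()) ** 2)) + 1e-300

    effects: list[AnovaEffect] = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(1, k + 1), r):
            name = ":".join(names[ax - 1] for ax in combo)
            df_eff = int(np.prod([values.shape[ax] - 1 for ax in combo]))
            if df_eff == 0:
                raise ValueError(f"effect {name}: factor with a single level")
            ss_eff = _moebius_ss(values, frozenset(combo))
            ss_err = _moebius_ss(values, frozenset(combo) | {0})
            df_err = df_eff * (n - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            if ss_eff <= ss_floor:
                F = 0.0
            elif ss_err <= ss_floor:
                F = float("inf")
            else:
                F = ms_eff / ms_err
            p_raw = float(sst.f.sf(F, df_eff, df_err))
            eps = gg_epsilon(values, [f"f{ax}" for ax in combo])
            p_gg = float(sst.f.sf(F, eps * df_eff, eps * df_err))
            W, p_w = mauchly(values, [f"f{ax}" for ax in combo])
            applied = bool(np.isnan(p_w) or p_w < mauchly_alpha) and df_eff > 1
            effects.append(
                AnovaEffect(
                    name=name,
                    ss=ss_eff,
                    df=df_eff,
                    ms=ms_eff,
                    error_ss=ss_err,
                    error_df=df_err,
                    error_ms=ms_err,
                    F=float(F),
                    p_uncorrected=p_raw,
                    epsilon_gg=eps,
                    p_gg=p_gg,
                    mauchly_w=W,
                    mauchly_p=p_w,
                    sphericity_applied=applied,
                )
            )
    return effects


def bonferroni(p_values: Sequence[float], n_tests: Optional[int] = None) -> list[float]:
    """Multiply each p-value by the family size, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n_tests is None else int(n_tests)
    return [float(x) for x in np.minimum(1.0, p * n)]


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with the two-tailed t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * sst.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p_two_tailed=p)


def bhy_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg-Yekutieli step-up FDR control.

    The arbitrary-dependence variant: thresholds are shrunk by the harmonic
    sum c(m) = sum_{j<=m} 1/j. Returns the adjusted p-values (monotone after
    sorting, capped at 1) in the input order, and the rejection flags at
    level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return [], []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # enforce step-up monotonicity
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    # step-up rejections at level q
    reject_sorted = ranked <= (np.arange(1, m + 1) * q) / (m * c_m)
    k = np.nonzero(reject_sorted)[0]
    flags = np.zeros(m, dtype=bool)
    if k.size:
        flags[order[: k[-1] + 1]] = True
    return list(adjusted), list(flags)
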