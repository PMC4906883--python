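"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import numpy as np


def _orthonormal_complement_of_ones(size: int, seed: int = 0) -> np.ndarray:
    """(size, size-1) orthonormal basis orthogonal to the constant vector,
    built by QR of [ones | random] — deliberately not the Helmert matrix."""
    rng = np.random.default_rng(seed + size)
    m = np.column_stack([np.ones(size), rng.standard_normal((size, size - 1))])
    q, _ = np.linalg.qr(m)
    return q[:, 1:]


def anova_projection_oracle(values: np.ndarray) -> dict[str, tuple[float, float]]:
    """Fully-within rmANOVA by explicit tensor-basis projection.

    Decomposes the subject x levels data tensor in the orthonormal Kronecker
    basis {ones/sqrt(l), contrast basis} per dimension; the sum of squared
    coefficients of the blocks selecting contrasts exactly on a dim subset
    is that subset's SS. Returns {effect name: (SS_effect, SS_error)} with
    factor effects named "f1", "f2", ..., interactions joined by ":".
    """
    values = np.asarray(values, dtype=float)
    ndim = values.ndim
    coeffs = values.copy()
    # transform each dimension into [mean direction | contrast directions]
    for ax in range(ndim):
        l = values.shape[ax]
        basis = np.column_stack(
            [np.full(l, 1 / np.sqrt(l)), _orthonormal_complement_of_ones(l)]
        )
        coeffs = np.moveaxis(np.tensordot(coeffs, basis, axes=([ax], [0])), -1, ax)
    out: dict[str, tuple[float, float]] = {}
    factor_axes = list(range(1, ndim))
    for r in range(1, ndim):
        for combo in itertools.combinations(factor_axes, r):
            name = ":".join(f"f{ax}" for ax in combo)
            ss_eff = _block_ss(coeffs, set(combo))
            ss_err = _block_ss(coeffs, set(combo) | {0})
            out[name] = (ss_eff, ss_err)
    return out


def _block_ss(coeffs: np.ndarray, contrast_dims: set[int]) -> float:
    idx = tuple(
        slice(1, None) if ax in contrast_dims else slice(0, 1)
        for ax in range(coeffs.ndim)
    )
    return float(np.sum(coeffs[idx] ** 2))


def anova_oracle_f(values: np.ndarray) -> dict[str, float]:
    """F statistics from the projection oracle."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    out = {}
    for name, (ss_eff, ss_err) in anova_projection_oracle(values).items():
        axes = [int(p[1:]) for p in name.split(":")]
        df_eff = int(np.prod([values.shape[ax] - 1 for ax in axes]))
        df_err = df_eff * (n - 1)
        out[name] = (ss_eff / df_eff) / (ss_err / df_err)
    return out


def stop_criterion_bruteforce(flags) -> int | None:
    """Literal sliding-window scan of the 50%-in-four stop rule."""
    flags = list(flags)
    for i in range(3, len(flags)):
        if sum(flags[i - 3 : i + 1]) >= 2:
            return i + 1
    return None
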