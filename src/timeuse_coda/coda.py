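"""Compositional arithmetic for the four-part daily behaviour composition.

A day is treated as a composition of sedentary behaviour (SB), light physical
activity (LPA), moderate-to-vigorous physical activity (MVPA) and sleep,
closed to 1440 minutes.  The module provides closure, geometric means,
rounded-zero imputation, and the sequential-binary-partition (SBP) isometric
log-ratio (ilr) machinery, including the four pivot rotations that put each
behaviour in the "relative to the rest" role.

All array-level functions accept a single composition of shape ``(4,)`` or a
stack of compositions of shape ``(n, 4)`` with parts in the canonical order
``PARTS = ("sb", "lpa", "mvpa", "sleep")``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

PARTS: tuple[str, ...] = ("sb", "lpa", "mvpa", "sleep")
D = len(PARTS)
CLOSURE_TOTAL = 1440.0

__all__ = [
    "PARTS",
    "D",
    "CLOSURE_TOTAL",
    "SignMatrix",
    "IlrBasis",
    "close_composition",
    "geometric_mean_composition",
    "arithmetic_mean_composition",
    "multiplicative_replacement",
    "impute_zeros_lrem",
    "sbp_to_contrast_matrix",
    "ilr_transform",
    "ilr_inverse",
    "rotate_sbp",
    "default_basis",
]


def _as_2d(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def close_composition(parts, total: float = CLOSURE_TOTAL) -> np.ndarray:
    """Rescale strictly positive parts so each row sums to ``total``.

    Raises ``ValueError`` on non-positive parts: zeros carry no ratio
    information and must be imputed (see :func:`impute_zeros_lrem`) before
    closure.
    """
    arr, single = _as_2d(parts)
    if arr.shape[-1] != D:
        raise ValueError(f"expected {D} parts, got {arr.shape[-1]}")
    if total <= 0:
        raise ValueError("closure total must be positive")
    if np.any(arr <= 0):
        raise ValueError(
            "composition contains non-positive parts; impute zeros "
            "(impute_zeros_lrem / multiplicative_replacement) before closure"
        )
    out = arr * (total / arr.sum(axis=-1, keepdims=True))
    return out[0] if single else out


def arithmetic_mean_composition(rows, total: float = CLOSURE_TOTAL) -> np.ndarray:
    """Component-wise arithmetic mean of the raw minutes, closed to ``total``."""
    arr, _ = _as_2d(rows)
    if arr.shape[0] == 0:
        raise ValueError("cannot average an empty collection of compositions")
    return close_composition(arr.mean(axis=0), total)


def geometric_mean_composition(rows, total: float = CLOSURE_TOTAL) -> np.ndarray:
    """Component-wise geometric mean, closed to ``total``.

    This is the compositional centre: the composition whose ilr coordinates
    equal the mean of the rows' ilr coordinates.
    """
    arr, _ = _as_2d(rows)
    if arr.shape[0] == 0:
        raise ValueError("cannot average an empty collection of compositions")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive parts")
    return close_composition(np.exp(np.log(arr).mean(axis=0)), total)


# ---------------------------------------------------------------------------
# Rounded-zero imputation
# ---------------------------------------------------------------------------

def multiplicative_replacement(
    table, detection_limit=1.0, fraction: float = 0.65, total: float = CLOSURE_TOTAL
) -> np.ndarray:
    """Replace zeros with ``fraction * detection_limit`` and re-close.

    Simple deterministic imputation: each zero becomes a fixed small value and
    the observed (non-zero) parts of the row are rescaled multiplicatively so
    the row still sums to ``total``.  Serves as the fallback for — and the
    reference point of — the EM imputation below.
    """
    arr, single = _as_2d(table)
    limits = np.broadcast_to(np.asarray(detection_limit, dtype=float), (D,))
    _check_imputable(arr, limits)
    out = arr * (total / np.where(arr.sum(axis=1) > 0, arr.sum(axis=1), 1.0)[:, None])
    zero = out == 0
    if zero.any():
        repl = np.broadcast_to(fraction * limits, out.shape)
        filled = np.where(zero, repl, 0.0)
        budget = total - filled.sum(axis=1, keepdims=True)
        observed_sum = np.where(zero, 0.0, out).sum(axis=1, keepdims=True)
        out = np.where(zero, filled, out * budget / observed_sum)
    return out[0] if single else out


def _check_imputable(arr: np.ndarray, limits: np.ndarray) -> None:
    if np.any(arr < 0):
        raise ValueError("negative durations are not a valid composition")
    n_pos = (arr > 0).sum(axis=1)
    if np.any(n_pos <= 1):
        bad = np.nonzero(n_pos <= 1)[0]
        raise ValueError(
            f"rows {bad.tolist()} have <= 1 positive part: no log-ratio "
            "information to impute from"
        )
    has_zero = (arr == 0).any(axis=0)
    if np.any(has_zero & (limits <= 0)):
        raise ValueError("detection limit must be positive for parts containing zeros")


def impute_zeros_lrem(
    table,
    detection_limit=1.0,
    total: float = CLOSURE_TOTAL,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Impute rounded zeros by expectation–maximisation on log-ratios.

    Zeros are treated as censored observations below their detection limit.
    Working in additive log-ratio coordinates (reference = the part with the
    fewest zeros), the algorithm alternates:

    * E-step: replace each censored coordinate by the conditional expectation
      of a normal truncated above the limit's log-ratio, given the row's
      observed coordinates;
    * M-step: re-estimate the coordinate mean vector and covariance.

    Iteration stops when the largest parameter change falls below ``tol``.
    Imputed minutes are clipped into ``(0, detection_limit)``; observed parts
    are rescaled so each row closes to ``total``.  Falls back to
    :func:`multiplicative_replacement` when the table is too small to
    estimate a stable log-ratio covariance (< 10 rows) or when the reference
    part itself is censored.
    """
    arr, single = _as_2d(table)
    limits = np.broadcast_to(np.asarray(detection_limit, dtype=float), (D,)).copy()
    _check_imputable(arr, limits)

    closed = arr * (total / arr.sum(axis=1, keepdims=True))
    zero_mask = closed == 0
    if not zero_mask.any():
        return closed[0] if single else closed
    ref = int(np.argmin(zero_mask.sum(axis=0)))
    if arr.shape[0] < 10 or zero_mask[:, ref].any():
        # too few rows for a stable 3-D covariance, or a censored reference
        # part that would poison every ratio: multiplicative replacement
        out = multiplicative_replacement(arr, limits, total=total)
        return out[0] if single else out
    others = [j for j in range(D) if j != ref]

    # initialise censored entries at 0.65 * limit (the multiplicative start)
    start = multiplicative_replacement(closed, limits, total=total)
    z = np.log(start[:, others] / start[:, [ref]])
    cens = zero_mask[:, others]
    # censoring threshold in alr space, using each row's observed reference
    thresh = np.log(limits[None, others] / start[:, [ref]])

    mu = z.mean(axis=0)
    sigma = np.cov(z, rowvar=False) + 1e-9 * np.eye(len(others))
    for _ in range(max_iter):
        for i in np.nonzero(cens.any(axis=1))[0]:
            c = cens[i]
            o = ~c
            if o.any():
                s_oo = sigma[np.ix_(o, o)]
                s_co = sigma[np.ix_(c, o)]
                cond_mu = mu[c] + s_co @ np.linalg.solve(s_oo, z[i, o] - mu[o])
                cond_var = np.diag(
                    sigma[np.ix_(c, c)] - s_co @ np.linalg.solve(s_oo, s_co.T)
                )
            else:
                cond_mu = mu[c]
                cond_var = np.diag(sigma)[c]
            sd = np.sqrt(np.maximum(cond_var, 1e-12))
            b = (thresh[i, c] - cond_mu) / sd
            z[i, c] = truncnorm.mean(-np.inf, b, loc=cond_mu, scale=sd)
        new_mu = z.mean(axis=0)
        new_sigma = np.cov(z, rowvar=False) + 1e-9 * np.eye(len(others))
        delta = max(
            np.abs(new_mu - mu).max(), np.abs(new_sigma - sigma).max()
        )
        mu, sigma = new_mu, new_sigma
        if delta < tol:
            break

    out = closed.copy()
    imputed = start[:, [ref]] * np.exp(z)  # back to minutes via the reference
    for k, j in enumerate(others):
        rows = zero_mask[:, j]
        out[rows, j] = np.clip(imputed[rows, k], 1e-9, limits[j] * (1 - 1e-9))
    # rescale observed parts so rows close to `total` with imputed values fixed
    filled = np.where(zero_mask, out, 0.0).sum(axis=1, keepdims=True)
    obs_sum = np.where(zero_mask, 0.0, out).sum(axis=1, keepdims=True)
    out = np.where(zero_mask, out, out * (total - filled) / obs_sum)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# SBP / ilr machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignMatrix:
    """A sequential binary partition over the four behaviours.

    ``matrix`` has one row per partition step and one column per part in
    ``part_order``; entries are +1 (numerator group), -1 (denominator group)
    or 0 (part not involved at that step).
    """

    matrix: tuple[tuple[int, ...], ...]
    part_order: tuple[str, ...] = PARTS

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (D - 1, D):
            raise ValueError(f"sign matrix must be {D - 1}x{D}")
        if sorted(self.part_order) != sorted(PARTS):
            raise ValueError(f"part_order must be a permutation of {PARTS}")
        self.validate()

    def validate(self) -> None:
        """Check the rows form a valid sequential binary partition."""
        m = np.asarray(self.matrix)
        if not np.isin(m, (-1, 0, 1)).all():
            raise ValueError("sign matrix entries must be -1, 0 or +1")
        active: list[frozenset[int]] = [frozenset(range(D))]
        for r, row in enumerate(m):
            pos = frozenset(np.nonzero(row == 1)[0].tolist())
            neg = frozenset(np.nonzero(row == -1)[0].tolist())
            if not pos or not neg:
                raise ValueError(f"row {r} needs at least one +1 and one -1")
            group = pos | neg
            if group not in active:
                raise ValueError(
                    f"row {r} does not split a group produced by earlier rows: "
                    "not a sequential binary partition"
                )
            active.remove(group)
            if len(pos) > 1:
                active.append(pos)
            if len(neg) > 1:
                active.append(neg)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.asarray(self.matrix),
            columns=list(self.part_order),
            index=[f"ilr{k + 1}" for k in range(D - 1)],
        )


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal ilr basis generated from a sequential binary partition.

    ``contrast_matrix`` is the 4x3 balance-coefficient matrix V with rows in
    *canonical* part order (``PARTS``), so coordinates are ``log(x) @ V`` for
    data whose columns follow ``PARTS`` regardless of the pivot.
    """

    sign_matrix: SignMatrix
    contrast_matrix: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.contrast_matrix is None:
            object.__setattr__(
                self, "contrast_matrix", _contrast_from_sbp(self.sign_matrix)
            )

    @property
    def pivot(self) -> str:
        return self.sign_matrix.part_order[0]

    def to_frame(self):
        """Contrast matrix as a DataFrame with behaviour labels (CSV-ready)."""
        import pandas as pd

        return pd.DataFrame(
            self.contrast_matrix.T,
            columns=list(PARTS),
            index=[f"ilr{k + 1}" for k in range(D - 1)],
        )


def _contrast_from_sbp(sign: SignMatrix) -> np.ndarray:
    m = np.asarray(sign.matrix, dtype=float)
    V = np.zeros((D, D - 1))
    for k, row in enumerate(m):
        r = (row == 1).sum()
        s = (row == -1).sum()
        V[row == 1, k] = np.sqrt(s / (r * (r + s)))
        V[row == -1, k] = -np.sqrt(r / (s * (r + s)))
    # reorder rows from the sign matrix's part order to canonical order
    perm = [sign.part_order.index(p) for p in PARTS]
    return V[perm]


def sbp_to_contrast_matrix(sign: SignMatrix) -> IlrBasis:
    """Build the orthonormal ilr basis for a sequential binary partition."""
    return IlrBasis(sign_matrix=sign)


_PIVOT_TEMPLATE = ((1, -1, -1, -1), (0, 1, -1, -1), (0, 0, 1, -1))


def rotate_sbp(pivot: str = "sb") -> SignMatrix:
    """The pivot-first sign matrix: +1 on the pivot vs the rest in row 1.

    Rotating which behaviour occupies the x1 role makes that behaviour's
    first coordinate directly interpretable as "this behaviour relative to
    all others"; the remaining parts keep their cyclic canonical order.
    """
    if pivot not in PARTS:
        raise ValueError(f"unknown behaviour {pivot!r}; expected one of {PARTS}")
    i = PARTS.index(pivot)
    order = tuple(PARTS[(i + k) % D] for k in range(D))
    return SignMatrix(matrix=_PIVOT_TEMPLATE, part_order=order)


def default_basis(pivot: str = "sb") -> IlrBasis:
    return sbp_to_contrast_matrix(rotate_sbp(pivot))


def ilr_transform(x, basis: IlrBasis | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates of one or many compositions.

    Coordinate k is ``sum_i V[i, k] * ln(x_i)``; with the pivot-first basis,
    the first coordinate is ``sqrt(3/4) * ln(pivot / gmean(others))``.
    Scale-invariant: closing or rescaling ``x`` does not change the result.
    """
    if basis is None:
        basis = default_basis()
    arr, single = _as_2d(x)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("ilr requires strictly positive finite parts")
    z = np.log(arr) @ basis.contrast_matrix
    return z[0] if single else z


def ilr_inverse(z, basis: IlrBasis | None = None, total: float = CLOSURE_TOTAL) -> np.ndarray:
    """Map ilr coordinates back to a composition closed to ``total``."""
    if basis is None:
        basis = default_basis()
    arr, single = _as_2d(np.asarray(z, dtype=float))
    if arr.shape[-1] != D - 1:
        raise ValueError(f"expected {D - 1} coordinates, got {arr.shape[-1]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ilr coordinates must be finite")
    x = np.exp(arr @ basis.contrast_matrix.T)
    x = x * (total / x.sum(axis=-1, keepdims=True))
    return x[0] if single else x
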