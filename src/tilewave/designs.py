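"""Design-matrix construction for tiling-array models.

Builds the N x q design matrices that encode the experimental layout:
two-group dummy coding, orthogonal-polynomial time-course codings, Helmert
contrasts for unordered factors, first-harmonic Fourier codings for circadian
designs, and QR-orthogonalized custom (e.g. multi-factor) matrices.

All constructors can return a *normalized* matrix X'' with X''^T X'' = I_q,
which is what the common-smoothing empirical-Bayes fit requires; the column
norms divided out are retained so coefficients can be mapped back to the
original coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidDesignError, RankError

__all__ = [
    "DesignSpec",
    "DesignMatrix",
    "build_two_group",
    "build_time_polynomial",
    "build_helmert",
    "build_circadian",
    "orthogonalize",
    "build_design",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of an experimental design.

    Parameters
    ----------
    kind:
        One of ``two_group``, ``factor_helmert``, ``time_polynomial``,
        ``circadian``, ``custom``.
    labels:
        Per-array group labels (two-group / factor designs).
    times:
        Per-array time values (time-course / circadian designs).
    period:
        Oscillation period, same units as ``times`` (circadian only).
    custom:
        Explicit N x q matrix (custom designs only).
    normalize:
        Whether the resolved matrix should have orthonormal columns.
    """

    kind: str
    labels: Optional[Sequence] = None
    times: Optional[Sequence[float]] = None
    period: Optional[float] = None
    custom: Optional[np.ndarray] = None
    normalize: bool = True

    def __post_init__(self) -> None:
        kinds = {"two_group", "factor_helmert", "time_polynomial", "circadian", "custom"}
        if self.kind not in kinds:
            raise InvalidDesignError(f"unknown design kind {self.kind!r}; expected one of {sorted(kinds)}")
        if self.n_arrays < 2:
            raise InvalidDesignError("a design needs at least 2 arrays")
        if self.kind in ("time_polynomial", "circadian"):
            if self.times is None:
                raise InvalidDesignError(f"{self.kind} design requires per-array time values")
            distinct = np.unique(np.asarray(self.times, dtype=float)).size
            minimum = 3 if self.kind == "circadian" else 2
            if distinct < minimum:
                raise InvalidDesignError(
                    f"{self.kind} design requires >= {minimum} distinct time points, got {distinct}"
                )
        if self.kind == "circadian" and (self.period is None or self.period <= 0):
            raise InvalidDesignError("circadian design requires a positive period")
        if self.kind in ("two_group", "factor_helmert") and self.labels is None:
            raise InvalidDesignError(f"{self.kind} design requires per-array group labels")
        if self.kind == "custom" and self.custom is None:
            raise InvalidDesignError("custom design requires an explicit matrix")

    @property
    def n_arrays(self) -> int:
        for attr in (self.labels, self.times):
            if attr is not None:
                return len(attr)
        if self.custom is not None:
            return int(np.asarray(self.custom).shape[0])
        return 0


@dataclass
class DesignMatrix:
    """A resolved N x q design matrix with coding provenance.

    Attributes
    ----------
    values:
        The matrix itself (arrays in rows, effects in columns).
    column_roles:
        One tag per column: ``overall_mean``, ``group_diff``,
        ``poly_degree_<d>``, ``sine``, ``cosine``, ``main_effect``,
        ``interaction``.
    normalized:
        True when columns are orthonormal (X^T X = I_q).
    column_scales:
        Norms divided out during normalization (ones when unnormalized);
        original coding = values * column_scales.
    triangular:
        Upper-triangular factor of a QR-orthogonalized custom design
        (``values @ triangular`` reproduces the pre-orthogonalization
        matrix), or None.
    row_groups / group_sizes:
        Integer group index per array and per-group array counts, for
        designs with replicated conditions; used by pairwise inference.
    times / period:
        Provenance for time-based designs.
    """

    values: np.ndarray
    column_roles: list[str]
    normalized: bool = False
    column_scales: np.ndarray = None  # type: ignore[assignment]
    triangular: Optional[np.ndarray] = None
    row_groups: Optional[np.ndarray] = None
    group_sizes: Optional[np.ndarray] = None
    times: Optional[np.ndarray] = None
    period: Optional[float] = None
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidDesignError("design matrix must be 2-D")
        if self.column_scales is None:
            self.column_scales = np.ones(self.q)
        if len(self.column_roles) != self.q:
            raise InvalidDesignError("one column role per design column required")
        if self.normalized:
            dev = np.max(np.abs(self.values.T @ self.values - np.eye(self.q)))
            if dev > 1e-8:
                raise InvalidDesignError(f"matrix flagged normalized but X^T X deviates from I by {dev:.2e}")

    @property
    def n_arrays(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @property
    def gram(self) -> np.ndarray:
        return self.values.T @ self.values

    @property
    def original(self) -> np.ndarray:
        """The matrix on its original (pre-normalization / pre-QR) coding."""
        if self.triangular is not None:
            return self.values @ self.triangular
        return self.values * self.column_scales

    def normalize(self) -> "DesignMatrix":
        """Return a copy with unit-norm columns (X''^T X'' = I for orthogonal codings)."""
        if self.normalized:
            return self
        norms = np.linalg.norm(self.values, axis=0)
        if np.any(norms == 0):
            raise InvalidDesignError("cannot normalize a design with a zero column")
        # unit columns give X''^T X'' = I only when the coding is orthogonal
        return replace(
            self,
            values=self.values / norms,
            column_scales=self.column_scales * norms,
            normalized=bool(_is_orthonormal(self.values / norms)),
        )

    def to_tsv(self, path) -> None:
        """Dump the resolved matrix with a role header, for audit."""
        import pandas as pd

        pd.DataFrame(self.values, columns=self.column_roles).to_csv(path, sep="\t", index=False)


def _is_orthonormal(x: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    g = x.T @ x
    return bool(np.max(np.abs(g - np.eye(x.shape[1]))) < tol)


def _grouped(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Group index per row (first-appearance order) and per-group counts."""
    order: dict = {}
    idx = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        idx[i] = order.setdefault(lab, len(order))
    sizes = np.bincount(idx, minlength=len(order))
    return idx, sizes


def build_two_group(n1: int, n2: int, normalize: bool = False) -> DesignMatrix:
    """Two-condition design: intercept plus +/-1 dummy coding.

    Column 0 (all ones) models the mean expression level; column 1 is +1 for
    the ``n1`` condition-1 arrays and -1 for the ``n2`` condition-2 arrays, so
    twice its effect function is the fitted between-condition difference.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidDesignError(f"both group sizes must be positive, got ({n1}, {n2})")
    col1 = np.concatenate([np.ones(n1), -np.ones(n2)])
    x = np.column_stack([np.ones(n1 + n2), col1])
    dm = DesignMatrix(
        values=x,
        column_roles=["overall_mean", "group_diff"],
        row_groups=np.repeat([0, 1], [n1, n2]),
        group_sizes=np.array([n1, n2]),
        kind="two_group",
    )
    return dm.normalize() if normalize else dm


def _integer_style(col: np.ndarray) -> np.ndarray:
    """Rescale a column by its smallest-magnitude nonzero entry.

    On balanced equidistant designs this reproduces the classical integer
    orthogonal-contrast tables, e.g. (1,1,1), (-1,0,1), (1,-2,1).
    """
    mags = np.abs(col)
    nonzero = mags > 1e-9 * mags.max()
    return col / mags[nonzero].min()


def build_time_polynomial(time_values: Sequence[float], normalize: bool = False) -> DesignMatrix:
    """Orthogonal-polynomial coding of a time course.

    Column d evaluates a degree-d polynomial, orthogonal over the design
    points, at each array's time; q = number of distinct time points. Built by
    QR decomposition of the Vandermonde matrix of centered times, so unbalanced
    and non-equidistant layouts are handled uniformly.
    """
    t = np.asarray(time_values, dtype=float)
    uniq = np.unique(t)
    q = uniq.size
    if q < 2:
        raise InvalidDesignError("time design requires >= 2 distinct time points")
    centered = t - t.mean()
    vand = np.vander(centered, N=q, increasing=True)
    qmat, rmat = np.linalg.qr(vand)
    sign = np.sign(np.diag(rmat))
    sign[sign == 0] = 1.0
    qmat = qmat * sign
    cols = np.column_stack([_integer_style(qmat[:, d]) for d in range(q)])
    roles = ["overall_mean"] + [f"poly_degree_{d}" for d in range(1, q)]
    row_groups = np.searchsorted(uniq, t)
    dm = DesignMatrix(
        values=cols,
        column_roles=roles,
        row_groups=row_groups,
        group_sizes=np.bincount(row_groups),
        times=t,
        kind="time_polynomial",
    )
    return dm.normalize() if normalize else dm


def _helmert_columns(row_groups: np.ndarray, q: int) -> np.ndarray:
    """Intercept plus q-1 Helmert contrasts over group indices.

    Contrast j compares group j+1 with the mean of groups 1..j: its column is
    -1 on arrays of the first j groups, +j on group j+1, 0 afterwards.
    """
    n = row_groups.size
    x = np.ones((n, q))
    for j in range(1, q):
        col = np.zeros(n)
        col[row_groups < j] = -1.0
        col[row_groups == j] = float(j)
        x[:, j] = col
    return x


def build_helmert(group_sizes: Sequence[int], normalize: bool = False) -> DesignMatrix:
    """Helmert-contrast design for an unordered factor with q >= 2 levels.

    Each contrast compares one level's mean expression with the overall mean
    of all preceding levels, which keeps the effect functions estimable
    orthogonally: the cross-product X^T X is diagonal with entries
    N, sum_{i<=2} N_i, 2 sum_{i<=3} N_i, ..., (q-1) sum_{i<=q} N_i.
    """
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.size < 2:
        raise InvalidDesignError("Helmert design requires q >= 2 groups")
    if np.any(sizes < 1):
        raise InvalidDesignError("all group sizes must be positive")
    q = sizes.size
    row_groups = np.repeat(np.arange(q), sizes)
    dm = DesignMatrix(
        values=_helmert_columns(row_groups, q),
        column_roles=["overall_mean"] + ["group_diff"] * (q - 1),
        row_groups=row_groups,
        group_sizes=sizes,
        kind="factor_helmert",
    )
    return dm.normalize() if normalize else dm


def build_circadian(
    time_values: Sequence[float], period: float, normalize: bool = False
) -> DesignMatrix:
    """First-harmonic Fourier design for circadian-rhythm detection.

    Rows are [1, sin(2*pi*t/period), cos(2*pi*t/period)]. For equally spaced
    designs covering whole cycles X^T X = diag(N, N/2, N/2).
    """
    if period is None or period <= 0:
        raise InvalidDesignError("circadian period must be positive")
    t = np.asarray(time_values, dtype=float)
    uniq = np.unique(t)
    if uniq.size < 3:
        raise InvalidDesignError("circadian design requires >= 3 distinct time points")
    phase = 2.0 * np.pi * t / period
    x = np.column_stack([np.ones(t.size), np.sin(phase), np.cos(phase)])
    row_groups = np.searchsorted(uniq, t)
    dm = DesignMatrix(
        values=x,
        column_roles=["overall_mean", "sine", "cosine"],
        row_groups=row_groups,
        group_sizes=np.bincount(row_groups),
        times=t,
        period=float(period),
        kind="circadian",
    )
    return dm.normalize() if normalize else dm


def orthogonalize(
    custom: np.ndarray, column_roles: Optional[Sequence[str]] = None
) -> DesignMatrix:
    """QR-orthogonalize a custom (typically multi-factor) design matrix.

    Returns X_orth with orthonormal columns and stores the upper-triangular
    factor X_tri so that X_orth @ X_tri reproduces the input; model parameters
    fitted on X_orth are mapped back to the original coding by X_tri^{-1}.
    The sign convention (positive X_tri diagonal) makes the factorization
    reproducible across linear-algebra backends.
    """
    x = np.asarray(custom, dtype=float)
    if x.ndim != 2 or x.shape[0] < x.shape[1]:
        raise InvalidDesignError("custom design must be N x q with N >= q")
    qmat, rmat = np.linalg.qr(x)
    diag = np.abs(np.diag(rmat))
    scale = np.max(diag) if np.max(diag) > 0 else 1.0
    bad = np.nonzero(diag < 1e-10 * scale)[0]
    if bad.size:
        raise RankError(f"design matrix is rank deficient: column {bad[0]} is linearly dependent")
    sign = np.sign(np.diag(rmat))
    sign[sign == 0] = 1.0
    qmat = qmat * sign
    rmat = rmat * sign[:, None]
    if column_roles is None:
        column_roles = ["overall_mean"] + ["main_effect"] * (x.shape[1] - 1)
    return DesignMatrix(
        values=qmat,
        column_roles=list(column_roles),
        normalized=True,
        triangular=rmat,
        kind="custom",
    )


def build_design(spec: DesignSpec) -> DesignMatrix:
    """Resolve a :class:`DesignSpec` into a :class:`DesignMatrix`."""
    if spec.kind == "two_group":
        row_groups, sizes = _grouped(spec.labels)
        if sizes.size != 2:
            raise InvalidDesignError(f"two_group design needs exactly 2 distinct labels, got {sizes.size}")
        col1 = np.where(row_groups == 0, 1.0, -1.0)
        dm = DesignMatrix(
            values=np.column_stack([np.ones(row_groups.size), col1]),
            column_roles=["overall_mean", "group_diff"],
            row_groups=row_groups,
            group_sizes=sizes,
            kind="two_group",
        )
        return dm.normalize() if spec.normalize else dm
    if spec.kind == "factor_helmert":
        row_groups, sizes = _grouped(spec.labels)
        if sizes.size < 2:
            raise InvalidDesignError("factor_helmert design needs >= 2 distinct labels")
        dm = DesignMatrix(
            values=_helmert_columns(row_groups, sizes.size),
            column_roles=["overall_mean"] + ["group_diff"] * (sizes.size - 1),
            row_groups=row_groups,
            group_sizes=sizes,
            kind="factor_helmert",
        )
        return dm.normalize() if spec.normalize else dm
    if spec.kind == "time_polynomial":
        return build_time_polynomial(spec.times, normalize=spec.normalize)
    if spec.kind == "circadian":
        return build_circadian(spec.times, spec.period, normalize=spec.normalize)
    return orthogonalize(spec.custom)
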