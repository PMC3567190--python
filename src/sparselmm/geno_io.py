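"""Genotype / phenotype / relatedness-matrix I/O and preprocessing.

Genotypes are dosage matrices (individuals x markers) with values in
``[0, 2]`` counting copies of the minor allele.  Columns are mean-imputed
and centered (but not standardized) before any model fitting.  The
relatedness matrix is ``K = X X^T / p`` from the centered dosages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "Kinship",
    "read_bimbam_genotypes",
    "write_bimbam_genotypes",
    "read_plain_genotypes",
    "write_plain_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "impute_and_center",
    "center_with_means",
    "compute_kinship",
    "compute_cross_kinship",
    "read_kinship",
    "write_kinship",
]

PathLike = Union[str, Path]


@dataclass
class GenotypeMatrix:
    """An ``n x p`` dosage matrix plus per-marker metadata.

    Attributes
    ----------
    dosages
        ``(n, p)`` float array.  Raw values lie in ``[0, 2]``; after
        :func:`impute_and_center` each column has zero mean.
    marker_ids
        Length-``p`` marker identifiers.
    allele_pair
        Optional per-marker ``(minor, major)`` allele strings.
    missing_mask
        ``(n, p)`` boolean; ``True`` where the raw dosage was missing.
    centered
        Whether columns have been imputed and mean-centered.
    col_means
        Per-column means of the observed raw dosages (set on centering).
    col_vars
        Per-column variances (divisor ``n``) of the centered dosages.
    s_a
        Mean of ``col_vars``: the average genotype variance across markers.
    """

    dosages: np.ndarray
    marker_ids: list[str]
    allele_pair: Optional[list[tuple[str, str]]] = None
    missing_mask: Optional[np.ndarray] = None
    centered: bool = False
    col_means: Optional[np.ndarray] = None
    col_vars: Optional[np.ndarray] = None
    s_a: Optional[float] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.dosages.shape, dtype=bool)
        if len(self.marker_ids) != self.dosages.shape[1]:
            raise ValueError(
                f"{len(self.marker_ids)} marker ids for "
                f"{self.dosages.shape[1]} columns"
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset preserving marker metadata and centering state."""
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            marker_ids=list(self.marker_ids),
            allele_pair=self.allele_pair,
            missing_mask=self.missing_mask[idx],
            centered=self.centered,
            col_means=self.col_means,
            col_vars=self.col_vars,
            s_a=self.s_a,
        )


@dataclass
class PhenotypeVector:
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        observed = self.values[~self.missing_mask]
        self.is_binary = bool(
            observed.size > 0 and np.all(np.isin(observed, (0.0, 1.0)))
        )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def observed_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.missing_mask)


@dataclass
class Kinship:
    """Symmetric relatedness matrix with its cached eigendecomposition.

    Eigenvalues are stored in descending order; small negative values
    (below ``1e-8 * lambda_max``) are clamped to zero.
    """

    K: np.ndarray
    s_b: float = 0.0
    eigenvalues: Optional[np.ndarray] = None
    eigenvectors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        asym = np.max(np.abs(self.K - self.K.T)) if n else 0.0
        if asym > 1e-8 * max(1.0, np.max(np.abs(self.K)) if n else 1.0):
            raise ValueError(f"kinship matrix asymmetric (max |K-K^T| = {asym:g})")
        self.s_b = float(np.mean(np.diag(self.K))) if n else 0.0
        if self.eigenvalues is None or self.eigenvectors is None:
            w, U = np.linalg.eigh(self.K)
            order = np.argsort(-w, kind="stable")
            w, U = w[order], U[:, order]
            lam_max = max(w[0], 0.0) if n else 0.0
            if n and w[-1] < -1e-8 * max(lam_max, 1.0):
                raise ValueError(
                    f"kinship matrix has eigenvalue {w[-1]:g} far below zero"
                )
            self.eigenvalues = np.clip(w, 0.0, None)
            self.eigenvectors = U

    @property
    def n(self) -> int:
        return self.K.shape[0]


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------

def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_bimbam_genotypes(path: PathLike) -> GenotypeMatrix:
    """Read a BIMBAM mean-genotype file.

    Each line holds ``marker_id, allele1, allele2`` followed by ``n``
    dosages in ``[0, 2]``; ``NA`` marks a missing dosage.  Fields may be
    separated by commas and/or whitespace.  The returned matrix is
    transposed to individuals-by-markers with marker order preserved.
    """
    marker_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    miss_rows: list[np.ndarray] = []
    n: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = _tokenize(line)
            if not toks:
                continue
            if len(toks) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected id, 2 alleles and "
                    f"at least one dosage, got {len(toks)} fields"
                )
            marker_ids.append(toks[0])
            alleles.append((toks[1], toks[2]))
            vals = toks[3:]
            if n is None:
                n = len(vals)
            elif len(vals) != n:
                raise ValueError(
                    f"{path}: line {lineno}: ragged line "
                    f"({len(vals)} dosages, expected {n})"
                )
            miss = np.array([v.upper() == "NA" for v in vals])
            row = np.array(
                [0.0 if m else float(v) for v, m in zip(vals, miss)]
            )
            bad = ~miss & ((row < -1e-6) | (row > 2 + 1e-6))
            if np.any(bad):
                j = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: line {lineno}: dosage {row[j]:g} outside [0, 2]"
                )
            rows.append(np.clip(row, 0.0, 2.0))
            miss_rows.append(miss)
    if not rows:
        raise ValueError(f"{path}: no genotype records")
    return GenotypeMatrix(
        dosages=np.array(rows).T,
        marker_ids=marker_ids,
        allele_pair=alleles,
        missing_mask=np.array(miss_rows).T,
    )


def write_bimbam_genotypes(g: GenotypeMatrix, path: PathLike) -> None:
    """Write raw dosages in BIMBAM mean-genotype format (full precision)."""
    alleles = g.allele_pair or [("A", "T")] * g.p
    with open(path, "w") as fh:
        for j in range(g.p):
            vals = []
            for i in range(g.n):
                if g.missing_mask[i, j]:
                    vals.append("NA")
                else:
                    vals.append(repr(float(g.dosages[i, j])))
            fh.write(
                f"{g.marker_ids[j]}, {alleles[j][0]}, {alleles[j][1]}, "
                + ", ".join(vals)
                + "\n"
            )


def read_plain_genotypes(
    path: PathLike, marker_ids: Optional[Sequence[str]] = None
) -> GenotypeMatrix:
    """Read a header-free whitespace-delimited ``n x p`` dosage matrix.

    ``NA``/``nan`` entries are treated as missing.  ``marker_ids`` may be
    a sidecar list; defaults to ``m0..m{p-1}``.
    """
    with open(path) as fh:
        text = fh.read()
    arr = np.genfromtxt(io.StringIO(text), missing_values="NA", dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    miss = ~np.isfinite(arr)
    arr = np.where(miss, 0.0, arr)
    ids = list(marker_ids) if marker_ids is not None else [
        f"m{j}" for j in range(arr.shape[1])
    ]
    return GenotypeMatrix(dosages=arr, marker_ids=ids, missing_mask=miss)


def write_plain_genotypes(g: GenotypeMatrix, path: PathLike) -> None:
    out = np.where(g.missing_mask, np.nan, g.dosages)
    with open(path, "w") as fh:
        for row in out:
            fh.write(" ".join("NA" if not np.isfinite(v) else repr(float(v)) for v in row))
            fh.write("\n")


def read_phenotypes(path: PathLike) -> PhenotypeVector:
    """Read one phenotype value per line; ``NA`` marks missing."""
    vals: list[float] = []
    miss: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok.upper() == "NA":
                vals.append(np.nan)
                miss.append(True)
            else:
                try:
                    vals.append(float(tok))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: cannot parse {tok!r}"
                    ) from exc
                miss.append(False)
    if not vals:
        raise ValueError(f"{path}: no phenotype values")
    return PhenotypeVector(values=np.array(vals), missing_mask=np.array(miss))


def write_phenotypes(y: PhenotypeVector, path: PathLike) -> None:
    with open(path, "w") as fh:
        for v, m in zip(y.values, y.missing_mask):
            fh.write("NA\n" if m else f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_and_center(g: GenotypeMatrix, standardize: bool = False) -> GenotypeMatrix:
    """Mean-impute missing dosages per marker, then center each column.

    Populates ``col_means`` (means of observed raw dosages), ``col_vars``
    (variance of the centered column, divisor ``n``) and ``s_a`` (their
    mean).  Columns are centered but *not* standardized by default;
    ``standardize=True`` additionally scales each polymorphic column to
    unit variance.  Raises if any marker has no observed dosages.
    """
    X = g.dosages.copy()
    miss = g.missing_mask
    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {g.marker_ids[j]} has no observed dosages")
    sums = np.where(miss, 0.0, X).sum(axis=0)
    col_means = sums / n_obs
    X = np.where(miss, col_means[None, :], X)
    # after imputation every column mean equals the observed mean
    X = X - X.mean(axis=0, keepdims=True)
    col_vars = np.mean(X * X, axis=0)
    if standardize:
        scale = np.where(col_vars > 0, np.sqrt(col_vars), 1.0)
        X = X / scale[None, :]
        col_vars = np.mean(X * X, axis=0)
    return GenotypeMatrix(
        dosages=X,
        marker_ids=list(g.marker_ids),
        allele_pair=g.allele_pair,
        missing_mask=miss.copy(),
        centered=True,
        col_means=col_means,
        col_vars=col_vars,
        s_a=float(np.mean(col_vars)),
    )


def center_with_means(g: GenotypeMatrix, col_means: np.ndarray) -> GenotypeMatrix:
    """Impute and center *test* dosages using training column means.

    Prediction must not peek at the test distribution, so both the
    imputation value and the centering offset come from ``col_means``.
    """
    col_means = np.asarray(col_means, dtype=float)
    if col_means.shape != (g.p,):
        raise ValueError("col_means length does not match marker count")
    X = np.where(g.missing_mask, col_means[None, :], g.dosages)
    X = X - col_means[None, :]
    col_vars = np.mean(X * X, axis=0)
    return GenotypeMatrix(
        dosages=X,
        marker_ids=list(g.marker_ids),
        allele_pair=g.allele_pair,
        missing_mask=g.missing_mask.copy(),
        centered=True,
        col_means=col_means,
        col_vars=col_vars,
        s_a=float(np.mean(col_vars)),
    )


def compute_kinship(g: GenotypeMatrix) -> Kinship:
    """Relatedness matrix ``K = X X^T / p`` from centered dosages."""
    if g.p == 0:
        raise ValueError("cannot compute kinship with zero markers")
    if not g.centered:
        raise ValueError("genotypes must be imputed and centered first")
    K = (g.dosages @ g.dosages.T) / g.p
    K = (K + K.T) / 2.0  # kill rounding asymmetry
    return Kinship(K=K)


def compute_cross_kinship(
    g_test: GenotypeMatrix, g_train: GenotypeMatrix
) -> np.ndarray:
    """``n_test x n_train`` cross block of ``X X^T / p``.

    Both inputs must be centered with the *training* column means and
    share the same marker set in the same order.
    """
    if g_test.marker_ids != g_train.marker_ids:
        bad = [
            a for a, b in zip(g_test.marker_ids, g_train.marker_ids) if a != b
        ] or ["(length mismatch)"]
        raise ValueError(f"train/test marker mismatch: {bad[:5]}")
    if not (g_test.centered and g_train.centered):
        raise ValueError("both genotype sets must be centered")
    return (g_test.dosages @ g_train.dosages.T) / g_train.p


def read_kinship(path: PathLike, n: int) -> Kinship:
    """Read a whitespace-delimited ``n x n`` relatedness matrix.

    Mild asymmetry (``<= 1e-6``) is symmetrized away; anything larger or a
    dimension mismatch is an error.
    """
    arr = np.loadtxt(path, dtype=float, ndmin=2)
    if arr.shape != (n, n):
        raise ValueError(
            f"{path}: expected a {n}x{n} matrix, got {arr.shape[0]}x{arr.shape[1]}"
        )
    asym = float(np.max(np.abs(arr - arr.T)))
    if asym > 1e-6:
        raise ValueError(f"{path}: asymmetry {asym:g} exceeds 1e-6")
    return Kinship(K=(arr + arr.T) / 2.0)


def write_kinship(kin: Kinship, path: PathLike) -> None:
    with open(path, "w") as fh:
        for row in kin.K:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
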