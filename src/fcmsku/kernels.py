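"""Candidate kernel construction over a pathway's SNP submatrix.

Three positive-semidefinite kernel families over subjects' genotype vectors:

* linear      k(x, y) = x'y + c
* gaussian    k(x, y) = exp(-||x - y||^2 / (2 sigma^2))
* polynomial  k(x, y) = (alpha x'y + c)^d

The Gaussian bandwidth may be left as the ``"median"`` sentinel, resolved by
the median heuristic sigma^2 = median_{i<j} ||x_i - x_j||^2 / 2.  Kernels are
centred (K -> HKH, H = I - 11'/n) before the U-statistic, which removes
grand-mean similarity and makes the statistic location-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "kernel_matrix",
    "median_heuristic_bandwidth",
    "center_kernel",
    "default_kernel_bundle",
    "parse_kernel_bundle",
]

FAMILIES = ("linear", "gaussian", "polynomial")


@dataclass(frozen=True)
class KernelSpec:
    """One candidate kernel family with its hyperparameters."""

    family: str
    c: float = 0.0
    sigma: Union[float, str] = "median"
    alpha: float = 1.0
    d: int = 2

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "gaussian":
            if not (self.sigma == "median" or (np.isreal(self.sigma) and self.sigma > 0)):
                raise ValueError("sigma must be positive or 'median'")
        if self.family == "polynomial":
            if self.d < 1:
                raise ValueError("polynomial degree d must be >= 1")
            if self.alpha <= 0 or self.c < 0:
                raise ValueError("polynomial needs alpha > 0 and c >= 0 for PSD")

    def label(self) -> str:
        if self.family == "linear":
            return f"linear(c={self.c:g})"
        if self.family == "gaussian":
            s = self.sigma if isinstance(self.sigma, str) else f"{self.sigma:g}"
            return f"gaussian(sigma={s})"
        return f"poly(d={self.d},alpha={self.alpha:g},c={self.c:g})"


@dataclass
class KernelMatrix:
    """Symmetric n x n kernel evaluations with provenance."""

    values: np.ndarray
    spec: KernelSpec
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")


def median_heuristic_bandwidth(X: np.ndarray) -> float:
    """Median-heuristic Gaussian bandwidth sigma.

    sigma^2 is the median of squared pairwise distances divided by 2, so the
    median pair gets kernel value exp(-1/2).  Zero distances (duplicate rows)
    are excluded from the median; all-identical rows raise.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    d2 = _sq_dists(X)
    iu = np.triu_indices_from(d2, k=1)
    pair = d2[iu]
    pair = pair[pair > 1e-12]
    if pair.size == 0:
        raise ValueError("all rows identical: bandwidth undefined")
    return float(np.sqrt(np.median(pair) / 2.0))


def _sq_dists(X: np.ndarray) -> np.ndarray:
    g = X @ X.T
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    return d2


def kernel_matrix(X: np.ndarray, spec: KernelSpec,
                  standardize: bool = False) -> KernelMatrix:
    """Evaluate one kernel over the rows of the genotype submatrix X.

    With ``standardize`` each SNP column is z-scored first; by default the
    additive 0/1/2 coding is used as-is.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be n x p with p >= 1 SNPs")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite genotype values")
    if standardize:
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("cannot standardize monomorphic SNP columns")
        X = (X - X.mean(axis=0)) / sd
    if spec.family == "linear":
        K = X @ X.T + spec.c
    elif spec.family == "gaussian":
        sigma = spec.sigma
        if sigma == "median":
            sigma = median_heuristic_bandwidth(X)
        K = np.exp(-_sq_dists(X) / (2.0 * float(sigma) ** 2))
    else:  # polynomial
        K = (spec.alpha * (X @ X.T) + spec.c) ** spec.d
    K = (K + K.T) / 2.0  # enforce exact symmetry
    return KernelMatrix(values=K, spec=spec, centered=False)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-centre: K -> HKH with H = I - 11'/n.  Idempotent."""
    V = K.values
    row = V.mean(axis=1, keepdims=True)
    col = V.mean(axis=0, keepdims=True)
    grand = V.mean()
    C = V - row - col + grand
    C = (C + C.T) / 2.0
    return KernelMatrix(values=C, spec=K.spec, centered=True)


def default_kernel_bundle() -> list[KernelSpec]:
    """The M = 3 candidate bundle: linear, median-bandwidth Gaussian,
    degree-2 polynomial."""
    return [
        KernelSpec("linear", c=0.0),
        KernelSpec("gaussian", sigma="median"),
        KernelSpec("polynomial", alpha=1.0, c=1.0, d=2),
    ]


def parse_kernel_bundle(text: str) -> list[KernelSpec]:
    """Parse a comma-separated bundle string.

    Grammar per item: ``linear``, ``gaussian[:sigma|median]``,
    ``poly:d[:alpha[:c]]``.  Example: ``linear,gaussian:median,poly:2``.
    """
    specs: list[KernelSpec] = []
    for raw in text.split(","):
        parts = raw.strip().split(":")
        name = parts[0].lower()
        if name == "linear":
            c = float(parts[1]) if len(parts) > 1 else 0.0
            specs.append(KernelSpec("linear", c=c))
        elif name == "gaussian":
            sigma: Union[float, str] = "median"
            if len(parts) > 1 and parts[1] != "median":
                sigma = float(parts[1])
            specs.append(KernelSpec("gaussian", sigma=sigma))
        elif name in ("poly", "polynomial"):
            if len(parts) < 2:
                raise ValueError("poly kernel needs a degree: poly:d[:alpha[:c]]")
            d = int(parts[1])
            alpha = float(parts[2]) if len(parts) > 2 else 1.0
            c = float(parts[3]) if len(parts) > 3 else 1.0
            specs.append(KernelSpec("polynomial", alpha=alpha, c=c, d=d))
        else:
            raise ValueError(f"unknown kernel family {name!r}")
    if not specs:
        raise ValueError("empty kernel bundle")
    return specs
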