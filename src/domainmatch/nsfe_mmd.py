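"""Quadratic-kernel MMD^2 between image domains and the NSFE normalization.

Maximum Mean Discrepancy (MMD) measures the distance between two probability
distributions as the distance between their kernel mean embeddings in a
reproducing kernel Hilbert space.  From finite samples X = {x_1..x_n} and
Y = {y_1..y_m} it is estimated from kernel sums:

    unbiased (U-statistic):
        MMD^2 = 1/(n(n-1)) sum_{i != j} k(x_i, x_j)
              + 1/(m(m-1)) sum_{i != j} k(y_i, y_j)
              - 2/(nm)     sum_{i, j}   k(x_i, y_j)

    biased (V-statistic): prefactors 1/n^2, 1/m^2 with diagonals included.

The kernel is fixed to the quadratic kernel k(x, y) = (x . y)^2, chosen
because the small appearance differences between egg domains live mostly in
second-moment (covariance-like) structure of the intensity features.  For
this kernel the biased estimator has a closed form: it equals the squared
Frobenius distance between the two empirical second-moment matrices

    MMD^2_biased = || (1/n) sum x_i x_i^T  -  (1/m) sum y_j y_j^T ||_F^2,

which this module exposes as an exact independent oracle.

NSFE-MMD (Normalized Squared Feature Estimation MMD) divides each raw
pairwise MMD^2 by the maximum off-diagonal pairwise value in the candidate
domain set, so distances are comparable across feature spaces and the most
dissimilar pair scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .imageio_features import FeatureMatrix

Estimator = Literal["unbiased", "biased"]


def quadratic_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """k(x, y) = (x . y)^2 — symmetric, nonnegative, bandwidth-free."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.dot(x, y) ** 2)


@dataclass(frozen=True)
class MMDEstimate:
    """One MMD^2 estimate between two sample sets.

    The unbiased U-statistic may be negative; ``clamped_value`` is
    max(raw_value, 0) and is what enters distance matrices.  The biased
    V-statistic is always >= 0.
    """

    raw_value: float
    estimator: Estimator
    n: int
    m: int

    @property
    def clamped_value(self) -> float:
        return max(self.raw_value, 0.0)


def _gram(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # quadratic kernel Gram block: squared dot products
    return (a @ b.T) ** 2


def mmd2(X: FeatureMatrix, Y: FeatureMatrix, estimator: Estimator = "unbiased") -> MMDEstimate:
    """Quadratic-kernel MMD^2 between two feature matrices.

    Both matrices must come from the same feature config (checked via the
    config hash).  The unbiased estimator needs n >= 2 and m >= 2; the biased
    one needs n >= 1 and m >= 1.
    """
    if X.d != Y.d:
        raise ValueError(f"dimension mismatch: {X.d} vs {Y.d}")
    if X.config_hash != Y.config_hash:
        raise ValueError(
            f"feature configs differ: {X.config_hash} vs {Y.config_hash}"
        )
    n, m = X.n, Y.n
    if estimator == "unbiased" and (n < 2 or m < 2):
        raise ValueError(f"unbiased estimator needs n, m >= 2 (got n={n}, m={m})")
    if estimator not in ("unbiased", "biased"):
        raise ValueError(f"unknown estimator {estimator!r}")

    kxx = _gram(X.values, X.values)
    kyy = _gram(Y.values, Y.values)
    kxy = _gram(X.values, Y.values)

    if estimator == "unbiased":
        xx = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
        yy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    else:
        xx = kxx.sum() / (n * n)
        yy = kyy.sum() / (m * m)
    xy = 2.0 * kxy.sum() / (n * m)
    return MMDEstimate(raw_value=float(xx + yy - xy), estimator=estimator, n=n, m=m)


def mmd2_frobenius_oracle(X: FeatureMatrix, Y: FeatureMatrix) -> float:
    """Closed-form check for the biased quadratic-kernel MMD^2.

    Returns ``|| (1/n) X^T X - (1/m) Y^T Y ||_F^2``, the squared Frobenius
    distance between the empirical second-moment matrices.  Agrees with
    ``mmd2(..., estimator="biased")`` to floating-point accuracy on any
    input; kept as an independent verification path.
    """
    if X.d != Y.d:
        raise ValueError(f"dimension mismatch: {X.d} vs {Y.d}")
    mx = X.values.T @ X.values / X.n
    my = Y.values.T @ Y.values / Y.n
    return float(np.sum((mx - my) ** 2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise domain-distance matrix, raw and NSFE-normalized.

    ``raw[i, j]`` holds the clamped MMD^2 between domains i and j;
    ``normalized`` divides by the maximum off-diagonal raw entry (when that
    maximum is positive), so entries lie in [0, 1] and the most dissimilar
    pair scores exactly 1.0.
    """

    domain_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray

    def entry(self, id_a: str, id_b: str, normalized: bool = True) -> float:
        i = self.domain_ids.index(id_a)
        j = self.domain_ids.index(id_b)
        mat = self.normalized if normalized else self.raw
        return float(mat[i, j])

    def off_diagonal(self, normalized: bool = True) -> np.ndarray:
        mat = self.normalized if normalized else self.raw
        iu = np.triu_indices(len(self.domain_ids), k=1)
        return mat[iu]

    def to_csv(self, path: str | Path, normalized: bool = True) -> None:
        """Serialize at full float precision; header row/column = domain ids."""
        mat = self.normalized if normalized else self.raw
        lines = ["domain," + ",".join(self.domain_ids)]
        for i, did in enumerate(self.domain_ids):
            lines.append(did + "," + ",".join(repr(float(v)) for v in mat[i]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        """Reload a serialized matrix; renormalizes from the stored entries
        (a no-op when the stored matrix was already normalized)."""
        lines = Path(path).read_text().strip().splitlines()
        ids = lines[0].split(",")[1:]
        raw = np.array([[float(v) for v in ln.split(",")[1:]] for ln in lines[1:]])
        if raw.shape != (len(ids), len(ids)):
            raise ValueError(f"{path}: malformed distance matrix")
        max_off = raw.max()
        normalized = raw / max_off if max_off > 0 else raw.copy()
        return cls(domain_ids=ids, raw=raw, normalized=normalized)

    def to_text_table(self, decimals: int = 2) -> str:
        """Human-readable pair table, rounded for display only."""
        lines = ["Domain Pair\tNSFE-MMD"]
        for i in range(len(self.domain_ids)):
            for j in range(i + 1, len(self.domain_ids)):
                val = round(float(self.normalized[i, j]), decimals)
                lines.append(f"{self.domain_ids[i]}-{self.domain_ids[j]}\t{val:g}")
        return "\n".join(lines)


def pairwise_nsfe_mmd(
    domains: Sequence[FeatureMatrix],
    estimator: Estimator = "unbiased",
) -> DistanceMatrix:
    """Pairwise NSFE-MMD distance matrix over a set of feature domains.

    Raw entries are clamped MMD^2 values (a distance must be nonnegative;
    the unbiased estimator can dip below zero on near-identical domains).
    Normalization divides by the maximum off-diagonal raw entry; if every
    raw entry is zero the normalized matrix is the (all-zero) raw matrix.
    """
    if len(domains) < 2:
        raise ValueError("need at least 2 domains for a distance matrix")
    hashes = {d.config_hash for d in domains}
    if len(hashes) != 1:
        raise ValueError(f"mixed feature configs: {sorted(hashes)}")
    ids = [d.domain_id for d in domains]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate domain ids: {ids}")

    k = len(domains)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            est = mmd2(domains[i], domains[j], estimator=estimator)
            raw[i, j] = raw[j, i] = est.clamped_value

    max_off = raw.max()
    normalized = raw / max_off if max_off > 0 else raw.copy()
    return DistanceMatrix(domain_ids=list(ids), raw=raw, normalized=normalized)
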