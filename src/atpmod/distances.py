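"""Co-evolution distance measures on binary phylogenetic profiles.

Six measures quantify how similarly two genes are gained and lost across a
species panel, each mapping a pair of presence/absence vectors X, Y in
{0,1}^n to a nonnegative distance:

* Minkowski L_p norm (p=1 Manhattan, p=2 Euclidean) — on binary vectors this
  is the Hamming mismatch count raised to 1/p.
* Jaccard distance, 1 - |X ∧ Y| / |X ∨ Y| over presences.
* Mutual-information distance, 1 - I(X;Y) with plug-in (empirical) cell
  probabilities and log base 2, so I <= 1 bit and the distance stays in [0,1].
* Kendall tau rank distance: the number of index pairs ordered oppositely in
  the two vectors, normalized by n(n-1)/2; tied pairs count as concordant.
* Pearson absolute anti-correlation distance, 1 - |cor(X,Y)|; a constant
  vector carries no correlation information and yields distance 1.

The matrix builder evaluates the same definitions from the 2x2 contingency
counts of every gene pair, so each matrix entry equals the pairwise operation
applied directly (including the diagonal: the mutual-information
self-distance is 1 - H(X), which is nonzero for unbalanced vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METHODS = (
    "euclidean",
    "manhattan",
    "jaccard",
    "mutual_information",
    "kendall_tau",
    "pearson_abs_anticorr",
)


def _as_binary(x) -> np.ndarray:
    arr = np.asarray(x)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("profile vectors must be binary (0/1)")
    return arr.astype(np.int64)


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = _as_binary(x), _as_binary(y)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError(
            f"length mismatch: {xa.shape} vs {ya.shape}; expected equal 1-D vectors"
        )
    return xa, ya


def minkowski_distance(x, y, p: float) -> float:
    """L_p norm of x - y; equals (Hamming count)**(1/p) on binary vectors."""
    if p <= 0:
        raise ValueError("Minkowski order p must be positive")
    xa, ya = _check_pair(x, y)
    return float(np.sum(np.abs(xa - ya) ** p) ** (1.0 / p))


def manhattan_distance(x, y) -> float:
    return minkowski_distance(x, y, 1)


def euclidean_distance(x, y) -> float:
    return minkowski_distance(x, y, 2)


def jaccard_distance(x, y) -> float:
    """1 - shared presences / union of presences; two all-absent profiles
    are identical, so the empty-union case returns 0 by convention."""
    xa, ya = _check_pair(x, y)
    inter = int(np.sum((xa == 1) & (ya == 1)))
    union = int(np.sum((xa == 1) | (ya == 1)))
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits (log base 2, 0·log0 := 0)."""
    xa, ya = _check_pair(x, y)
    n = xa.size
    if n < 1:
        raise ValueError("vectors must be nonempty")
    info = 0.0
    for xv in (0, 1):
        px = np.sum(xa == xv) / n
        for yv in (0, 1):
            pxy = np.sum((xa == xv) & (ya == yv)) / n
            py = np.sum(ya == yv) / n
            if pxy > 0:
                info += pxy * np.log2(pxy / (px * py))
    return max(info, 0.0)


def mutual_information_distance(x, y) -> float:
    return 1.0 - mutual_information(x, y)


def kendall_tau_distance(x, y) -> float:
    """Fraction of strictly discordant index pairs.

    A pair {i, j} is discordant iff the two elements are ordered oppositely
    in X and in Y; on binary vectors this counts i with (x,y)=(1,0) against
    j with (x,y)=(0,1).  Ties contribute nothing.  Normalized by n(n-1)/2.
    """
    xa, ya = _check_pair(x, y)
    n = xa.size
    if n < 2:
        raise ValueError("Kendall tau distance requires n >= 2")
    n10 = int(np.sum((xa == 1) & (ya == 0)))
    n01 = int(np.sum((xa == 0) & (ya == 1)))
    return (n10 * n01) / (n * (n - 1) / 2)


def pearson_anticorrelation_distance(x, y) -> float:
    """1 - |cor(X, Y)|; constant vectors yield 1 (no correlation signal)."""
    xa, ya = _check_pair(x, y)
    if xa.size < 2:
        raise ValueError("Pearson distance requires n >= 2")
    if xa.std() == 0 or ya.std() == 0:
        return 1.0
    return 1.0 - abs(float(np.corrcoef(xa, ya)[0, 1]))


_PAIRWISE = {
    "euclidean": euclidean_distance,
    "manhattan": manhattan_distance,
    "jaccard": jaccard_distance,
    "mutual_information": mutual_information_distance,
    "kendall_tau": kendall_tau_distance,
    "pearson_abs_anticorr": pearson_anticorrelation_distance,
}


def pairwise_distance(x, y, method: str, p: float | None = None) -> float:
    """Dispatch a single pairwise distance by method name."""
    if method not in _PAIRWISE:
        raise ValueError(f"unknown distance method {method!r}; choose from {METHODS}")
    if method in ("euclidean", "manhattan") and p is not None:
        return minkowski_distance(x, y, p)
    return _PAIRWISE[method](x, y)


@dataclass
class DistanceMatrix:
    """Symmetric gene x gene distance matrix tagged with its method."""

    gene_ids: list[str]
    values: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def condensed(self) -> np.ndarray:
        """Off-diagonal upper triangle in scipy condensed order."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.values[iu]


def distance_matrix(profiles: pd.DataFrame, method: str, p: float | None = None) -> DistanceMatrix:
    """All-pairs distances over a gene (rows) x species (columns) 0/1 matrix.

    Computed from the 2x2 contingency counts of every pair via matrix
    products; entries agree with the pairwise operations to floating-point
    round-off (asserted elementwise in the test suite).
    """
    if len(profiles.index) == 0:
        raise ValueError("empty gene set")
    if method not in _PAIRWISE:
        raise ValueError(f"unknown distance method {method!r}; choose from {METHODS}")
    M = _as_binary(profiles.to_numpy()).astype(float)
    g, s = M.shape
    n11 = M @ M.T
    n10 = M @ (1.0 - M).T
    n01 = n10.T
    n00 = s - n11 - n10 - n01

    if method == "manhattan":
        D = n10 + n01
        if p is not None and p != 1:
            raise ValueError("manhattan is the p=1 Minkowski distance")
    elif method == "euclidean":
        D = np.sqrt(n10 + n01)
    elif method == "jaccard":
        union = n11 + n10 + n01
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(union > 0, 1.0 - n11 / np.where(union > 0, union, 1), 0.0)
    elif method == "kendall_tau":
        if s < 2:
            raise ValueError("Kendall tau distance requires n >= 2 species")
        D = (n10 * n01) / (s * (s - 1) / 2)
    elif method == "mutual_information":
        rx = M.sum(axis=1)
        px1, px0 = rx / s, 1.0 - rx / s
        info = np.zeros((g, g))
        for joint, mx, my in (
            (n11, px1, px1), (n10, px1, px0), (n01, px0, px1), (n00, px0, px0),
        ):
            pj = joint / s
            denom = np.outer(mx, my)
            with np.errstate(invalid="ignore", divide="ignore"):
                term = pj * np.log2(np.where(pj > 0, pj / np.where(denom > 0, denom, 1), 1))
            info += np.where(pj > 0, term, 0.0)
        D = 1.0 - np.clip(info, 0.0, None)
    else:  # pearson_abs_anticorr
        rx = M.sum(axis=1)
        varx = s * rx - rx**2  # s^2 * population variance
        denom = np.sqrt(np.outer(varx, varx))
        num = s * n11 - np.outer(rx, rx)
        with np.errstate(invalid="ignore", divide="ignore"):
            cor = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
        D = np.where(denom > 0, 1.0 - np.abs(cor), 1.0)

    D = (D + D.T) / 2.0  # enforce exact symmetry against round-off
    return DistanceMatrix(list(profiles.index), D, method)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path, method: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), method)
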