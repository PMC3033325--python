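"""Entropy, mutual information and LD statistics for categorical markers.

All information quantities are plug-in (maximum-likelihood) estimates in
bits, with the convention 0·log 0 = 0.  These are the numeric substrate of
both the clustering step (pairwise MI matrices, quantile thresholds) and the
validation of latent variables (scaled MI, criterion C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_codes(x) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty vector")
    if x.ndim != 1:
        raise ValueError("expected a 1-D categorical vector")
    if not np.issubdtype(x.dtype, np.integer):
        _, x = np.unique(x, return_inverse=True)
    elif x.min() < 0:
        raise ValueError("negative category codes (missing data?) not allowed")
    return x.astype(np.int64, copy=False)


def entropy(column) -> float:
    """Plug-in Shannon entropy of a categorical vector, in bits."""
    x = _as_codes(column)
    counts = np.bincount(x)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def _mi_from_counts(counts: np.ndarray) -> float:
    """MI in bits from a joint contingency table of counts."""
    n = counts.sum()
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum())


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    kx = int(x.max()) + 1
    ky = int(y.max()) + 1
    joint = np.bincount(x * ky + y, minlength=kx * ky)
    return joint.reshape(kx, ky)


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two categorical vectors, in bits."""
    x = _as_codes(x)
    y = _as_codes(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return max(_mi_from_counts(_contingency(x, y)), 0.0)


def scaled_mutual_information(x, y) -> float:
    """MI normalised by the smaller marginal entropy; in [0, 1].

    When either variable is constant (entropy 0) the result is 0: a variable
    carrying no information is never counted as captured.
    """
    x = _as_codes(x)
    y = _as_codes(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    h = min(entropy(x), entropy(y))
    if h <= 0.0:
        return 0.0
    return min(mutual_information(x, y) / h, 1.0)


@dataclass
class MiMatrix:
    """Symmetric pairwise mutual-information matrix (bits), zero diagonal."""

    values: np.ndarray
    variable_ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("MI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("MI matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("MI entries must be non-negative")
        self.values = v


def pairwise_mi_matrix(data, variable_ids=None) -> MiMatrix:
    """All-pairs MI over the columns of an ``n × p`` categorical matrix."""
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    p = data.shape[1]
    cols = [_as_codes(data[:, j]) for j in range(p)]
    cards = [int(c.max()) + 1 for c in cols]
    out = np.zeros((p, p))
    for i in range(p):
        xi, ki = cols[i], cards[i]
        for j in range(i + 1, p):
            counts = np.bincount(xi * cards[j] + cols[j],
                                 minlength=ki * cards[j]).reshape(ki, cards[j])
            out[i, j] = out[j, i] = max(_mi_from_counts(counts), 0.0)
    ids = list(variable_ids) if variable_ids is not None else list(range(p))
    return MiMatrix(out, ids)


def mi_quantile_threshold(mi: MiMatrix, q: float) -> float:
    """Nearest-rank q-quantile of the strictly-upper-triangle MI entries."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must lie in [0, 1], got {q}")
    iu = np.triu_indices(mi.values.shape[0], k=1)
    entries = np.sort(mi.values[iu])
    if entries.size == 0:
        return 0.0
    rank = min(int(np.ceil(q * entries.size)) - 1, entries.size - 1)
    return float(entries[max(rank, 0)])


def r_squared(x, y) -> float:
    """Squared Pearson correlation of the numeric allele/dosage codes.

    On {0,1} haplotypes this is the standard allelic r²; on {0,1,2}
    genotypes it is the composite r².  Undefined (raises) for constant
    columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r² undefined for a constant column")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))
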