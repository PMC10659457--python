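"""Functional network connectivity and the DMN weighted clustering coefficient.

The brain outcome used downstream is a single scalar per subject: the
average weighted clustering coefficient over the 7 default-mode-network
(DMN) nodes of the 53-node intrinsic-connectivity-network (ICN) graph.

Given ICN time courses (53 x T), functional network connectivity (FNC) is
the matrix of pairwise Pearson correlations.  The graph is kept fully
weighted (no proportional thresholding).  Correlations are mapped to edge
weights either as |r| (default) or max(r, 0), then normalized by the
maximum off-diagonal weight, and the per-node clustering coefficient uses
the Onnela geometric-mean triangle intensity:

    C_i = sum_{j != h} (w~_ij w~_jh w~_ih)^(1/3) / (k_i (k_i - 1))

with k_i the number of nonzero-weight neighbors of i.  On {0,1} weights
this reduces to the binary clustering coefficient; C_i is in [0, 1].
Nodes with fewer than two neighbors get C_i = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_N_ICNS",
    "DMN_SIZE",
    "DEFAULT_DMN_INDICES",
    "FNCMatrix",
    "compute_fnc",
    "clustering_weights",
    "clustering_coefficient",
    "all_clustering_coefficients",
    "dmn_clustering",
    "dmn_clustering_batch",
]

DEFAULT_N_ICNS = 53
DMN_SIZE = 7
#: default positions of the 7 DMN nodes within the 53-ICN ordering
DEFAULT_DMN_INDICES: tuple[int, ...] = (23, 24, 25, 26, 27, 28, 29)

_DOMAINS = (
    "subcortical",
    "auditory",
    "sensorimotor",
    "visual",
    "cognitive_control",
    "default_mode",
    "cerebellar",
)


def default_domain_of(
    n_icns: int = DEFAULT_N_ICNS,
    dmn_indices: tuple[int, ...] = DEFAULT_DMN_INDICES,
) -> dict[int, str]:
    """Node→domain map: DMN nodes labelled default_mode, the rest cycled."""
    others = [d for d in _DOMAINS if d != "default_mode"]
    out = {}
    j = 0
    for i in range(n_icns):
        if i in dmn_indices:
            out[i] = "default_mode"
        else:
            out[i] = others[j % len(others)]
            j += 1
    return out


@dataclass
class FNCMatrix:
    """Symmetric ICN correlation matrix with node metadata."""

    values: np.ndarray
    node_labels: tuple[str, ...] = ()
    domain_of: dict[int, str] = field(default_factory=dict)
    dmn_indices: tuple[int, ...] = DEFAULT_DMN_INDICES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FNC values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FNC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FNC diagonal must be 1")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1 + 1e-10):
            raise ValueError("FNC off-diagonals must lie in [-1, 1]")
        self.values = v
        self.dmn_indices = tuple(int(i) for i in self.dmn_indices)
        n = v.shape[0]
        if any(not 0 <= i < n for i in self.dmn_indices):
            raise ValueError("dmn_indices out of range")
        if len(set(self.dmn_indices)) != len(self.dmn_indices):
            raise ValueError("dmn_indices must be distinct")
        if not self.node_labels:
            self.node_labels = tuple(f"ICN{i:02d}" for i in range(n))
        if not self.domain_of:
            self.domain_of = default_domain_of(n, self.dmn_indices)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_fnc(
    timeseries: np.ndarray,
    dmn_indices: tuple[int, ...] = DEFAULT_DMN_INDICES,
) -> FNCMatrix:
    """Pearson-correlation FNC of an (n_icns x T) time-course matrix."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (nodes x time)")
    if ts.shape[1] < 3:
        raise ValueError("need T >= 3 time points to correlate")
    sd = ts.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant time course at node {int(flat[0])}")
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return FNCMatrix(values=r, dmn_indices=dmn_indices)


def clustering_weights(fnc: FNCMatrix, weight_mode: str = "abs") -> np.ndarray:
    """Edge-weight matrix: transformed correlations, zero diagonal,
    normalized by the maximum off-diagonal weight."""
    if weight_mode == "abs":
        w = np.abs(fnc.values.copy())
    elif weight_mode == "positive":
        w = np.maximum(fnc.values, 0.0)
    else:
        raise ValueError(f"weight_mode must be 'abs' or 'positive', got {weight_mode!r}")
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    return w


def _onnela(w: np.ndarray) -> np.ndarray:
    """Per-node Onnela clustering for a normalized weight matrix."""
    w13 = np.cbrt(w)
    tri = np.einsum("ij,jh,hi->i", w13, w13, w13)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(w.shape[0])
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def all_clustering_coefficients(
    fnc: FNCMatrix, weight_mode: str = "abs"
) -> np.ndarray:
    """Vector of C_i for every node of the full graph."""
    return _onnela(clustering_weights(fnc, weight_mode))


def clustering_coefficient(
    fnc: FNCMatrix, node: int, weight_mode: str = "abs"
) -> float:
    """Onnela weighted clustering coefficient of one node; in [0, 1]."""
    if not 0 <= node < fnc.n_nodes:
        raise ValueError(f"node {node} out of range")
    return float(all_clustering_coefficients(fnc, weight_mode)[node])


def dmn_clustering(fnc: FNCMatrix, weight_mode: str = "abs") -> float:
    """Unweighted mean of C_i over the DMN nodes, on the full graph."""
    c = all_clustering_coefficients(fnc, weight_mode)
    return float(c[list(fnc.dmn_indices)].mean())


def dmn_clustering_batch(
    series: np.ndarray,
    dmn_indices: tuple[int, ...] = DEFAULT_DMN_INDICES,
    weight_mode: str = "abs",
) -> np.ndarray:
    """Vectorized per-subject DMN clustering for (n_subjects, n_icns, T) data.

    Equivalent to ``dmn_clustering(compute_fnc(x))`` subject by subject but
    computed with batched matrix products (one large einsum instead of a
    Python loop), so whole cohorts run in seconds.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 3:
        raise ValueError("series must be (n_subjects, n_icns, T)")
    n_sub, n_icns, T = x.shape
    if T < 3:
        raise ValueError("need T >= 3 time points to correlate")
    xc = x - x.mean(axis=2, keepdims=True)
    sd = xc.std(axis=2)
    if np.any(sd == 0):
        s, i = np.argwhere(sd == 0)[0]
        raise ValueError(f"constant time course at subject {s}, node {i}")
    xn = xc / (sd[:, :, None] * np.sqrt(T))
    r = np.einsum("sit,sjt->sij", xn, xn)
    r = np.clip(r, -1.0, 1.0)
    if weight_mode == "abs":
        w = np.abs(r)
    elif weight_mode == "positive":
        w = np.maximum(r, 0.0)
    else:
        raise ValueError(f"weight_mode must be 'abs' or 'positive', got {weight_mode!r}")
    eye = np.eye(n_icns, dtype=bool)
    w[:, eye] = 0.0
    wmax = w.max(axis=(1, 2))
    wmax[wmax == 0] = 1.0
    w = w / wmax[:, None, None]
    w13 = np.cbrt(w)
    tri = np.einsum("sij,sjh,shi->si", w13, w13, w13)
    k = (w > 0).sum(axis=2)
    denom = k * (k - 1)
    c = np.zeros((n_sub, n_icns))
    ok = denom > 0
    c[ok] = tri[ok] / denom[ok]
    return c[:, list(dmn_indices)].mean(axis=1)
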