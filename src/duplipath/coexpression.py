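"""Weighted gene co-expression network core and regulator screening.

Implements the standard weighted co-expression construction from scratch:
an unsigned adjacency a_ij = |cor_ij|^beta with the soft threshold beta
chosen for scale-free topology fit (R^2 > 0.85), the topological overlap
matrix (TOM), average-linkage module detection on 1 - TOM with eigengene
merging, and extraction of regulator->target edges above a weighted-edge
cutoff (default 0.2) with the regulation sign taken from the underlying
Pearson correlation (positive = activation, negative = repression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SoftThresholdReport",
    "NetworkMatrices",
    "RegulatoryEdge",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "extract_regulator_edges",
    "export_network",
    "read_network",
]

DEFAULT_POWERS = tuple(range(1, 21))
RSQ_TARGET = 0.85
EDGE_CUTOFF = 0.2


def _pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlations (genes are rows, samples columns).

    Constant-expression genes have undefined correlations and must be dropped
    by the caller beforehand.
    """
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=1))
    cor = (x @ x.T) / np.outer(norms, norms)
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero variance across samples (warns if any)."""
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant-expression gene(s)",
            stacklevel=2,
        )
    return expr.loc[~constant]


def adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency |Pearson r|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("soft-threshold power beta must be >= 1")
    cor = _pearson_matrix(expr)
    adj = np.abs(cor.to_numpy()) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression over binned connectivity.

    The scale-free topology criterion: if the degree distribution follows a
    power law, the log-log relation between connectivity and its density is
    linear.  Bins are quantile-based (equal gene counts) and the density is
    count / (n * bin width), which keeps the sparse high-connectivity tail
    from dominating the fit; returns 0 when fewer than 3 informative bins
    remain.
    """
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    xs, ys = [], []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        members = (k >= lo) & ((k < hi) if i < len(edges) - 2 else (k <= hi))
        width = hi - lo
        if members.sum() == 0 or width <= 0:
            continue
        xs.append(np.log10(k[members].mean()))
        ys.append(np.log10(members.sum() / (k.size * width)))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(np.asarray(xs), np.asarray(ys))[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r**2)


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # power, rsq, mean_connectivity, median_connectivity
    chosen_power: int
    rsq_target: float
    target_met: bool

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: tuple[int, ...] = DEFAULT_POWERS,
    rsq_target: float = RSQ_TARGET,
    min_samples: int = 15,
    min_genes: int = 50,
) -> SoftThresholdReport:
    """Choose the soft-threshold power for scale-free topology.

    Picks the smallest candidate power whose scale-free fit R^2 exceeds
    ``rsq_target``; if none qualifies, falls back to the power maximizing R^2
    with a warning.  Fewer than ``min_samples`` samples triggers a warning
    (correlations become unstable); fewer than ``min_genes`` genes is an
    error.
    """
    expr = drop_constant_genes(expr)
    if expr.shape[0] < min_genes:
        raise ValueError(f"need at least {min_genes} genes, got {expr.shape[0]}")
    if expr.shape[1] < min_samples:
        warnings.warn(
            f"only {expr.shape[1]} samples; co-expression estimates below "
            f"{min_samples} samples are unreliable",
            stacklevel=2,
        )
    cor_abs = np.abs(_pearson_matrix(expr).to_numpy())
    np.fill_diagonal(cor_abs, 0.0)

    rows = []
    for power in powers:
        a = cor_abs**power
        k = a.sum(axis=1)
        rows.append(
            {
                "power": power,
                "rsq": _scale_free_fit(k),
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
            }
        )
    table = pd.DataFrame(rows)
    qualifying = table[table["rsq"] > rsq_target]
    if len(qualifying) > 0:
        chosen = int(qualifying["power"].iloc[0])
        met = True
    else:
        chosen = int(table.loc[table["rsq"].idxmax(), "power"])
        met = False
        warnings.warn(
            f"no candidate power reached R^2 > {rsq_target}; "
            f"using power {chosen} with the best fit",
            stacklevel=2,
        )
    return SoftThresholdReport(table=table, chosen_power=chosen, rsq_target=rsq_target, target_met=met)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from a symmetric adjacency in [0, 1].

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_{u != i,j} a_iu * a_uj and k_i = sum_{u != i} a_iu; the
    diagonal is 1.  Two genes overlap strongly when they are directly
    connected and share neighbors.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if (a < 0).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # (A @ A)_ij counts paths through every u, including u = i or j; with a
    # zero diagonal those terms vanish, so l_ij = (A @ A)_ij directly.
    l = a @ a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module id; 0 = unassigned
    eigengenes: pd.DataFrame  # samples x modules

    @property
    def n_modules(self) -> int:
        return int((pd.unique(self.labels) != 0).sum())


def _eigengene(expr_block: pd.DataFrame) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Sign-anchored so that the eigengene correlates positively with the mean
    module profile (PCA sign is otherwise arbitrary).
    """
    x = expr_block.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    x = x / sd[:, None]
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc1 = vt[0]
    if np.corrcoef(pc1, x.mean(axis=0))[0, 1] < 0:
        pc1 = -pc1
    return pc1


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_threshold: float = 0.75,
) -> ModuleAssignment:
    """Average-linkage module detection on the TOM dissimilarity 1 - TOM.

    The dendrogram is cut at ``cut_height``; clusters below
    ``min_module_size`` go to the unassigned label 0; modules whose eigengenes
    (first principal components) correlate above ``merge_threshold`` are
    merged iteratively.  Labels are renumbered 1..n by decreasing size.
    """
    genes = list(tom.index)
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=genes, dtype=int)
    sizes = labels.value_counts()
    small = sizes[sizes < min_module_size].index
    labels[labels.isin(small)] = 0

    labels = _merge_by_eigengene(labels, expr, merge_threshold)

    # renumber by decreasing size, 0 stays unassigned
    sizes = labels[labels != 0].value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    remap[0] = 0
    labels = labels.map(remap).astype(int)

    eig = {}
    for mod in sorted(set(labels) - {0}):
        members = labels.index[labels == mod]
        eig[mod] = _eigengene(expr.loc[members])
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    return ModuleAssignment(labels=labels, eigengenes=eigengenes)


def _merge_by_eigengene(labels: pd.Series, expr: pd.DataFrame, threshold: float) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        eig = {m: _eigengene(expr.loc[labels.index[labels == m]]) for m in mods}
        best = None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1 :]:
                r = np.corrcoef(eig[m1], eig[m2])[0, 1]
                if r > threshold and (best is None or r > best[0]):
                    best = (r, m1, m2)
        if best is None:
            return labels
        _, m1, m2 = best
        labels[labels == m2] = m1


@dataclass(frozen=True)
class RegulatoryEdge:
    regulator: str
    target: str
    weight: float
    sign: str  # positive | negative

    @property
    def interaction(self) -> str:
        return "activates" if self.sign == "positive" else "represses"


@dataclass
class NetworkMatrices:
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    beta: int

    @classmethod
    def from_expression(cls, expr: pd.DataFrame, beta: int) -> "NetworkMatrices":
        expr = drop_constant_genes(expr)
        cor = _pearson_matrix(expr)
        adj = pd.DataFrame(
            np.abs(cor.to_numpy()) ** beta, index=cor.index, columns=cor.columns
        )
        np.fill_diagonal(adj.values, 1.0)
        return cls(correlation=cor, adjacency=adj, tom=tom_similarity(adj), beta=beta)


def extract_regulator_edges(
    net: NetworkMatrices,
    targets: list[str],
    regulators: list[str],
    cutoff: float = EDGE_CUTOFF,
) -> list[RegulatoryEdge]:
    """Regulator->target edges whose TOM weight reaches the cutoff.

    The edge weight is the topological-overlap value; the regulation sign is
    the sign of the plain Pearson correlation (positive = activation shown as
    a solid line in network viewers, negative = repression shown dashed).
    """
    present = set(net.tom.index)
    missing = [g for g in list(targets) + list(regulators) if g not in present]
    if missing:
        raise KeyError(f"genes absent from network matrices: {missing[:10]}")
    edges = []
    for t in targets:
        for r in regulators:
            if r == t:
                continue
            w = float(net.tom.loc[r, t])
            if w >= cutoff:
                sign = "positive" if float(net.correlation.loc[r, t]) >= 0 else "negative"
                edges.append(RegulatoryEdge(regulator=r, target=t, weight=w, sign=sign))
    return edges


def export_network(edges: list[RegulatoryEdge], sif_path: str | Path, attr_path: str | Path) -> None:
    """Write a Cytoscape SIF file plus a TSV edge-attribute table.

    SIF lines read ``regulator<TAB>activates|represses<TAB>target``; the
    attribute file stores weights at 6 decimals so a write->read round trip
    preserves them.
    """
    if not edges:
        raise ValueError("refusing to export an empty edge list")
    with open(sif_path, "w") as fh:
        for e in edges:
            fh.write(f"{e.regulator}\t{e.interaction}\t{e.target}\n")
    pd.DataFrame(
        {
            "regulator": [e.regulator for e in edges],
            "target": [e.target for e in edges],
            "weight": [round(e.weight, 6) for e in edges],
            "sign": [e.sign for e in edges],
        }
    ).to_csv(attr_path, sep="\t", index=False, float_format="%.6f")


def read_network(attr_path: str | Path) -> list[RegulatoryEdge]:
    df = pd.read_csv(attr_path, sep="\t")
    return [
        RegulatoryEdge(
            regulator=row.regulator, target=row.target, weight=float(row.weight), sign=row.sign
        )
        for row in df.itertuples(index=False)
    ]
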