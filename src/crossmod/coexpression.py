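"""Weighted co-expression network construction and module detection.

Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with the soft power chosen
by the scale-free topology criterion, topological overlap as the clustering
similarity, average-linkage hierarchical clustering with a static branch
cut (minimum module size 30), module eigengenes as first principal
components, and eigengene-correlation module merging at height 0.25.
Modules are named with the conventional WGCNA color sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix

log = logging.getLogger(__name__)

GREY = "grey"

# Standard WGCNA module color order (labels2colors), for interoperability of
# outputs with the field's module-naming convention.
WGCNA_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "mediumorchid", "magenta4", "skyblue1", "honeydew1", "lightyellow4",
]


@dataclass
class Network:
    """Unsigned weighted network: adjacency in [0,1] with unit diagonal."""

    genes: list[str]
    adjacency: np.ndarray
    soft_power: int

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency values must lie in [0, 1]")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("adjacency diagonal must be 1")

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1) - np.diag(self.adjacency)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes (scipy linkage encoding)."""

    genes: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        if not self.leaf_order:
            self.leaf_order = leaves_list(self.linkage_matrix).tolist()


@dataclass
class ModuleAssignment:
    """Gene -> module label map; "grey" marks unassigned genes."""

    labels: dict[str, str]

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, label in self.labels.items():
            out.setdefault(label, []).append(gene)
        return out

    def non_grey(self) -> dict[str, list[str]]:
        return {m: g for m, g in self.modules().items() if m != GREY}

    def relabel(self, mapping: dict[str, str]) -> "ModuleAssignment":
        return ModuleAssignment(
            {g: mapping.get(lab, lab) for g, lab in self.labels.items()}
        )


def _abs_cor(values: np.ndarray) -> np.ndarray:
    sds = values.std(axis=1)
    if (sds == 0).any():
        raise ValueError("zero-variance genes present; filter upstream")
    c = np.corrcoef(values)
    return np.clip(np.abs(c), 0.0, 1.0)


def compute_adjacency(expr: ExpressionMatrix, soft_power: int = 8) -> Network:
    """Unsigned adjacency |pearson|^power with unit diagonal."""
    if len(expr.samples) < 3:
        raise ValueError("compute_adjacency requires >= 3 samples")
    values = expr.values
    sds = values.std(axis=1)
    if (sds == 0).any():
        bad = [g for g, s in zip(expr.genes, sds) if s == 0]
        raise ValueError(f"zero-variance genes: {bad[:10]}")
    a = _abs_cor(values) ** soft_power
    np.fill_diagonal(a, 1.0)
    return Network(expr.genes, a, soft_power)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit R^2 and slope of log10 p(k) vs log10 k.

    Connectivities are split into equal-occupancy bins; p(k) is the
    empirical density in each bin (bin fraction / bin width) so the fit is
    meaningful for equal-count bins. R^2 is negated when the slope is
    positive (scale-free topology requires a decreasing density).
    """
    k = np.sort(np.asarray(connectivity, float))
    if np.allclose(k, k[0]):
        raise ValueError("all connectivities identical; scale-free fit undefined")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        raise ValueError("too few distinct connectivity values to bin")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        mask = idx == b
        if not mask.any():
            continue
        width = edges[b + 1] - edges[b]
        if width <= 0:
            continue
        mean_k = k[mask].mean()
        density = mask.mean() / width
        if mean_k > 0 and density > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(density))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity distribution")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = ((ys - fitted) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    signed = -r2 if slope > 0 else r2
    return float(signed), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: list[int] | None = None,
    r2_target: float = 0.85,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power whose signed scale-free fit R^2 reaches the
    target; falls back to the best power with a warning when none does."""
    if len(expr.genes) < 30:
        raise ValueError("pick_soft_threshold requires >= 30 genes")
    powers = list(powers) if powers is not None else list(range(1, 21))
    cor = _abs_cor(expr.values)
    rows = []
    for power in powers:
        a = cor ** power
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        signed_r2, slope = scale_free_fit(k)
        rows.append(
            {"power": power, "signed_r2": signed_r2, "slope": slope,
             "mean_k": float(k.mean()), "max_k": float(k.max())}
        )
    fit = pd.DataFrame(rows)
    reaching = fit[fit["signed_r2"] >= r2_target]
    if len(reaching):
        chosen = int(reaching.iloc[0]["power"])
    else:
        chosen = int(fit.loc[fit["signed_r2"].idxmax(), "power"])
        log.warning(
            "no power reached signed R^2 >= %.2f; using best power %d (R^2=%.3f)",
            r2_target, chosen, fit["signed_r2"].max(),
        )
    return chosen, fit


def compute_tom(net: Network) -> tuple[np.ndarray, np.ndarray]:
    """Topological overlap matrix and its dissimilarity 1 - TOM.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u != i, j and unit diagonal.
    """
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a  # with zero diagonal this is sum over u != i, j
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    return tom, 1.0 - tom


def cluster_and_cut(
    dissimilarity: np.ndarray,
    genes: list[str],
    min_size: int = 30,
    cut_height: float | None = None,
    cut_height_frac: float = 0.995,
) -> tuple[Dendrogram, ModuleAssignment]:
    """Average-linkage clustering with a static branch cut.

    Branches below the cut height with >= ``min_size`` genes become modules,
    labeled by decreasing size with the WGCNA color sequence; all other
    genes are "grey". The cut height defaults to ``cut_height_frac`` times
    the maximum merge height.
    """
    d = np.asarray(dissimilarity, float)
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="average")
    dend = Dendrogram(list(genes), Z)
    if min_size > len(genes):
        log.warning("min_size %d exceeds gene count %d; all genes grey",
                    min_size, len(genes))
        return dend, ModuleAssignment({g: GREY for g in genes})
    height = cut_height if cut_height is not None else cut_height_frac * Z[:, 2].max()
    branch = fcluster(Z, t=height, criterion="distance")
    sizes: dict[int, int] = {}
    first_idx: dict[int, int] = {}
    for i, b in enumerate(branch):
        sizes[b] = sizes.get(b, 0) + 1
        first_idx.setdefault(b, i)
    eligible = [b for b, s in sizes.items() if s >= min_size]
    # deterministic: big modules first, ties by first gene position
    eligible.sort(key=lambda b: (-sizes[b], first_idx[b]))
    color_of: dict[int, str] = {}
    for rank, b in enumerate(eligible):
        color_of[b] = (
            WGCNA_COLORS[rank] if rank < len(WGCNA_COLORS) else f"module{rank + 1}"
        )
    labels = {g: color_of.get(b, GREY) for g, b in zip(genes, branch)}
    return dend, ModuleAssignment(labels)


def compute_eigengenes(
    expr: ExpressionMatrix, assignment: ModuleAssignment
) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes: per-module first principal component over samples.

    Member genes are standardized across samples first; the eigengene is
    scaled to unit (sample) variance and oriented so its mean correlation
    with member expression is nonnegative. Also returns the fraction of
    module variance each eigengene explains.
    """
    data = expr.data
    me_rows = {}
    var_expl = {}
    for module, genes in sorted(assignment.non_grey().items()):
        sub = data.loc[genes].to_numpy(dtype=float)
        sds = sub.std(axis=1, ddof=1)
        if (sds == 0).any():
            bad = [g for g, s in zip(genes, sds) if s == 0]
            raise ValueError(f"module {module}: zero-variance genes {bad[:5]}")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sds[:, None]
        U, S, Vt = np.linalg.svd(z, full_matrices=False)
        me = Vt[0]
        me = me / me.std(ddof=1)
        cors = (z @ me) / (np.linalg.norm(z, axis=1) * np.linalg.norm(me))
        if cors.mean() < 0:
            me = -me
        me_rows[module] = me
        var_expl[module] = float(S[0] ** 2 / (S ** 2).sum())
    if not me_rows:
        raise ValueError("no non-grey modules to summarize")
    me_df = pd.DataFrame(me_rows, index=expr.samples).T
    me_df.index.name = "module"
    return me_df, pd.Series(var_expl, name="variance_explained")


def merge_close_modules(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    merge_height: float = 0.25,
) -> tuple[ModuleAssignment, pd.DataFrame]:
    """Iteratively merge module pairs whose eigengene dissimilarity
    (1 - correlation) is below ``merge_height``; the merged module keeps the
    larger module's label and eigengenes are recomputed after each merge."""
    assignment = ModuleAssignment(dict(assignment.labels))
    while True:
        me, _ = compute_eigengenes(expr, assignment)
        if len(me) < 2:
            break
        modules = me.index.tolist()
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            break
        sizes = {m: len(g) for m, g in assignment.non_grey().items()}
        a, b = modules[i], modules[j]
        if sizes[a] > sizes[b] or (sizes[a] == sizes[b] and a <= b):
            keep, drop = a, b
        else:
            keep, drop = b, a
        log.info("merging module %s into %s (eigengene cor %.3f)", drop, keep, cor[i, j])
        assignment = assignment.relabel({drop: keep})
    me, _ = compute_eigengenes(expr, assignment)
    return assignment, me
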