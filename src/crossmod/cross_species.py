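"""Mouse-to-human module comparison: the package's core analysis.

Two complementary views of cross-species agreement:

* **Set overlap** — the Jaccard index between a mouse module (mapped
  through orthologs) and a human module, with an empirical p-value from a
  permutation null that redraws the mouse module from the union of all
  mouse module genes (10,000 draws by default).
* **Directional concordance** — per gene, the perturbation effect beta of
  each mutant strain from the regression log2(expr) = beta0 + sum_i beta_i
  + eps (control as reference), correlated with the human log2FC(AD/control)
  over the genes of each human module (Pearson, BH across all
  strain x module x region tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, HumanLFCTable, OrthologMap, SampleMetadata
from .stats import adjust_bh, pearson_cor_test

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class OverlapResult:
    """One mouse-module x human-module overlap record."""

    mouse_module: str
    human_module: str
    jaccard: float
    intersection: int
    p: float
    n_perm: int


@dataclass
class PerturbationEffects:
    """Per-gene strain effects from the one-hot perturbation regression."""

    betas: pd.DataFrame       # genes x strains (log2 units)
    intercept: pd.Series
    sigma: pd.Series
    n: int


@dataclass(frozen=True)
class ConcordanceResult:
    """Directional concordance of one (strain, human module, region)."""

    strain: str
    human_module: str
    region: str
    r: float
    p: float
    n: int
    untestable: bool = False


def map_orthologs(
    mouse_genes,
    omap: OrthologMap,
    policy: str = "all_pairs",
) -> pd.DataFrame:
    """Mouse->human pairs for a gene set under a mapping policy.

    ``all_pairs`` keeps every mapped pair (used for set overlap);
    ``one_to_one`` keeps only genes with a unique partner in both directions
    (used for correlations, avoiding pseudo-replicated observations).
    """
    if policy not in ("all_pairs", "one_to_one"):
        raise ValueError(f"unknown mapping policy {policy!r}")
    genes = set(mouse_genes)
    tab = omap.table
    sub = tab[tab["mouse"].isin(genes)][["mouse", "human"]]
    if policy == "one_to_one":
        mouse_deg = tab["mouse"].value_counts()
        human_deg = tab["human"].value_counts()
        ok = sub["mouse"].map(mouse_deg).eq(1) & sub["human"].map(human_deg).eq(1)
        sub = sub[ok]
    n_unmapped = len(genes) - sub["mouse"].nunique()
    if n_unmapped:
        log.info("map_orthologs(%s): %d of %d genes unmapped",
                 policy, n_unmapped, len(genes))
    if sub.empty:
        raise ValueError("no mouse genes could be mapped to human orthologs")
    return sub.reset_index(drop=True)


def jaccard(a, b) -> float:
    """|a intersect b| / |a union b|; empty union gives 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def permutation_overlap_test(
    mouse_module,
    human_module,
    mouse_universe,
    omap: OrthologMap,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    mouse_name: str = "mouse",
    human_name: str = "human",
) -> OverlapResult:
    """Jaccard overlap with an empirical permutation p-value.

    The observed statistic maps the mouse module to human gene space
    (all-pairs policy) and takes the Jaccard index with the human module.
    Null draws sample the same number of genes without replacement from the
    union of all mouse module genes and are mapped and scored identically.
    p uses the add-one estimator (1 + #{J_null >= J_obs}) / (n_perm + 1).
    """
    module = set(mouse_module)
    human = frozenset(human_module)
    universe = sorted(set(mouse_universe))  # sort: p invariant to input order
    if not module <= set(universe):
        raise ValueError("mouse module must be a subset of the mouse universe")
    if len(module) > len(universe):
        raise ValueError("module larger than universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    partners = omap.human_partners()

    def mapped_jaccard(genes) -> tuple[float, int]:
        mapped: set[str] = set()
        for g in genes:
            mapped.update(partners.get(g, ()))
        inter = len(mapped & human)
        union = len(mapped | human)
        return (inter / union if union else 0.0), inter

    j_obs, intersection = mapped_jaccard(module)
    m = len(module)
    universe_arr = np.asarray(universe, dtype=object)
    n_ge = 0
    for _ in range(n_perm):
        draw = rng.choice(universe_arr, size=m, replace=False)
        j_null, _ = mapped_jaccard(draw)
        if j_null >= j_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (n_perm + 1.0)
    return OverlapResult(mouse_name, human_name, float(j_obs), intersection,
                         float(p), n_perm)


def overlap_table(
    mouse_modules: dict[str, list[str]],
    human_catalog: dict[str, frozenset[str]] | dict[str, set[str]],
    omap: OrthologMap,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """All mouse x human module overlaps with BH across every pair.

    The mouse universe is the union of all mouse module genes, matching the
    permutation null's stated sampling frame.
    """
    universe = sorted(set().union(*mouse_modules.values()))
    rng = np.random.default_rng(seed)
    rows = []
    for m_name in sorted(mouse_modules):
        for h_name in sorted(human_catalog):
            res = permutation_overlap_test(
                mouse_modules[m_name], human_catalog[h_name], universe, omap,
                n_perm=n_perm, seed=rng, mouse_name=m_name, human_name=h_name,
            )
            rows.append(
                {"mouse_module": m_name, "human_module": h_name,
                 "jaccard": res.jaccard, "intersection": res.intersection,
                 "p": res.p, "n_perm": res.n_perm}
            )
    table = pd.DataFrame(rows)
    table["padj"] = adjust_bh(table["p"].to_numpy())
    return table


def fit_perturbation_model(
    log_expr: ExpressionMatrix,
    meta: SampleMetadata,
    with_batch: bool = False,
) -> PerturbationEffects:
    """Per-gene OLS of log2 expression on strain indicators.

    Control is the reference level, so with the one-hot design each beta_i
    is the strain-i mean minus the control mean (in log2 units). Batch
    indicators are optional and off by default, matching the plain
    perturbation model; the design must be full rank.
    """
    if log_expr.scale_tag != "log2tpm":
        raise ValueError("fit_perturbation_model expects a log2tpm matrix")
    meta.validate_against(log_expr)
    tab = meta.table.loc[log_expr.samples]
    strains = [s for s in dict.fromkeys(tab["strain"]) if s != meta.control]
    if not strains:
        raise ValueError("no non-control strains present")
    counts = tab["strain"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        raise ValueError(f"strains need >= 2 samples: {small}")
    cols = {"intercept": np.ones(len(tab))}
    for s in strains:
        cols[s] = (tab["strain"] == s).to_numpy(float)
    if with_batch:
        for b in list(dict.fromkeys(tab["batch"]))[1:]:
            cols[f"batch_{b}"] = (tab["batch"] == b).to_numpy(float)
    X = pd.DataFrame(cols, index=tab.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = []
        base = X.to_numpy()
        for j, c in enumerate(X.columns):
            reduced = np.delete(base, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    Y = log_expr.values.T  # samples x genes
    beta, _, _, _ = np.linalg.lstsq(X.to_numpy(), Y, rcond=None)
    fitted = X.to_numpy() @ beta
    resid = Y - fitted
    dof = max(len(tab) - X.shape[1], 1)
    sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    betas = pd.DataFrame(beta[1:len(strains) + 1].T,
                         index=log_expr.genes, columns=strains)
    return PerturbationEffects(
        betas,
        pd.Series(beta[0], index=log_expr.genes, name="intercept"),
        pd.Series(sigma, index=log_expr.genes, name="sigma"),
        len(tab),
    )


def module_concordance(
    effects: PerturbationEffects,
    lfc: HumanLFCTable,
    human_module,
    omap: OrthologMap,
    strain: str,
    region: str | None = None,
    human_name: str = "human",
) -> ConcordanceResult:
    """Pearson correlation of human log2FC vs mouse beta within one module.

    Genes enter when they lie in the human module, have an LFC value in the
    region, and map one-to-one to a mouse gene carrying a beta. Fewer than
    3 usable genes or a degenerate (zero-variance) vector yields an
    untestable result instead of an exception.
    """
    if strain not in effects.betas.columns:
        raise ValueError(f"strain {strain!r} has no fitted effects")
    region = region if region is not None else lfc.regions[0]
    if region not in lfc.regions:
        raise ValueError(f"unknown region {region!r}")
    pairs = map_orthologs(effects.betas.index, omap, policy="one_to_one")
    human_to_mouse = dict(zip(pairs["human"], pairs["mouse"]))
    lfc_col = lfc.table[region]
    xs, ys = [], []
    for h in set(human_module):
        m = human_to_mouse.get(h)
        if m is None or h not in lfc_col.index:
            continue
        xs.append(float(lfc_col.loc[h]))
        ys.append(float(effects.betas.loc[m, strain]))
    n = len(xs)
    if n < 3:
        return ConcordanceResult(strain, human_name, region, float("nan"),
                                 float("nan"), n, untestable=True)
    try:
        res = pearson_cor_test(xs, ys)
    except ValueError:
        return ConcordanceResult(strain, human_name, region, float("nan"),
                                 float("nan"), n, untestable=True)
    return ConcordanceResult(strain, human_name, region, res.statistic, res.p, n)


def concordance_table(
    effects: PerturbationEffects,
    lfc: HumanLFCTable,
    human_catalog: dict[str, frozenset[str]] | dict[str, set[str]],
    omap: OrthologMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (strain x human module x region) concordances, BH-adjusted jointly.

    Untestable combinations are kept in the table with a flag; BH runs over
    the testable rows only. Rows with adjusted p > alpha are reported but
    marked non-significant.
    """
    rows = []
    for strain in effects.betas.columns:
        for h_name in sorted(human_catalog):
            for region in lfc.regions:
                res = module_concordance(
                    effects, lfc, human_catalog[h_name], omap, strain,
                    region=region, human_name=h_name,
                )
                rows.append(
                    {"strain": strain, "human_module": h_name, "region": region,
                     "r": res.r, "p": res.p, "n": res.n,
                     "untestable": res.untestable}
                )
    table = pd.DataFrame(rows)
    padj = np.full(len(table), np.nan)
    testable = ~table["untestable"].to_numpy()
    if testable.any():
        padj[testable] = adjust_bh(table.loc[testable, "p"].to_numpy())
    table["padj"] = padj
    table["significant"] = (table["padj"] < alpha).fillna(False)
    return table
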