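"""Synthetic mouse panel + human reference with known ground truth.

Emulates the study design this package analyzes: six mutant mouse strains
(five late-onset AD risk-gene perturbations and one early-onset APP/PS1
transgenic) plus B6 controls, 48 samples across three experimental batches
(36 / 8 / 4), planted co-expression modules whose eigengenes shift in
driver strains, an ortholog map to a human gene namespace, a human module
catalog with planted Jaccard overlap, and human log2FC(AD/control) tables
with planted directional concordance per (strain, human module).

Every quantity the downstream stages are supposed to recover is recorded in
:class:`SimulationTruth`, and generation is fully deterministic given a
seed (one documented RNG stream per generator call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    GeneSetCatalog,
    HumanLFCTable,
    OrthologMap,
    SampleMetadata,
)

log = logging.getLogger(__name__)


def _default_replicates() -> dict[str, int]:
    # 5 late-onset strains x 6, APP/PS1 x 5, B6 x 13 -> 48 samples
    return {
        "Apoe_KO": 6, "APOE4": 6, "Bin1_het": 6, "Cd2ap_het": 6, "Clu_KO": 6,
        "APP_PS1": 5, "B6": 13,
    }


def _default_batch_plan() -> dict[str, list[str]]:
    # batch1: all late-onset models + 6 B6 (N=36); batch2: 1 APP/PS1 + 7 B6
    # (N=8); batch3: 4 APP/PS1 (N=4)
    plan = {s: ["batch1"] * 6 for s in
            ("Apoe_KO", "APOE4", "Bin1_het", "Cd2ap_het", "Clu_KO")}
    plan["APP_PS1"] = ["batch2"] + ["batch3"] * 4
    plan["B6"] = ["batch1"] * 6 + ["batch2"] * 7
    return plan


@dataclass
class DesignConfig:
    """Design and generative parameters of the synthetic study.

    Defaults mirror the emulated design (replicate counts, 3 batches) and
    desk-scale module structure; effect sizes delta in [0.3, 1.5] log2
    units are a calibration choice. ``within_module_cor`` sets the noise
    level: with unit loadings, noise_sd = sqrt((1-r)/r).
    """

    control: str = "B6"
    replicates: Mapping[str, int] = field(default_factory=_default_replicates)
    batch_plan: Mapping[str, Sequence[str]] | None = field(
        default_factory=_default_batch_plan
    )
    module_sizes: Sequence[int] = (80, 70, 60, 50, 40)
    n_background: int = 700
    within_module_cor: float = 0.7
    noise_sd: float | None = None
    loading: float = 1.0
    signal_sd: float = 1.0  # per-sample sd of the module eigengene signal
    baseline_range: tuple[float, float] = (4.0, 9.0)
    batch_sd: float = 0.3
    delta_range: tuple[float, float] = (0.3, 1.5)
    module_delta: Mapping[tuple[str, str], float] | None = None
    n_de_per_strain: int = 25
    de_lfc_range: tuple[float, float] = (1.0, 2.0)
    library_size_range: tuple[float, float] = (8e5, 1.6e6)
    dispersion: float = 0.05
    ortholog_frac: float = 0.9
    one_to_many_frac: float = 0.05
    contamination_frac: float = 0.2
    r_matched: float = 0.5
    regions: Sequence[str] = ("TCX",)
    r_target: Mapping[tuple[str, str], float] | None = None

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        r = self.within_module_cor
        if not 0 < r <= 1:
            raise ValueError("within_module_cor must be in (0, 1]")
        return float(self.loading * self.signal_sd * np.sqrt((1.0 - r) / r))

    def validate(self) -> None:
        if self.control not in self.replicates:
            raise ValueError(f"control strain {self.control!r} has no replicates")
        for strain, n in self.replicates.items():
            if n < 2:
                raise ValueError(f"strain {strain!r} needs >= 2 replicates, got {n}")
        for size in self.module_sizes:
            if size < 1:
                raise ValueError("module sizes must be >= 1")


@dataclass
class SimulationTruth:
    """Everything the generator planted, for downstream recovery checks."""

    membership: dict[str, str]                 # mouse gene -> module ("grey")
    delta: pd.DataFrame                        # modules x strains, log2 shifts
    beta_true: pd.DataFrame                    # genes x non-control strains
    batch_offsets: pd.DataFrame                # genes x batches
    noise_sd: float
    seed: int
    eigengene_signal: pd.DataFrame | None = None  # modules x samples (shifted)
    r_target: dict[tuple[str, str], float] = field(default_factory=dict)

    def module_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, m in self.membership.items():
            if m != "grey":
                out.setdefault(m, []).append(g)
        return out


def generate_design(config: DesignConfig, seed: int = 0) -> SampleMetadata:
    """Sample sheet for the configured design (deterministic given seed)."""
    config.validate()
    if config.replicates[config.control] < 1:
        raise ValueError("control strain needs at least one replicate")
    rows = []
    for strain, n in config.replicates.items():
        plan = None
        if config.batch_plan is not None:
            plan = list(config.batch_plan.get(strain, []))
        for i in range(n):
            if plan and i < len(plan):
                batch = plan[i]
            elif plan:
                batch = plan[-1]
            else:
                batch = "batch1"
            rows.append({"sample": f"{strain}_{i + 1}", "strain": strain,
                         "batch": batch})
    table = pd.DataFrame(rows).set_index("sample")
    return SampleMetadata(table, control=config.control)


def _module_names(config: DesignConfig) -> list[str]:
    return [f"M{i + 1}" for i in range(len(config.module_sizes))]


def _planted_deltas(config: DesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(module, strain) eigengene shifts; control always zero.

    Unless overridden, each module gets one driver strain (round-robin over
    the mutant strains) with delta drawn uniformly from ``delta_range`` and
    a random sign.
    """
    modules = _module_names(config)
    strains = [s for s in config.replicates if s != config.control]
    delta = pd.DataFrame(0.0, index=modules, columns=strains)
    if config.module_delta is not None:
        for (m, s), d in config.module_delta.items():
            if s == config.control:
                raise ValueError("cannot plant a shift for the control strain")
            delta.loc[m, s] = float(d)
        return delta
    lo, hi = config.delta_range
    for i, m in enumerate(modules):
        s = strains[i % len(strains)]
        delta.loc[m, s] = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
    return delta


def generate_mouse_expression(
    design: SampleMetadata, config: DesignConfig, seed: int = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimulationTruth]:
    """Simulate TPM and counts with planted modules, shifts and batches.

    Latent log2 expression = baseline + loading * (module eigengene signal
    + strain shift) + batch offset + Gaussian noise. TPM = 2^latent - 1
    (clipped at 0, columns rescaled to a constant sum); counts are
    gamma-Poisson with mean TPM x library size and the configured
    dispersion.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    samples = design.table.index.tolist()
    strains = design.table["strain"].tolist()
    batches = design.table["batch"].tolist()
    batch_levels = list(dict.fromkeys(batches))
    n_samples = len(samples)

    modules = _module_names(config)
    n_module_genes = int(sum(config.module_sizes))
    n_genes = n_module_genes + config.n_background
    if n_module_genes > n_genes:
        raise ValueError("module sizes exceed the gene count")
    genes = [f"mgene{i:05d}" for i in range(n_genes)]
    membership: dict[str, str] = {}
    pos = 0
    for m, size in zip(modules, config.module_sizes):
        for g in genes[pos:pos + size]:
            membership[g] = m
        pos += size
    for g in genes[pos:]:
        membership[g] = "grey"

    noise_sd = config.resolved_noise_sd()
    delta = _planted_deltas(config, rng)
    mutant_strains = delta.columns.tolist()

    baseline = rng.uniform(*config.baseline_range, size=n_genes)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(n_genes, len(batch_levels)))
    offsets = pd.DataFrame(batch_offsets, index=genes, columns=batch_levels)

    # shared module signals: normal per sample (sd = signal_sd), shifted per strain
    signal = pd.DataFrame(
        rng.normal(0.0, config.signal_sd, size=(len(modules), n_samples)),
        index=modules, columns=samples,
    )
    shifted = signal.copy()
    for j, (smp, strain) in enumerate(zip(samples, strains)):
        if strain in mutant_strains:
            shifted.iloc[:, j] += delta[strain].to_numpy()

    # background differential-expression genes, planted per strain
    de_effects = np.zeros((n_genes, len(mutant_strains)))
    lo, hi = config.de_lfc_range
    cursor = pos  # first background gene index
    for si in range(len(mutant_strains)):
        stop = min(cursor + config.n_de_per_strain, n_genes)
        n_chosen = stop - cursor
        if n_chosen > 0:
            de_effects[cursor:stop, si] = (
                rng.uniform(lo, hi, size=n_chosen) * rng.choice([-1.0, 1.0], size=n_chosen)
            )
        cursor = stop

    module_row = {m: i for i, m in enumerate(modules)}
    mod_idx = np.array([module_row.get(membership[g], -1) for g in genes],
                       dtype=int)
    batch_col = np.array([batch_levels.index(b) for b in batches])
    strain_onehot = np.array(
        [[1.0 if st == s else 0.0 for st in strains] for s in mutant_strains]
    )  # strains x samples
    if modules:
        in_module = (mod_idx >= 0)[:, None]
        safe_idx = np.clip(mod_idx, 0, None)
        beta_values = np.where(
            in_module, config.loading * delta.to_numpy()[safe_idx], de_effects
        )
        module_part = np.where(
            in_module, config.loading * shifted.to_numpy()[safe_idx], 0.0
        )
        grey_part = np.where(~in_module, de_effects @ strain_onehot, 0.0)
    else:
        beta_values = de_effects
        module_part = 0.0
        grey_part = de_effects @ strain_onehot
    beta_true = pd.DataFrame(beta_values, index=genes, columns=mutant_strains)
    latent = (
        baseline[:, None]
        + batch_offsets[:, batch_col]
        + module_part
        + grey_part
        + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    )

    tpm_raw = np.clip(np.exp2(latent) - 1.0, 0.0, None)
    col_sums = tpm_raw.sum(axis=0)
    tpm_values = tpm_raw / col_sums * 1e6
    tpm = ExpressionMatrix(pd.DataFrame(tpm_values, index=genes, columns=samples), "tpm")

    lib = rng.uniform(*config.library_size_range, size=n_samples)
    mean = tpm_values * (lib / 1e6)
    d = config.dispersion
    if d <= 1e-12:
        count_values = rng.poisson(mean)
    else:
        lam = rng.gamma(shape=1.0 / d, scale=np.maximum(mean, 1e-12) * d)
        count_values = rng.poisson(lam)
    counts = ExpressionMatrix(
        pd.DataFrame(count_values.astype(np.int64), index=genes, columns=samples),
        "counts",
    )

    truth = SimulationTruth(
        membership=membership,
        delta=delta,
        beta_true=beta_true,
        batch_offsets=offsets,
        noise_sd=noise_sd,
        seed=seed,
        eigengene_signal=shifted,
    )
    return tpm, counts, truth


def _one_to_one(omap: OrthologMap) -> dict[str, str]:
    tab = omap.table
    mouse_deg = tab["mouse"].value_counts()
    human_deg = tab["human"].value_counts()
    ok = tab["mouse"].map(mouse_deg).eq(1) & tab["human"].map(human_deg).eq(1)
    sub = tab[ok]
    return dict(zip(sub["mouse"], sub["human"]))


def generate_human_reference(
    truth: SimulationTruth, config: DesignConfig, seed: int = 0
) -> tuple[GeneSetCatalog, HumanLFCTable, OrthologMap]:
    """Human module catalog, LFC tables and ortholog map matched to truth.

    Each human module ``hs_<M>`` collects the orthologs of mouse module M's
    genes plus ``contamination_frac`` random human genes (controlling the
    planted Jaccard). Human LFC in a module with target correlation r for
    its driver strain is r * zscore(beta) + sqrt(1-r^2) * noise over the
    module genes that carry a one-to-one beta, so the realized correlation
    over the genes the concordance test actually uses is ~r. Fills
    ``truth.r_target`` in place as a side effect.
    """
    rng = np.random.default_rng(seed)
    mouse_genes = list(truth.membership)
    n = len(mouse_genes)
    n_mapped = int(round(config.ortholog_frac * n))
    mapped = sorted(rng.choice(np.array(mouse_genes, dtype=object), size=n_mapped,
                               replace=False).tolist())
    rows = [{"mouse": g, "human": "H" + g.upper()} for g in mapped]
    n_multi = int(round(config.one_to_many_frac * n_mapped))
    if n_multi:
        multi = rng.choice(np.array(mapped, dtype=object), size=n_multi, replace=False)
        rows.extend({"mouse": g, "human": "H" + g.upper() + "B"} for g in sorted(multi))
    omap = OrthologMap(pd.DataFrame(rows))
    all_human = sorted(set(omap.table["human"]))

    partners: dict[str, list[str]] = omap.human_partners()
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    module_genes = truth.module_genes()
    for m in sorted(module_genes):
        base: set[str] = set()
        for g in module_genes[m]:
            base.update(partners.get(g, ()))
        if not base:
            continue
        pool = [h for h in all_human if h not in base]
        n_cont = int(round(config.contamination_frac * len(base)))
        n_cont = min(n_cont, len(pool))
        cont = rng.choice(np.array(pool, dtype=object), size=n_cont,
                          replace=False).tolist() if n_cont else []
        sets[f"hs_{m}"] = frozenset(base | set(cont))
        descriptions[f"hs_{m}"] = f"synthetic human counterpart of {m}"
    catalog = GeneSetCatalog(sets, descriptions)

    # planted concordance targets: driver strain of each module gets r_matched
    r_target: dict[tuple[str, str], float] = dict(config.r_target or {})
    if config.r_target is None:
        for m in sorted(module_genes):
            name = f"hs_{m}"
            if name not in sets:
                continue
            row = truth.delta.loc[m]
            if (row != 0).any():
                driver = row.abs().idxmax()
                r_target[(driver, name)] = config.r_matched
    for r in r_target.values():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"r_target {r} outside [-1, 1]")
    truth.r_target = r_target

    one2one = _one_to_one(omap)
    human_to_mouse = {h: m for m, h in one2one.items()}
    lfc_cols: dict[str, pd.Series] = {}
    for region in config.regions:
        lfc = pd.Series(rng.normal(size=len(all_human)), index=all_human)
        planted: set[str] = set()
        for (strain, h_name), r in sorted(r_target.items()):
            if h_name not in sets or r == 0.0:
                continue
            usable = [h for h in sorted(sets[h_name])
                      if h in human_to_mouse and h not in planted]
            if len(usable) < 3:
                continue
            beta = truth.beta_true.loc[[human_to_mouse[h] for h in usable], strain]
            beta = beta.to_numpy(dtype=float)
            sd = beta.std()
            noise = rng.normal(size=len(usable))
            if sd == 0:
                values = noise
            else:
                z = (beta - beta.mean()) / sd
                values = r * z + np.sqrt(1.0 - r * r) * noise
            lfc.loc[usable] = values
            planted.update(usable)
        lfc_cols[region] = lfc
    lfc_table = HumanLFCTable(pd.DataFrame(lfc_cols))
    return catalog, lfc_table, omap


def generate_mouse_genesets(
    truth: SimulationTruth, seed: int = 0, n_random: int = 5, random_size: int = 40
) -> GeneSetCatalog:
    """Mouse-namespace gene sets for exercising the enrichment stage:
    one set per planted module plus random decoy sets."""
    rng = np.random.default_rng(seed)
    genes = np.array(list(truth.membership), dtype=object)
    sets: dict[str, frozenset[str]] = {}
    for m, members in sorted(truth.module_genes().items()):
        sets[f"pathway_{m}"] = frozenset(members)
    for i in range(n_random):
        sets[f"decoy_{i + 1}"] = frozenset(
            rng.choice(genes, size=min(random_size, genes.size), replace=False)
        )
    return GeneSetCatalog(sets, {name: "synthetic" for name in sets})
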