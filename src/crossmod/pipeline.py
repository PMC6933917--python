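"""One-config orchestration of the full analysis.

preprocess -> per-strain differential expression -> network/module
detection -> strain association -> (optional) enrichment -> cross-species
comparison, with a run manifest and summary tables written next to the
outputs. Stage-specific random substreams are derived from the global seed
so changing one stage's randomness leaves upstream outputs unchanged.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import data_io as io
from .association import associate_strains
from .coexpression import (
    cluster_and_cut,
    compute_adjacency,
    compute_eigengenes,
    compute_tom,
    merge_close_modules,
    pick_soft_threshold,
)
from .cross_species import concordance_table, fit_perturbation_model, overlap_table
from .diffexpr import nb_wald_test
from .enrichment import ora
from .preprocessing import correct_batch, filter_low_expression, log_transform, run_pca
from .synthetic import (
    DesignConfig,
    generate_design,
    generate_human_reference,
    generate_mouse_expression,
    generate_mouse_genesets,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for one pipeline run."""

    tpm: str = ""
    counts: str = ""
    metadata: str = ""
    human_gmt: str = ""
    orthologs: str = ""
    lfc: str = ""
    enrichment_gmt: str = ""          # optional; stage skipped when empty
    out_dir: str = "results"
    control: str = "B6"
    min_tpm: float = 10.0
    max_frac_below: float = 0.9
    soft_power: int | str = 8         # integer or "auto"
    r2_target: float = 0.85
    min_module_size: int = 30
    merge_height: float = 0.25
    alpha: float = 0.05
    n_perm: int = 10_000
    combat_covariates: bool = True
    combat_eb: bool = True
    seed: int = 1

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not (0 <= self.merge_height <= 1):
            raise ValueError("merge_height must be in [0, 1]")
        if self.soft_power != "auto" and int(self.soft_power) < 1:
            raise ValueError("soft_power must be a positive integer or 'auto'")
        if abs(int(self.seed)) >= 2 ** 31:
            raise ValueError("seed must fit in a signed 32-bit integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Handles to the main in-memory outputs of a run."""

    out_dir: Path
    corrected: "io.ExpressionMatrix"
    assignment: dict[str, str]
    eigengenes: pd.DataFrame
    drivers: pd.DataFrame
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    overlaps: pd.DataFrame | None = None
    concordance: pd.DataFrame | None = None


def _stage_seed(seed: int, stage: int) -> int:
    """Independent 31-bit substream seed for one pipeline stage."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    manifest: dict = {
        "crossmod_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
    }

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ----- inputs ---------------------------------------------------------
    try:
        tpm = io.read_expression(config.tpm, "tpm")
        counts = io.read_expression(config.counts, "counts")
        meta = io.read_metadata(config.metadata, control=config.control)
        meta.validate_against(tpm)
        meta.validate_against(counts)
        human_catalog = io.read_gmt(config.human_gmt)
        omap = io.read_ortholog_map(config.orthologs)
        lfc = io.read_lfc_table(config.lfc)
        enr_catalog = io.read_gmt(config.enrichment_gmt) if config.enrichment_gmt else None
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        _fail("read_inputs", exc)
    log.info("stage=read_inputs genes=%d samples=%d human_modules=%d",
             len(tpm.genes), len(tpm.samples), len(human_catalog))
    manifest["stages"]["read_inputs"] = {
        "genes": len(tpm.genes), "samples": len(tpm.samples),
        "human_modules": len(human_catalog),
    }

    # ----- preprocess -----------------------------------------------------
    try:
        filtered = filter_low_expression(tpm, config.min_tpm, config.max_frac_below)
        logged = log_transform(filtered)
        corrected = correct_batch(
            logged, meta, eb=config.combat_eb, covariates=config.combat_covariates
        )
        pca = run_pca(corrected)
    except Exception as exc:
        _fail("preprocess", exc)
    io.write_expression(corrected, out / "expression_corrected.tsv")
    pca.scores.iloc[:, :10].to_csv(out / "pca_scores.tsv", sep="\t",
                                   index_label="sample")
    pd.Series(pca.variance_fraction[:10],
              index=pca.scores.columns[:10], name="variance_fraction").to_csv(
        out / "pca_variance.tsv", sep="\t", index_label="component")
    log.info("stage=preprocess kept=%d of %d genes; PC1 var=%.3f",
             len(filtered.genes), len(tpm.genes), pca.variance_fraction[0])
    manifest["stages"]["preprocess"] = {
        "genes_kept": len(filtered.genes),
        "genes_removed": len(tpm.genes) - len(filtered.genes),
        "pc1_variance_fraction": float(pca.variance_fraction[0]),
    }

    # ----- differential expression ---------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    counts_f = io.ExpressionMatrix(counts.data.loc[filtered.genes], "counts")
    strains = [s for s in meta.strains() if s != meta.control]
    try:
        for strain in strains:
            table = nb_wald_test(counts_f, meta, strain, alpha_level=config.alpha)
            de_tables[strain] = table
            table.to_csv(out / f"de_{strain}.tsv", sep="\t")
    except Exception as exc:
        _fail("diffexpr", exc)
    de_counts = {s: int(t["significant"].sum()) for s, t in de_tables.items()}
    log.info("stage=diffexpr significant=%s", de_counts)
    manifest["stages"]["diffexpr"] = {"significant_genes": de_counts}

    # ----- network / modules ----------------------------------------------
    try:
        if config.soft_power == "auto":
            power, fit = pick_soft_threshold(corrected, r2_target=config.r2_target)
        else:
            power = int(config.soft_power)
            _, fit = pick_soft_threshold(corrected, r2_target=config.r2_target)
        fit.to_csv(out / "soft_threshold_fit.tsv", sep="\t", index=False)
        net = compute_adjacency(corrected, soft_power=power)
        _, dissim = compute_tom(net)
        _, assignment = cluster_and_cut(dissim, corrected.genes,
                                        min_size=config.min_module_size)
        if assignment.non_grey():
            assignment, eigengenes = merge_close_modules(
                corrected, assignment, merge_height=config.merge_height
            )
        else:
            raise ValueError("no modules found above the minimum size")
    except Exception as exc:
        _fail("network", exc)
    io.write_module_assignment(assignment.labels, out / "module_assignment.tsv")
    eigengenes.to_csv(out / "module_eigengenes.tsv", sep="\t")
    sizes = {m: len(g) for m, g in assignment.non_grey().items()}
    log.info("stage=network power=%d modules=%d grey=%d",
             power, len(sizes), sum(1 for v in assignment.labels.values() if v == "grey"))
    manifest["stages"]["network"] = {"soft_power": power, "module_sizes": sizes}

    # ----- strain association ---------------------------------------------
    try:
        driver_table = associate_strains(eigengenes, meta, alpha=config.alpha)
    except Exception as exc:
        _fail("associate", exc)
    driver_table.module_table.to_csv(out / "module_anova.tsv", sep="\t", index=False)
    driver_table.contrast_table.to_csv(out / "module_drivers.tsv", sep="\t", index=False)
    n_driven = sum(1 for v in driver_table.drivers().values() if v)
    log.info("stage=associate driven_modules=%d of %d", n_driven, len(sizes))
    manifest["stages"]["associate"] = {"driven_modules": n_driven}

    # ----- enrichment (optional) ------------------------------------------
    if enr_catalog is not None:
        try:
            universe = corrected.genes
            enr_frames = []
            for module, members in sorted(assignment.non_grey().items()):
                res = ora(members, enr_catalog, universe, alpha=config.alpha)
                res.insert(0, "module", module)
                enr_frames.append(res)
            enrichment = pd.concat(enr_frames, ignore_index=True)
        except Exception as exc:
            _fail("enrich", exc)
        enrichment.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "significant_sets": int(enrichment["significant"].sum())
        }

    # ----- cross-species ---------------------------------------------------
    try:
        effects = fit_perturbation_model(corrected, meta)
        overlaps = overlap_table(
            assignment.non_grey(), human_catalog.sets, omap,
            n_perm=config.n_perm, seed=_stage_seed(config.seed, 6),
        )
        concordance = concordance_table(
            effects, lfc, human_catalog.sets, omap, alpha=config.alpha
        )
    except Exception as exc:
        _fail("compare", exc)
    effects.betas.to_csv(out / "perturbation_effects.tsv", sep="\t",
                         index_label="gene")
    overlaps.to_csv(out / "module_overlaps.tsv", sep="\t", index=False)
    overlaps.pivot(index="mouse_module", columns="human_module",
                   values="jaccard").to_csv(out / "overlap_heatmap.tsv", sep="\t")
    concordance.to_csv(out / "module_concordance.tsv", sep="\t", index=False)
    manifest["stages"]["compare"] = {
        "significant_overlaps": int((overlaps["padj"] < config.alpha).sum()),
        "significant_concordances": int(concordance["significant"].sum()),
    }

    # ----- summary ---------------------------------------------------------
    summary = driver_table.module_table.copy()
    summary["size"] = summary["module"].map(sizes)
    drivers = driver_table.drivers()
    summary["driver_strains"] = summary["module"].map(
        lambda m: ",".join(sorted(drivers.get(m, [])))
    )
    summary.to_csv(out / "module_summary.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        out_dir=out,
        corrected=corrected,
        assignment=assignment.labels,
        eigengenes=eigengenes,
        drivers=driver_table.contrast_table,
        de_tables=de_tables,
        overlaps=overlaps,
        concordance=concordance,
    )


def simulate_inputs(out_dir, seed: int = 1,
                    config: DesignConfig | None = None) -> dict[str, str]:
    """Generate all pipeline inputs (plus truth tables) into a directory."""
    cfg = config or DesignConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = int(np.random.SeedSequence([seed, 0]).generate_state(1)[0] % (2 ** 31))
    design = generate_design(cfg, seed=base)
    tpm, counts, truth = generate_mouse_expression(design, cfg, seed=base + 1)
    catalog, lfc, omap = generate_human_reference(truth, cfg, seed=base + 2)
    genesets = generate_mouse_genesets(truth, seed=base + 3)

    paths = {
        "tpm": str(out / "tpm.tsv"),
        "counts": str(out / "counts.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "human_gmt": str(out / "human_modules.gmt"),
        "orthologs": str(out / "orthologs.tsv"),
        "lfc": str(out / "human_lfc.tsv"),
        "enrichment_gmt": str(out / "mouse_genesets.gmt"),
    }
    io.write_expression(tpm, paths["tpm"])
    io.write_expression(counts, paths["counts"])
    io.write_metadata(design, paths["metadata"])
    io.write_gmt(catalog, paths["human_gmt"])
    io.write_ortholog_map(omap, paths["orthologs"])
    io.write_lfc_table(lfc, paths["lfc"])
    io.write_gmt(genesets, paths["enrichment_gmt"])
    # ground truth, for tests and post-hoc checks
    io.write_module_assignment(truth.membership, out / "truth_membership.tsv")
    truth.delta.to_csv(out / "truth_delta.tsv", sep="\t", index_label="module")
    truth.beta_true.to_csv(out / "truth_beta.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        [{"strain": s, "human_module": h, "r_target": r}
         for (s, h), r in sorted(truth.r_target.items())]
    ).to_csv(out / "truth_r_target.tsv", sep="\t", index=False)
    return paths


def run_demo(out_dir, seed: int = 1, n_perm: int = 1000) -> PipelineResult:
    """simulate + run with the default analysis parameters (reduced n_perm)."""
    out = Path(out_dir)
    paths = simulate_inputs(out / "inputs", seed=seed)
    config = PipelineConfig(
        **paths, out_dir=str(out / "analysis"), n_perm=n_perm, seed=seed
    )
    return run_pipeline(config)
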