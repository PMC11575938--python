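"""End-to-end driver chaining census -> DE -> bias -> network -> reports.

``run_pipeline`` reproduces the analysis shape of the study on synthetic or
user-supplied data: a gene census of the duplicated pathway, negative-binomial
differential expression under UV-B, six-category homoeolog-bias
classification, and regulator screening on a multi-stress co-expression
panel.  Every run writes its configuration and a summary JSON to the output
directory so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bias import classify_all
from .catalog import GeneCatalog, pair_homoeologs, summarize_loci, family_census
from .coexpression import (
    NetworkMatrices,
    extract_regulator_edges,
    detect_modules,
    export_network,
    pick_soft_threshold,
)
from .expression import compute_fpkm, de_test, log_transform
from .simulate import SimulationConfig, generate_catalog, simulate_counts, simulate_multistress_panel

logger = logging.getLogger("duplipath")

__all__ = ["RunConfig", "run_pipeline", "regulator_family_census"]


@dataclass
class RunConfig:
    """Thresholds and paths for a full pipeline run.

    Defaults carry the study's stated constants: DEG at padj < 0.05 with
    |log2FC| > 1, bias calls at p < 0.05 per ratio, weighted-edge cutoff 0.2,
    scale-free fit target R^2 > 0.85, and an expression floor of FPKM >= 1
    for "simultaneously expressed" homoeolog pairs.
    """

    outdir: str = "duplipath_out"
    seed: int = 0
    alpha: float = 0.05
    lfc: float = 1.0
    bias_alpha: float = 0.05
    edge_cutoff: float = 0.2
    rsq: float = 0.85
    expressed_fpkm: float = 1.0
    max_genes: int | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    catalog_path: str | None = None
    panel_path: str | None = None
    roles_path: str | None = None
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.bias_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not 0 <= self.edge_cutoff <= 1:
            raise ValueError("edge cutoff must lie in [0, 1]")
        if not 0 < self.rsq < 1:
            raise ValueError("rsq target must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["size_factor_range"] = list(d["sim"]["size_factor_range"])
        return d


def regulator_family_census(edges: list, roles: pd.DataFrame) -> pd.DataFrame:
    """Distinct regulators per transcription-factor family, plus sharing stats.

    A regulator hitting several targets is counted once for its family.  The
    returned frame also reports, per target, how many regulators it shares
    with at least one other target (the sharing analysis of the study).
    """
    if not edges:
        return pd.DataFrame(columns=["family", "n_regulators"])
    reg_ids = sorted({e.regulator for e in edges})
    fam = roles.loc[reg_ids, "family"]
    out = (
        fam.value_counts()
        .rename_axis("family")
        .reset_index(name="n_regulators")
        .sort_values(["n_regulators", "family"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def target_sharing(edges: list) -> pd.DataFrame:
    """Per target: regulator count and whether any regulator is shared."""
    if not edges:
        return pd.DataFrame(columns=["target", "n_regulators", "shared"])
    by_target: dict[str, set[str]] = {}
    for e in edges:
        by_target.setdefault(e.target, set()).add(e.regulator)
    reg_use: dict[str, int] = {}
    for regs in by_target.values():
        for r in regs:
            reg_use[r] = reg_use.get(r, 0) + 1
    rows = [
        {
            "target": t,
            "n_regulators": len(regs),
            "shared": any(reg_use[r] > 1 for r in regs),
        }
        for t, regs in sorted(by_target.items())
    ]
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("outdir", None)  # where results land does not change what they are
    payload = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Emits under ``config.outdir``: catalog/census TSVs, the DE table, the
    bias table and census, the soft-threshold report, module assignments, the
    regulator-edge SIF + attribute TSV, and ``summary.json``.  Identical
    (seed, config) pairs produce identical bundles.

    Returns the summary dictionary.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = SimulationConfig(**{**asdict(config.sim), "seed": config.seed})
        sim.family_weights = dict(sim.family_weights)
        catalog = generate_catalog(sim)
        counts, metadata, truth = simulate_counts(catalog, sim)
        panel, roles, panel_truth = simulate_multistress_panel(catalog, sim)
    else:
        for name in ("counts_path", "metadata_path", "catalog_path", "panel_path", "roles_path"):
            if getattr(config, name) is None:
                raise FileNotFoundError(f"{name} is required when simulate is off")
        catalog = GeneCatalog.from_tsv(config.catalog_path)
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        metadata = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
        panel = pd.read_csv(config.panel_path, sep="\t", index_col=0)
        roles = pd.read_csv(config.roles_path, sep="\t", index_col=0)
        truth = panel_truth = None
        missing = counts.index.difference([r.gene_id for r in catalog.records])
        if len(missing) > 0:
            raise ValueError(f"count matrix genes absent from catalog: {sorted(missing)[:10]}")

    # --- census -----------------------------------------------------------
    logger.info("census: %d genes", len(catalog))
    catalog.to_tsv(outdir / "catalog.tsv")
    locus_summary = summarize_loci(catalog)
    census = family_census(catalog)
    census.to_csv(outdir / "family_census.tsv", sep="\t", index=False)
    pairs, at_only, dt_only = pair_homoeologs(catalog)

    # --- differential expression -----------------------------------------
    de = de_test(counts, metadata, alpha=config.alpha, lfc_threshold=config.lfc)
    de.table.to_csv(outdir / "de_table.tsv", sep="\t")
    logger.info("DE: %d DEGs (%d up / %d down)", de.n_deg, de.n_up, de.n_down)

    # --- homoeolog bias ---------------------------------------------------
    lengths = pd.Series(
        {r.gene_id: max(r.cds_length, 1) for r in catalog.records}, name="length"
    )
    fpkm = compute_fpkm(counts, lengths)
    bias_table, bias_census, unexpressed = classify_all(
        fpkm, pairs, metadata, alpha=config.bias_alpha, expressed_min_mean=config.expressed_fpkm
    )
    bias_table.to_csv(outdir / "bias_table.tsv", sep="\t", index=False)
    bias_census.to_csv(outdir / "bias_census.tsv", sep="\t", index=False)

    # --- co-expression network -------------------------------------------
    if config.max_genes is not None:
        panel = panel.iloc[: config.max_genes]
    panel_log = log_transform(panel)
    st = pick_soft_threshold(panel_log, rsq_target=config.rsq)
    st.to_tsv(outdir / "soft_threshold.tsv")
    net = NetworkMatrices.from_expression(panel_log, st.chosen_power)
    modules = detect_modules(net.tom, panel_log)
    modules.labels.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
    targets = [g for g in roles.index[roles["role"] == "structural"] if g in net.tom.index]
    regulators = [g for g in roles.index[roles["role"] == "regulatory"] if g in net.tom.index]
    edges = extract_regulator_edges(net, targets, regulators, cutoff=config.edge_cutoff)
    if edges:
        export_network(edges, outdir / "network.sif", outdir / "network_edges.tsv")
    reg_census = regulator_family_census(edges, roles)
    reg_census.to_csv(outdir / "regulator_families.tsv", sep="\t", index=False)
    sharing = target_sharing(edges)

    # --- summary ----------------------------------------------------------
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "census": {
            "n_genes": locus_summary.n_genes,
            "n_loci": locus_summary.n_loci,
            "n_dual": locus_summary.n_dual,
            "n_at_only": locus_summary.n_at_only,
            "n_dt_only": locus_summary.n_dt_only,
        },
        "de": {"n_deg": de.n_deg, "n_up": de.n_up, "n_down": de.n_down},
        "bias": {
            row.category: int(row.n_pairs) for row in bias_census.itertuples(index=False)
        },
        "bias_pairs_classified": int(bias_census["n_pairs"].sum()),
        "bias_pairs_unexpressed": len(unexpressed),
        "network": {
            "chosen_power": st.chosen_power,
            "rsq_target_met": bool(st.target_met),
            "n_modules": modules.n_modules,
            "n_edges": len(edges),
            "n_regulators": len({e.regulator for e in edges}),
            "n_targets_with_regulators": len({e.target for e in edges}),
            "n_shared_targets": int(sharing["shared"].sum()) if len(sharing) else 0,
        },
        "regulator_families": {
            row.family: int(row.n_regulators) for row in reg_census.itertuples(index=False)
        },
    }
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    if config.simulate and truth is not None:
        truth.bias_category.update(panel_truth.bias_category)
        truth.regulator_edges = panel_truth.regulator_edges
        truth.module_of_gene = panel_truth.module_of_gene
        truth.to_json(outdir / "ground_truth.json")
    return summary
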