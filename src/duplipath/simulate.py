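"""Synthetic allotetraploid transcriptome generator with planted ground truth.

Emulates the study design the pipeline targets: a gene catalog shaped like
the glutathione-pathway census in upland cotton (125 loci, 80 of them with
both At- and Dt-homoeologs), negative-binomial count matrices for 3 CK + 3 UV
replicates with planted differential expression and homoeolog-bias
categories, a 33-sample multi-stress expression panel with planted
regulator->target co-expression modules (including a configurable negative
regulator), and qPCR Ct plates with known fold changes.  Every generator is
deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import CATEGORIES
from .catalog import GeneCatalog, GeneRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "generate_catalog",
    "simulate_counts",
    "simulate_multistress_panel",
    "simulate_scale_free_profile",
    "simulate_qpcr",
]

# The 12 structural enzyme families of the glutathione pathway; weights follow
# the relative family sizes of the cotton census (GST dominates).
STRUCTURAL_FAMILIES: dict[str, float] = {
    "GST": 0.50,
    "G6PDH": 0.06,
    "GPX": 0.08,
    "GGT": 0.05,
    "GR": 0.04,
    "IDH": 0.05,
    "LAP": 0.05,
    "OXP": 0.05,
    "PGDC": 0.04,
    "GGCT": 0.04,
    "GCL": 0.02,
    "GS": 0.02,
}

GST_SUBFAMILIES: dict[str, float] = {
    "Tau": 0.58, "Phi": 0.12, "Theta": 0.08, "Lambda": 0.06,
    "DHAR": 0.05, "Zeta": 0.04, "EF1Bgamma": 0.03, "TCHQD": 0.02, "MGST": 0.02,
}

# Transcription-factor families observed among the pathway's regulators.
REGULATOR_FAMILIES = (
    "WRKY", "C2H2", "HSF", "ERF", "MYB", "NAC", "bHLH", "C3H",
    "GRAS", "B3", "NF-X1", "RAV", "HD-Zip",
)

N_CHROMOSOMES = 13


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design parameters for every synthetic generator.

    Defaults mirror the real study: 125 loci split 80 dual / 18 At-only /
    27 Dt-only, 3 replicates per condition, and a 33-sample multi-stress
    panel (co-expression needs at least 15 samples).
    """

    n_loci: int = 125
    frac_dual: float = 80 / 125
    frac_at_only: float = 18 / 125
    frac_dt_only: float = 27 / 125
    family_weights: dict[str, float] = field(default_factory=lambda: dict(STRUCTURAL_FAMILIES))
    n_replicates: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    lfc_effect: float = 2.0
    bias_plan: dict[str, int] | None = None
    bias_fold: float = 4.0
    n_deg: int = 40
    n_stress_samples: int = 33
    n_modules: int = 3
    module_size: int = 30
    regulators_per_module: int = 5
    n_negative_regulators: int = 1
    noise_sd: float = 0.3
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_dual + self.frac_at_only + self.frac_dt_only
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"locus-category proportions sum to {total}, not 1")
        if self.n_loci < 0:
            raise ConfigError("n_loci must be nonnegative")
        if self.dispersion < 0:
            raise ConfigError("NB dispersion must be >= 0")
        if self.n_stress_samples < 15:
            raise ConfigError("co-expression panels need at least 15 samples")
        if self.bias_plan is not None:
            bad = set(self.bias_plan) - set(CATEGORIES)
            if bad:
                raise ConfigError(f"unknown bias categories: {sorted(bad)}")

    @property
    def counts_by_category(self) -> tuple[int, int, int]:
        """(n_dual, n_at_only, n_dt_only); rounding residue goes to dual."""
        n_at = round(self.n_loci * self.frac_at_only)
        n_dt = round(self.n_loci * self.frac_dt_only)
        n_dual = self.n_loci - n_at - n_dt
        return n_dual, n_at, n_dt


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    bias_category: dict[str, str] = field(default_factory=dict)  # pair_id -> category
    deg_direction: dict[str, str] = field(default_factory=dict)  # gene_id -> up|down
    regulator_edges: list[dict] = field(default_factory=list)  # regulator, target, sign
    module_of_gene: dict[str, int] = field(default_factory=dict)
    qpcr_fold: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _choose_families(rng: np.random.Generator, weights: dict[str, float], n: int) -> list[str]:
    fams = list(weights)
    p = np.array([weights[f] for f in fams], dtype=float)
    p = p / p.sum()
    return list(rng.choice(fams, size=n, p=p))


def generate_catalog(config: SimulationConfig) -> GeneCatalog:
    """Build a synthetic gene catalog honoring the Gohir identifier grammar.

    Loci are laid out with sequential locus numbers per chromosome; a dual
    locus places its At- and Dt-homoeolog at the same position on the
    corresponding A- and D-subgenome chromosome with mutual partner
    references.
    """
    rng = np.random.default_rng(config.seed)
    n_dual, n_at, n_dt = config.counts_by_category
    categories = ["dual"] * n_dual + ["at_only"] * n_at + ["dt_only"] * n_dt
    families = _choose_families(rng, config.family_weights, len(categories))

    next_locus = {c: 100 for c in range(1, N_CHROMOSOMES + 1)}
    records: list[GeneRecord] = []
    for i, (cat, fam) in enumerate(zip(categories, families)):
        chrom = (i % N_CHROMOSOMES) + 1
        locus_num = next_locus[chrom] * 100  # Gohir locus numbers step by 100
        next_locus[chrom] += 1
        locus_id = f"L{chrom:02d}_{locus_num:06d}"
        sub = ""
        if fam == "GST":
            sub = _choose_families(rng, GST_SUBFAMILIES, 1)[0]
        cds_length = int(rng.integers(261, 3874))
        exon_count = int(rng.integers(1, 16))
        at_id = f"Gohir.A{chrom:02d}G{locus_num:06d}"
        dt_id = f"Gohir.D{chrom:02d}G{locus_num:06d}"
        if cat == "dual":
            records.append(GeneRecord(at_id, locus_id, fam, sub, dt_id, cds_length, exon_count))
            records.append(GeneRecord(dt_id, locus_id, fam, sub, at_id, cds_length, exon_count))
        elif cat == "at_only":
            records.append(GeneRecord(at_id, locus_id, fam, sub, None, cds_length, exon_count))
        else:
            records.append(GeneRecord(dt_id, locus_id, fam, sub, None, cds_length, exon_count))
    catalog = GeneCatalog(records)
    catalog.validate()
    return catalog


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draws with var = m + alpha*m^2 (Poisson at alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _default_bias_plan(n_pairs: int) -> dict[str, int]:
    """Even allocation of pairs over all six bias categories."""
    base = n_pairs // len(CATEGORIES)
    plan = {c: base for c in CATEGORIES}
    for c in CATEGORIES[: n_pairs - base * len(CATEGORIES)]:
        plan[c] += 1
    return plan


# Mean multipliers (At, Dt) per condition implementing each bias category.
# "fold" is the planted dominance shift; lost_bias is biased under CK only,
# the get-bias categories only under UV.
def _bias_multipliers(category: str, fold: float) -> dict[str, tuple[float, float]]:
    table = {
        "no_bias": {"CK": (1, 1), "UV": (1, 1)},
        "lost_bias": {"CK": (fold, 1), "UV": (1, 1)},
        "At_bias": {"CK": (fold, 1), "UV": (fold, 1)},
        "Dt_bias": {"CK": (1, fold), "UV": (1, fold)},
        "get_At_bias": {"CK": (1, 1), "UV": (fold, 1)},
        "get_Dt_bias": {"CK": (1, 1), "UV": (1, fold)},
    }
    return table[category]


def simulate_counts(
    catalog: GeneCatalog,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the 3 CK + 3 UV count matrix with planted DEGs and bias.

    Returns ``(counts, metadata, truth)``.  Counts are NB(mean, dispersion)
    with per-sample library-size factors drawn log-uniform over
    ``size_factor_range``.  Planted DEGs (singleton loci only, so DE and bias
    plants never collide) shift the UV mean by 2**lfc_effect up or down;
    planted bias pairs shift the At vs Dt means per category.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(config.seed + 1)
    genes = catalog.gene_ids
    n_rep = config.n_replicates
    samples = [f"CK_{i+1}" for i in range(n_rep)] + [f"UV_{i+1}" for i in range(n_rep)]
    metadata = pd.DataFrame(
        {
            "condition": ["CK"] * n_rep + ["UV"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=pd.Index(samples, name="sample"),
    )

    # baseline means are drawn per locus (log-normal spread around the
    # configured mean) and shared by both homoeologs, so that planted
    # "no bias" pairs really are equal in expectation
    loci = sorted({r.locus_id for r in catalog.records})
    locus_base = {
        lid: config.baseline_mean * np.exp(rng.normal(0, 0.6)) for lid in loci
    }
    base = np.array([locus_base[r.locus_id] for r in catalog.records])
    mean_ck = pd.Series(base, index=genes)
    mean_uv = mean_ck.copy()
    truth = GroundTruth()

    # plant bias categories on dual loci
    pairs = [
        (r.gene_id, r.partner_id)
        for r in catalog.records
        if r.partner_id is not None and r.gene_id < r.partner_id
    ]
    pairs = [(a, d) if a.split(".")[1][0] == "A" else (d, a) for a, d in pairs]
    plan = config.bias_plan if config.bias_plan is not None else _default_bias_plan(len(pairs))
    if sum(plan.values()) > len(pairs):
        raise ConfigError("bias plan exceeds the number of dual loci")
    pair_iter = iter(pairs)
    for category, n_pairs in plan.items():
        for _ in range(n_pairs):
            at_id, dt_id = next(pair_iter)
            mult = _bias_multipliers(category, config.bias_fold)
            mean_ck[at_id] *= mult["CK"][0]
            mean_ck[dt_id] *= mult["CK"][1]
            mean_uv[at_id] *= mult["UV"][0]
            mean_uv[dt_id] *= mult["UV"][1]
            truth.bias_category[f"{at_id}|{dt_id}"] = category

    # plant DEGs on singleton loci (avoid interfering with bias pairs)
    singles = [r.gene_id for r in catalog.records if r.partner_id is None]
    n_deg = min(config.n_deg, len(singles))
    deg_genes = list(rng.choice(singles, size=n_deg, replace=False))
    for i, g in enumerate(deg_genes):
        if i % 2 == 0:
            mean_uv[g] *= 2.0**config.lfc_effect
            truth.deg_direction[g] = "up"
        else:
            mean_uv[g] /= 2.0**config.lfc_effect
            truth.deg_direction[g] = "down"

    lo, hi = config.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        mu = (mean_ck if metadata.loc[sample, "condition"] == "CK" else mean_uv).to_numpy()
        counts[:, j] = _nb_draw(rng, mu * sf[j], config.dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return counts_df, metadata, truth


def simulate_multistress_panel(
    catalog: GeneCatalog,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the multi-stress expression panel with planted modules.

    Structural genes from the catalog serve as module targets; synthetic
    transcription-factor genes (families WRKY, C2H2, HSF, ERF, ...) are added
    as regulators.  Module members share a latent stress-response profile plus
    Gaussian noise on the log2 scale; regulators follow their module's latent
    profile with positive sign except for ``n_negative_regulators`` planted
    repressors.  Background genes are independent noise.

    Returns ``(expression, roles, truth)`` where expression is on a linear
    FPKM-like scale (log-normal around ~256) and roles maps every gene to
    structural/regulatory plus a family label.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_needed = config.n_modules * config.module_size
    structural = catalog.gene_ids
    if n_needed > len(structural):
        raise ConfigError(
            f"{config.n_modules} modules x {config.module_size} genes exceed "
            f"the catalog ({len(structural)} genes)"
        )
    samples = [f"S{i+1:02d}" for i in range(config.n_stress_samples)]
    truth = GroundTruth()

    n_reg = config.n_modules * config.regulators_per_module
    regulator_ids = []
    reg_families = []
    for i in range(n_reg):
        fam = REGULATOR_FAMILIES[i % len(REGULATOR_FAMILIES)]
        chrom = (i % N_CHROMOSOMES) + 1
        letter = "A" if i % 2 == 0 else "D"
        regulator_ids.append(f"Gohir.{letter}{chrom:02d}G{900000 + i * 10:06d}")
        reg_families.append(fam)

    # module latents are orthogonalized (QR) so the planted stress axes are
    # uncorrelated by construction, not just in expectation
    raw_latents = rng.normal(0, 1, size=(len(samples), config.n_modules))
    q, _ = np.linalg.qr(raw_latents)
    latents = q.T * np.sqrt(len(samples))

    expr_log = {}
    member_iter = iter(structural)
    negative_left = config.n_negative_regulators
    for m in range(config.n_modules):
        latent = latents[m]
        module_targets = [next(member_iter) for _ in range(config.module_size)]
        for g in module_targets:
            expr_log[g] = latent + rng.normal(0, config.noise_sd, size=len(samples))
            truth.module_of_gene[g] = m + 1
        for r_local in range(config.regulators_per_module):
            rid = regulator_ids[m * config.regulators_per_module + r_local]
            sign = 1.0
            if negative_left > 0 and r_local == config.regulators_per_module - 1:
                sign = -1.0
                negative_left -= 1
            expr_log[rid] = sign * latent + rng.normal(0, config.noise_sd, size=len(samples))
            truth.module_of_gene[rid] = m + 1
            for g in module_targets:
                truth.regulator_edges.append(
                    {"regulator": rid, "target": g, "sign": "positive" if sign > 0 else "negative"}
                )

    for g in structural:
        if g not in expr_log:  # background: independent noise
            expr_log[g] = rng.normal(0, 1.0, size=len(samples))

    genes = structural + regulator_ids
    log_mat = np.vstack([expr_log[g] for g in genes])
    # map the latent log2 profiles onto a linear FPKM-like scale around 2^8
    expr = pd.DataFrame(
        2.0 ** (8.0 + 2.0 * log_mat),
        index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    fam_of = {r.gene_id: r.family for r in catalog.records}
    roles = pd.DataFrame(
        {
            "role": ["structural"] * len(structural) + ["regulatory"] * len(regulator_ids),
            "family": [fam_of[g] for g in structural] + reg_families,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return expr, roles, truth


def simulate_scale_free_profile(
    n_genes: int = 400,
    n_samples: int = 33,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression panel whose co-expression network has scale-free topology.

    A single latent stress axis drives every gene through a loading w_i in
    (0, 1) drawn so that w_i^6 is Pareto-distributed: gene-gene correlations
    are r_ij ~ w_i * w_j, hence soft-thresholded connectivity k_i ~ w_i^beta
    follows a power law -- the heavy-tailed hub structure a scale-free
    topology fit expects.  ``noise_sd`` perturbs the profiles on top of the
    intrinsic sqrt(1 - w^2) independent component.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, size=n_genes)
    # w^6 ~ Pareto(shape 1) truncated: heavy tail of hub loadings
    w = np.clip((0.02 / (1.0 - u * 0.999)) ** (1.0 / 6.0), 0.0, 0.98)
    latent = rng.normal(0, 1, size=n_samples)
    profiles = (
        w[:, None] * latent[None, :]
        + np.sqrt(1.0 - w[:, None] ** 2) * rng.normal(0, 1, size=(n_genes, n_samples))
        + rng.normal(0, noise_sd, size=(n_genes, n_samples))
    )
    genes = [f"Gohir.A{(j % N_CHROMOSOMES) + 1:02d}G{500000 + j * 100:06d}" for j in range(n_genes)]
    return pd.DataFrame(
        2.0 ** (8.0 + 2.0 * profiles),
        index=pd.Index(genes, name="gene_id"),
        columns=[f"S{j+1:02d}" for j in range(n_samples)],
    )


def simulate_qpcr(
    config: SimulationConfig,
    target_folds: dict[str, float] | None = None,
    reference_gene: str = "Gohir.A01G131900",
    ct_noise_sd: float = 0.15,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a Ct plate for relative quantification by the Livak method.

    Each target gene's UV ΔCt is shifted by -log2(fold) cycles relative to
    CK so that 2^-ΔΔCt recovers the planted fold; the reference gene has
    fold 1 by construction.  Gaussian cycle noise with ``ct_noise_sd``.
    """
    rng = np.random.default_rng(config.seed + 3)
    if target_folds is None:
        target_folds = {"Gohir.A05G123400": 4.0, "Gohir.D07G056700": 0.5}
    truth = GroundTruth(qpcr_fold=dict(target_folds))
    rows = []
    n_rep = config.n_replicates
    ref_ct = 20.0
    for cond in ("CK", "UV"):
        for rep in range(1, n_rep + 1):
            rows.append(
                {
                    "gene_id": reference_gene,
                    "condition": cond,
                    "replicate": rep,
                    "ct": ref_ct + rng.normal(0, ct_noise_sd),
                }
            )
    for gene, fold in target_folds.items():
        base_dct = rng.uniform(2.0, 6.0)  # target expressed below the reference
        for cond in ("CK", "UV"):
            shift = -np.log2(fold) if cond == "UV" else 0.0
            for rep in range(1, n_rep + 1):
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": ref_ct + base_dct + shift + rng.normal(0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows), truth
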