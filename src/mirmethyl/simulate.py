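"""Synthetic inputs with the statistical structure the pipeline assumes.

The methylation generator emulates an HM450 sub-array of miRNA-associated
probes from a small case/control corneal-endothelium cohort: per-probe
baselines are drawn bimodally on the M scale (low for unmethylated promoter
CpGs, high for gene bodies), group effects are planted gene-wise in miRNA
promoter probes as a constant M-scale shift, Gaussian M-scale noise is
added, and the matrix is mapped back to beta values through the logistic
transform beta = 2**M / (1 + 2**M).  Host-gene probes, one standout
("star") hypermethylated gene, and co-methylated host promoters are planted
so every downstream stage of the pipeline is exercisable.

The remaining generators invert the corresponding quantification formulas:
MethyLight plates are built so that PMR recomputation recovers the requested
truth exactly at zero noise, qPCR and luciferase experiments plant known
fold changes, UTRs embed exact seed-match windows on a rejection-sampled
background, and expression lists realise a requested overlap with the
planted hypermethylated gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import INTRAGENIC_CONTEXTS, validate_annotation
from .diffmeth import MethylationDataset
from .quant import PLATE_COLUMNS, MethyLightPlate
from .seeds import MatureMiRNA, find_seed_sites, site_window

# genomic-context proportions for intragenic miRNA genes (intronic, exonic, boundary)
_CONTEXT_PROPS = (0.56, 0.32, 0.12)
_PROMOTER_BASELINE = (-3.0, 0.5)  # M-scale mean, sd of unmethylated promoter baselines
_BODY_BASELINE = (2.0, 0.5)  # methylated gene-body baselines


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic methylation cohort.

    Defaults emulate the published study design: 2,227 miRNA-associated
    probes over 463 miRNA genes, 10 cases vs 9 controls, a 2.0 M-unit
    planted group effect with 0.5 M-unit per-probe noise, hypermethylation
    planted in ~7% and hypomethylation in ~3% of miRNA promoter probes, and
    one "star" gene boosted to twice the effect so a single standout
    hypermethylated miRNA exists, as observed in the real cohort.
    """

    n_probes: int = 2227
    n_mirna_genes: int = 463
    n_case: int = 10
    n_control: int = 9
    frac_hyper: float = 0.07
    frac_hypo: float = 0.03
    effect_size: float = 2.0
    noise_sd: float = 0.5
    frac_promoter: float = 0.7
    seed: int = 0
    # cohort structure beyond the miRNA probe matrix
    frac_intergenic: float = 0.27
    host_probes_per_gene: int = 8
    frac_host_promoter: float = 0.2
    frac_comethylated: float = 0.1
    star_gene_boost: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_mirna_genes", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_probes < self.n_mirna_genes:
            raise ValueError("n_probes must be >= n_mirna_genes")
        for name in ("frac_hyper", "frac_hypo", "frac_promoter", "frac_intergenic",
                     "frac_host_promoter", "frac_comethylated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_hyper + self.frac_hypo > 1:
            raise ValueError("frac_hyper + frac_hypo must not exceed 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.host_probes_per_gene < 0:
            raise ValueError("host_probes_per_gene must be >= 0")
        if self.star_gene_boost < 1:
            raise ValueError("star_gene_boost must be >= 1")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        # the largest |M| reachable must stay far from where beta rounds to 0/1
        extreme = max(abs(b[0]) for b in (_PROMOTER_BASELINE, _BODY_BASELINE))
        extreme += 4 * max(_PROMOTER_BASELINE[1], _BODY_BASELINE[1])
        if extreme + abs(self.effect_size) * self.star_gene_boost > 45:
            raise ValueError("effect_size pushes mean beta onto the (0,1) boundary")


@dataclass
class GroundTruth:
    """Planted truth: per-probe label in {hyper, hypo, null} and true M-scale group difference."""

    table: pd.DataFrame  # index probe_id: mirna_gene, host_gene, label, true_delta
    star_gene: str | None = None

    def __post_init__(self) -> None:
        null = self.table["label"] == "null"
        if (self.table.loc[null, "true_delta"] != 0).any():
            raise ValueError("null probes must have zero true difference")

    @property
    def hyper_genes(self) -> set[str]:
        mask = (self.table["label"] == "hyper") & (self.table["mirna_gene"] != "none")
        return set(self.table.loc[mask, "mirna_gene"])

    @property
    def hypo_genes(self) -> set[str]:
        mask = (self.table["label"] == "hypo") & (self.table["mirna_gene"] != "none")
        return set(self.table.loc[mask, "mirna_gene"])


def _plant_genes(rng, eligible: list[str], probes_per_gene: Mapping[str, int], target: int) -> list[str]:
    """Pick whole genes (in shuffled order) until their probe total reaches ``target``."""
    order = list(eligible)
    rng.shuffle(order)
    chosen, planted = [], 0
    for gene in order:
        if planted >= target:
            break
        chosen.append(gene)
        planted += probes_per_gene[gene]
    return chosen


def generate_methylation_dataset(config: SimulationConfig) -> tuple[MethylationDataset, GroundTruth]:
    """Simulate a beta-value matrix, probe annotation, sample metadata and ground truth.

    Deterministic given ``config.seed``.  Effects are planted gene-wise in
    miRNA promoter probes; for a fraction of hypermethylated genes the host
    gene's promoter probes receive the same shift (co-methylation).  The
    first planted hypermethylated gene is boosted by ``star_gene_boost`` and
    recorded as ``GroundTruth.star_gene``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = [f"miR-S{i:04d}" for i in range(1, cfg.n_mirna_genes + 1)]
    gene_idx = np.concatenate(
        [np.arange(cfg.n_mirna_genes), rng.integers(0, cfg.n_mirna_genes, cfg.n_probes - cfg.n_mirna_genes)]
    )
    rng.shuffle(gene_idx)
    mirna_gene = np.array(genes, dtype=object)[gene_idx]

    # per-gene host assignment
    intergenic = rng.random(cfg.n_mirna_genes) < cfg.frac_intergenic
    host_of, rel_of, ctx_of = {}, {}, {}
    for i, g in enumerate(genes):
        if intergenic[i]:
            host_of[g], rel_of[g], ctx_of[g] = "none", "none", "intergenic"
        else:
            host_of[g] = f"HOSTG{i + 1:04d}"
            rel_of[g] = "sense" if rng.random() < 0.8 else "antisense"
            ctx_of[g] = rng.choice(INTRAGENIC_CONTEXTS, p=_CONTEXT_PROPS)

    is_promoter = rng.random(cfg.n_probes) < cfg.frac_promoter
    region_class = np.where(is_promoter, "promoter", "body")
    host_gene = np.array([host_of[g] for g in mirna_gene], dtype=object)
    host_rel = np.array([rel_of[g] for g in mirna_gene], dtype=object)
    host_ctx = np.array([ctx_of[g] for g in mirna_gene], dtype=object)
    has_host = host_gene != "none"
    host_region = np.where(
        has_host, np.where(rng.random(cfg.n_probes) < cfg.frac_host_promoter, "promoter", "body"), "none"
    )
    probe_ids = [f"cg{i:08d}" for i in range(1, cfg.n_probes + 1)]

    rows = {
        "probe_id": probe_ids,
        "mirna_gene": list(mirna_gene),
        "region_class": list(region_class),
        "host_gene": list(host_gene),
        "host_relationship": list(host_rel),
        "host_context": list(host_ctx),
        "host_region_class": list(host_region),
    }

    # dedicated host-gene probes (mirna_gene == none)
    next_id = cfg.n_probes + 1
    host_rows = {k: [] for k in rows}
    for g in genes:
        host = host_of[g]
        if host == "none":
            continue
        for _ in range(cfg.host_probes_per_gene):
            host_rows["probe_id"].append(f"cg{next_id:08d}")
            next_id += 1
            host_rows["mirna_gene"].append("none")
            host_rows["region_class"].append("none")
            host_rows["host_gene"].append(host)
            host_rows["host_relationship"].append(rel_of[g])
            host_rows["host_context"].append(rng.choice(("intronic", "exonic"), p=(0.7, 0.3)))
            host_rows["host_region_class"].append(
                "promoter" if rng.random() < cfg.frac_host_promoter else "body"
            )
    annotation = pd.DataFrame({k: rows[k] + host_rows[k] for k in rows})
    annotation = validate_annotation(annotation)

    # gene-wise planting in miRNA promoter probes
    promoter_mask = annotation["region_class"] == "promoter"
    promoter_counts = annotation.loc[promoter_mask, "mirna_gene"].value_counts()
    eligible = sorted(promoter_counts.index)
    n_promoter = int(promoter_mask.sum())
    hyper_genes = _plant_genes(rng, eligible, promoter_counts, round(cfg.frac_hyper * n_promoter))
    remaining = [g for g in eligible if g not in set(hyper_genes)]
    hypo_genes = _plant_genes(rng, remaining, promoter_counts, round(cfg.frac_hypo * n_promoter))
    star = hyper_genes[0] if hyper_genes else None

    delta = pd.Series(0.0, index=annotation.index)
    label = pd.Series("null", index=annotation.index)
    for g in hyper_genes:
        mask = (annotation["mirna_gene"] == g) & promoter_mask
        eff = cfg.effect_size * (cfg.star_gene_boost if g == star else 1.0)
        delta[mask], label[mask] = eff, "hyper"
    for g in hypo_genes:
        mask = (annotation["mirna_gene"] == g) & promoter_mask
        delta[mask], label[mask] = -cfg.effect_size, "hypo"

    # co-methylation: host promoter probes of a fraction of hyper genes share the shift
    n_cometh = int(round(cfg.frac_comethylated * len(hyper_genes)))
    for g in hyper_genes[:n_cometh]:
        host = host_of[g]
        if host == "none":
            continue
        mask = (annotation["host_gene"] == host) & (annotation["host_region_class"] == "promoter")
        eff = cfg.effect_size * (cfg.star_gene_boost if g == star else 1.0)
        delta[mask], label[mask] = eff, "hyper"

    # baselines and sampling on the M scale
    n_total = len(annotation)
    low = (annotation["region_class"] == "promoter") | (
        (annotation["region_class"] == "none") & (annotation["host_region_class"] == "promoter")
    )
    mu = np.where(
        low,
        rng.normal(*_PROMOTER_BASELINE, n_total),
        rng.normal(*_BODY_BASELINE, n_total),
    )
    n_samples = cfg.n_case + cfg.n_control
    is_case = np.r_[np.ones(cfg.n_case, dtype=bool), np.zeros(cfg.n_control, dtype=bool)]
    m = (
        mu[:, None]
        + delta.to_numpy()[:, None] * is_case[None, :]
        + rng.normal(0.0, cfg.noise_sd, (n_total, n_samples))
    )
    beta = 1.0 / (1.0 + np.exp2(-m))
    if (beta <= 0).any() or (beta >= 1).any():
        raise ValueError("simulated beta values reached the (0,1) boundary; reduce effect_size")

    sample_ids = [f"FECD{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"CTRL{i + 1:02d}" for i in range(cfg.n_control)
    ]
    metadata = pd.DataFrame(
        {
            "group": np.where(is_case, "FECD", "control"),
            "age": np.round(rng.normal(70, 8, n_samples)).astype(int),
            "sex": rng.choice(("M", "F"), n_samples),
            "pachymetry": np.round(rng.normal(600, 30, n_samples), 1),
            "guttata_grade": rng.integers(0, 6, n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    beta_df = pd.DataFrame(beta, index=annotation.index, columns=sample_ids)

    dataset = MethylationDataset(beta=beta_df, metadata=metadata, annotation=annotation)
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "mirna_gene": annotation["mirna_gene"],
                "host_gene": annotation["host_gene"],
                "label": label,
                "true_delta": delta,
            },
            index=annotation.index,
        ),
        star_gene=star,
    )
    return dataset, truth


def generate_methylight_plate(
    true_pmr_by_sample: Mapping[str, float],
    ct_alu_base: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    gene: str = "GENE",
    reference_id: str = "M.SssI",
) -> MethyLightPlate:
    """Build a MethyLight plate whose exact PMR recomputation recovers the requested truth.

    The fully methylated reference gets equal GENE and ALU Cts (ratio 1);
    each sample's ALU Ct is fixed at ``ct_alu_base`` and its GENE Ct is
    offset by -log2(PMR/100), which makes the PMR formula exactly invertible
    at ``noise_sd = 0``.  A PMR of exactly 0 is represented by a GENE Ct 60
    cycles beyond the ALU baseline (far past any detection limit).
    """
    for sample, value in true_pmr_by_sample.items():
        if value < 0:
            raise ValueError(f"true PMR for {sample!r} must be >= 0, got {value}")
    if reference_id in true_pmr_by_sample:
        raise ValueError(f"{reference_id!r} is reserved for the methylated reference")
    if noise_sd < 0 or n_replicates < 1:
        raise ValueError("noise_sd must be >= 0 and n_replicates >= 1")
    rng = np.random.default_rng(seed)

    records = []

    def add_wells(sample: str, reaction: str, ct: float, is_ref: bool) -> None:
        for r in range(n_replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            records.append((sample, reaction, r + 1, ct + noise, is_ref))

    add_wells(reference_id, "GENE", ct_alu_base, True)
    add_wells(reference_id, "ALU", ct_alu_base, True)
    for sample, value in true_pmr_by_sample.items():
        ct_gene = ct_alu_base + 60.0 if value == 0 else ct_alu_base - float(np.log2(value / 100.0))
        add_wells(sample, "GENE", ct_gene, False)
        add_wells(sample, "ALU", ct_alu_base, False)

    wells = pd.DataFrame(records, columns=list(PLATE_COLUMNS))
    return MethyLightPlate(wells=wells, reference_sample_id=reference_id, gene=gene)


def generate_qpcr_experiment(
    true_fold: float = 0.5,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    ct_housekeeping: float = 18.0,
    ct_target_base: float = 24.0,
) -> dict[str, np.ndarray]:
    """Ct vectors for a qPCR experiment with a planted fold change vs control.

    Returns target/housekeeping Ct arrays for the condition and the control;
    with zero noise, :func:`mirmethyl.quant.ddct_fold_change` recovers
    ``true_fold`` exactly.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    rng = np.random.default_rng(seed)
    shape = (n_replicates,)
    dct_control = ct_target_base - ct_housekeeping
    return {
        "ct_target": ct_housekeeping + dct_control - np.log2(true_fold) + rng.normal(0, noise_sd, shape),
        "ct_housekeeping": np.full(shape, ct_housekeeping) + rng.normal(0, noise_sd, shape),
        "ct_target_control": np.full(shape, ct_target_base) + rng.normal(0, noise_sd, shape),
        "ct_housekeeping_control": np.full(shape, ct_housekeeping) + rng.normal(0, noise_sd, shape),
    }


def generate_luciferase_experiment(
    true_effect: float = 0.5,
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    firefly_base: float = 1e5,
    beta_gal_base: float = 5e4,
) -> dict[str, np.ndarray]:
    """Firefly / beta-galactosidase activities with a planted relative effect vs negative control."""
    if true_effect <= 0:
        raise ValueError("true_effect must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (n_replicates,)

    def noisy(base: float) -> np.ndarray:
        return np.clip(base * (1.0 + rng.normal(0, cv, shape)), base * 1e-3, None)

    return {
        "firefly": noisy(firefly_base * true_effect),
        "beta_gal": noisy(beta_gal_base),
        "negctrl_firefly": noisy(firefly_base),
        "negctrl_beta_gal": noisy(beta_gal_base),
    }


def generate_utr_with_sites(
    length: int,
    mirna: MatureMiRNA,
    site_starts: Sequence[int],
    seed: int = 0,
    site_type: str = "7mer-m8",
    max_attempts: int = 500,
) -> str:
    """A random 3'-UTR containing exact seed-match windows at the requested starts only.

    The requested windows are written at the given 1-based positions and the
    background is rejection-sampled until a rescan reports exactly the
    requested sites (no spurious matches, no class upgrades at the edges).
    """
    window = site_window(mirna, site_type)
    w = len(window)
    starts = sorted(int(s) for s in site_starts)
    for s in starts:
        if s < 1 or s + w - 1 > length:
            raise ValueError(f"site at {s} does not fit inside a {length}-nt UTR")
    for a, b in zip(starts, starts[1:]):
        if a + w > b:
            raise ValueError(f"sites at {a} and {b} overlap")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        seq = rng.choice(bases, size=length)
        for s in starts:
            seq[s - 1 : s - 1 + w] = list(window)
        candidate = "".join(seq)
        found = find_seed_sites(candidate, mirna)
        if [x.start for x in found] == starts and all(x.site_type == site_type for x in found):
            return candidate
    raise RuntimeError("could not sample a background free of spurious seed matches")


def generate_expression_list(
    ground_truth: GroundTruth,
    n_downregulated: int,
    overlap_with_hyper: int,
    seed: int = 0,
    must_include: Sequence[str] = (),
) -> list[str]:
    """Mature-miRNA names for a down-regulated list with a planted overlap.

    Exactly ``overlap_with_hyper`` names come from the planted
    hypermethylated miRNA genes (``must_include`` forces specific ones); the
    remainder are non-hypermethylated gene names, padded with invented names
    if needed.  Names are emitted in mature style (``hsa-<gene>-5p``) so the
    intersection stage has to normalise them.
    """
    hyper = sorted(ground_truth.hyper_genes)
    if overlap_with_hyper < 0 or n_downregulated <= 0:
        raise ValueError("counts must be positive")
    if overlap_with_hyper > min(n_downregulated, len(hyper)):
        raise ValueError(
            f"overlap {overlap_with_hyper} infeasible: only {len(hyper)} planted hyper genes "
            f"and {n_downregulated} requested names"
        )
    must = list(dict.fromkeys(must_include))
    if set(must) - set(hyper):
        raise ValueError("must_include contains genes that are not planted hypermethylated")
    if len(must) > overlap_with_hyper:
        raise ValueError("must_include longer than the requested overlap")

    rng = np.random.default_rng(seed)
    pool = sorted(set(hyper) - set(must))
    chosen = must + list(rng.choice(pool, size=overlap_with_hyper - len(must), replace=False))

    all_genes = set(ground_truth.table.loc[ground_truth.table["mirna_gene"] != "none", "mirna_gene"])
    non_hyper = sorted(all_genes - set(hyper))
    n_rest = n_downregulated - overlap_with_hyper
    if n_rest <= len(non_hyper):
        rest = list(rng.choice(non_hyper, size=n_rest, replace=False))
    else:
        rest = non_hyper + [f"miR-X{j:03d}" for j in range(1, n_rest - len(non_hyper) + 1)]

    names = [f"hsa-{g.lower()}-5p" for g in chosen + rest]
    rng.shuffle(names)
    return names
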