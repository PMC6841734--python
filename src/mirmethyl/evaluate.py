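"""End-to-end evaluation on synthetic data with known ground truth.

These routines quantify how well the pipeline behaves under its own
generative model: operating characteristics of the probe-level test
(sensitivity, empirical FDR, type-I error), exactness of the MethyLight
round trip, agreement of the seed scanner with a literal window-by-window
reference implementation, and a full synthetic run from planted
hypermethylation through expression overlap to a reporter-assay readout.

Problem sizes default to desk scale (a few thousand probes, ~10^3 random
UTRs) so a full evaluation completes in seconds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import hostgenes, integrate
from .diffmeth import differential_methylation, rank_top, volcano_filter
from .io import load_mature_mirnas
from .quant import ddct_fold_change, pmr, relative_luciferase
from .seeds import MatureMiRNA, design_mutant_utr, find_seed_sites, _RNA_TO_DNA_COMPLEMENT
from .simulate import (
    SimulationConfig,
    generate_expression_list,
    generate_luciferase_experiment,
    generate_methylation_dataset,
    generate_methylight_plate,
    generate_qpcr_experiment,
    generate_utr_with_sites,
)

#: conditions of the parameter-recovery benchmark: the planted effect, noise
#: and group sizes of the emulated cohort, but with true effects planted in
#: half the promoter probes so that the empirical FDR of raw-p selection is
#: a meaningful quantity (with mostly-null probes it is dominated by pi0).
RECOVERY_CONFIG = SimulationConfig(
    n_probes=2000,
    n_mirna_genes=400,
    n_case=10,
    n_control=9,
    frac_hyper=0.5,
    frac_hypo=0.2,
    effect_size=2.0,
    noise_sd=0.5,
    frac_promoter=0.7,
    host_probes_per_gene=0,
    frac_comethylated=0.0,
    star_gene_boost=1.0,
)


def parameter_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: SimulationConfig = RECOVERY_CONFIG,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.3,
) -> dict[str, float]:
    """Average sensitivity and empirical FDR of volcano selection over seeds.

    A planted probe counts as detected when it is selected with the planted
    direction; a selection is false when the probe is null or its direction
    disagrees with the planted one.
    """
    sens, fdr = [], []
    for i in range(n_seeds):
        ds, gt = generate_methylation_dataset(replace(config, seed=base_seed + i))
        res, _ = volcano_filter(differential_methylation(ds), p_threshold, fc_threshold)
        truth = gt.table["label"]
        planted = truth != "null"
        selected = res["direction"] != "ns"
        correct = selected & planted & (res["direction"] == truth)
        sens.append(correct.sum() / planted.sum())
        fdr.append((selected & ~correct).sum() / max(int(selected.sum()), 1))
    return {"sensitivity": float(np.mean(sens)), "fdr": float(np.mean(fdr)), "n_seeds": n_seeds}


def type1_error(
    n_probes: int = 10000, seed: int = 0, p_threshold: float = 0.05
) -> dict[str, float]:
    """Fraction of null probes with p below threshold (no effects planted)."""
    cfg = replace(
        RECOVERY_CONFIG, n_probes=n_probes, n_mirna_genes=max(n_probes // 5, 1),
        frac_hyper=0.0, frac_hypo=0.0, seed=seed,
    )
    ds, _ = generate_methylation_dataset(cfg)
    res = differential_methylation(ds)
    return {
        "rate": float((res["p_value"] < p_threshold).mean()),
        "n_probes": n_probes,
    }


def methylight_roundtrip(seed: int = 0) -> dict[str, float]:
    """Exactness of zero-noise PMR recovery and invariance under a global Ct shift."""
    truth = {"s_zero": 0.0, "s_low": 3.0, "s_mid": 20.0, "s_ref_like": 100.0, "s_high": 250.0}
    plate = generate_methylight_plate(truth, noise_sd=0.0, seed=seed)
    err = max(abs(pmr(plate, s).pmr - v) for s, v in truth.items())

    shifted = replace(plate, wells=plate.wells.assign(ct=plate.wells["ct"] + 2.5))
    shift_err = max(abs(pmr(shifted, s).pmr - pmr(plate, s).pmr) for s in truth)
    return {"roundtrip_max_abs_error": float(err), "shift_invariance_max_abs_error": float(shift_err)}


def _bruteforce_sites(utr: str, mirna: MatureMiRNA) -> list[tuple[int, int, str]]:
    """Reference seed scan: test complementarity literally at every window.

    Independent of :func:`mirmethyl.seeds.find_seed_sites`; returns
    (start, end, site_type) triples with 1-based inclusive coordinates.
    """
    utr = utr.upper()
    seq = mirna.sequence
    comp = _RNA_TO_DNA_COMPLEMENT
    out = []
    for p in range(len(utr) - 5):  # 0-based start of the 6-nt core
        ok = True
        for k in range(6):  # target base at p+k pairs miRNA position 7-k
            if utr[p + k] != comp[seq[6 - k]]:
                ok = False
                break
        if not ok:
            continue
        m8 = len(seq) >= 8 and p >= 1 and utr[p - 1] == comp[seq[7]]
        a1 = p + 6 < len(utr) and utr[p + 6] == "A"
        if m8 and a1:
            out.append((p, p + 7, "8mer"))
        elif m8:
            out.append((p, p + 6, "7mer-m8"))
        elif a1:
            out.append((p + 1, p + 7, "7mer-A1"))
        else:
            out.append((p + 1, p + 6, "6mer"))
    return sorted(out)


def seed_scanner_agreement(n_utrs: int = 1000, seed: int = 0, mirna: MatureMiRNA | None = None) -> dict[str, float]:
    """Fraction of random UTRs on which the scanner matches the brute-force reference."""
    if mirna is None:
        mirna = load_mature_mirnas()["miR-199b-5p"]
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGTN"))
    agree = 0
    for _ in range(n_utrs):
        length = int(rng.integers(30, 400))
        # bias the background toward the seed alphabet so matches actually occur
        utr = "".join(rng.choice(bases, size=length, p=(0.3, 0.25, 0.25, 0.19, 0.01)))
        got = [(s.start, s.end, s.site_type) for s in find_seed_sites(utr, mirna)]
        agree += got == _bruteforce_sites(utr, mirna)
    return {"agreement": agree / n_utrs, "n_utrs": n_utrs}


def end_to_end(seed: int = 0) -> dict[str, float]:
    """Full synthetic run: methylation -> overlap -> seed site -> reporter assay.

    Generates the default emulated cohort, selects differentially methylated
    probes, intersects the detected hypermethylated genes with a synthetic
    down-regulated list guaranteed to contain the planted star gene, and
    simulates the reporter follow-up: a UTR carrying one seed site for the
    packaged miR-199 guide, its seed-disrupted mutant, and luciferase/qPCR
    experiments in which the repression effect applies only when the scanner
    finds a site.
    """
    cfg = SimulationConfig(seed=seed)
    ds, gt = generate_methylation_dataset(cfg)
    res, counts = volcano_filter(differential_methylation(ds))

    # gene-level coefficients over selected hypermethylated miRNA promoter probes
    sel = res[(res["direction"] == "hyper") & (res["mirna_gene"] != "none")]
    coeff_by_gene = sel.groupby("mirna_gene")["coeff"].max().to_dict()

    star = gt.star_gene
    down = generate_expression_list(
        gt, n_downregulated=87, overlap_with_hyper=18, seed=seed + 1, must_include=[star]
    )
    overlap = integrate.intersect(coeff_by_gene, down)
    norm_star = integrate.normalize_mirna_name(star)
    star_rank = next(
        (i + 1 for i, (g, _, _) in enumerate(overlap.concurrent) if g == norm_star), 0
    )

    mirna = load_mature_mirnas()["miR-199b-5p"]
    utr = generate_utr_with_sites(1000, mirna, [725], seed=seed + 2)
    sites = find_seed_sites(utr, mirna, utr_id="synthetic_utr")
    mutant = design_mutant_utr(utr, sites[0], mirna)
    wt_has_site = bool(sites)
    mut_has_site = bool(find_seed_sites(mutant, mirna))

    luc_wt = generate_luciferase_experiment(0.5 if wt_has_site else 1.0, n_replicates=9, seed=seed + 3)
    luc_mut = generate_luciferase_experiment(0.5 if mut_has_site else 1.0, n_replicates=9, seed=seed + 4)
    wt_activity = relative_luciferase(**luc_wt, condition="mimic_wt").fold_change
    mut_activity = relative_luciferase(**luc_mut, condition="mimic_mut").fold_change

    qpcr = generate_qpcr_experiment(true_fold=0.5, n_replicates=9, seed=seed + 5)
    knockdown = ddct_fold_change(**qpcr, condition="mimic").fold_change

    return {
        "n_selected": counts.total,
        "n_hyper": counts.hyper,
        "n_hypo": counts.hypo,
        "n_concurrent": overlap.n_both,
        "star_rank": star_rank,
        "site_start": sites[0].start if sites else 0,
        "mutant_site_count": int(mut_has_site),
        "wt_mimic_luciferase": wt_activity,
        "mutant_mimic_luciferase": mut_activity,
        "qpcr_mimic_fold": knockdown,
    }
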