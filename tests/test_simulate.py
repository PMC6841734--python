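import numpy as np
import pytest

from mirmethyl.diffmeth import beta_to_m
from mirmethyl.quant import pmr
from mirmethyl.seeds import find_seed_sites
from mirmethyl.simulate import (
    SimulationConfig,
    generate_expression_list,
    generate_methylation_dataset,
    generate_methylight_plate,
    generate_utr_with_sites,
)


def test_same_seed_is_bit_identical():
    cfg = SimulationConfig(n_probes=200, n_mirna_genes=40, seed=9)
    ds1, gt1 = generate_methylation_dataset(cfg)
    ds2, gt2 = generate_methylation_dataset(cfg)
    assert np.array_equal(ds1.beta.to_numpy(), ds2.beta.to_numpy())
    assert gt1.table.equals(gt2.table)
    ds3, _ = generate_methylation_dataset(SimulationConfig(n_probes=200, n_mirna_genes=40, seed=10))
    assert not np.array_equal(ds1.beta.to_numpy(), ds3.beta.to_numpy())


def test_no_planted_effects_means_all_null():
    cfg = SimulationConfig(n_probes=150, n_mirna_genes=30, frac_hyper=0.0, frac_hypo=0.0, seed=2)
    ds, gt = generate_methylation_dataset(cfg)
    assert (gt.table["label"] == "null").all()
    assert (gt.table["true_delta"] == 0).all()
    assert gt.star_gene is None


def test_beta_strictly_inside_unit_interval_and_labels_partition():
    cfg = SimulationConfig(n_probes=300, n_mirna_genes=60, seed=4, host_probes_per_gene=2)
    ds, gt = generate_methylation_dataset(cfg)
    vals = ds.beta.to_numpy()
    assert (vals > 0).all() and (vals < 1).all()
    assert set(gt.table["label"]) <= {"hyper", "hypo", "null"}
    assert gt.table.index.equals(ds.beta.index)
    assert (gt.table.loc[gt.table["label"] == "null", "true_delta"] == 0).all()


def test_planted_effect_recovered_on_m_scale():
    cfg = SimulationConfig(
        n_probes=2000, n_mirna_genes=400, effect_size=2.0, noise_sd=0.5,
        n_case=10, n_control=9, host_probes_per_gene=0, star_gene_boost=1.0, seed=6,
    )
    ds, gt = generate_methylation_dataset(cfg)
    m = beta_to_m(ds.beta)
    hyper = gt.table.index[gt.table["label"] == "hyper"]
    diffs = m.loc[hyper, ds.case_samples].mean(axis=1) - m.loc[hyper, ds.control_samples].mean(axis=1)
    se = cfg.noise_sd * np.sqrt(1 / cfg.n_case + 1 / cfg.n_control) / np.sqrt(len(hyper))
    assert abs(diffs.mean() - 2.0) < 3 * se


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_case": 0},
        {"frac_hyper": 0.8, "frac_hypo": 0.3},
        {"frac_promoter": 1.2},
        {"noise_sd": 0.0},
        {"effect_size": 100.0},
        {"n_probes": 10, "n_mirna_genes": 20},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_methylight_zero_noise_recovers_truth_exactly():
    plate = generate_methylight_plate({"s1": 100.0}, noise_sd=0.0)
    assert pmr(plate, "s1").pmr == pytest.approx(100.0, abs=1e-9)
    plate = generate_methylight_plate({"s1": 20.0, "s2": 3.0}, noise_sd=0.0)
    assert pmr(plate, "s1").pmr == pytest.approx(20.0, abs=1e-9)
    assert pmr(plate, "s2").pmr == pytest.approx(3.0, abs=1e-9)
    assert pmr(plate, plate.reference_sample_id).pmr == pytest.approx(100.0)
    zero = generate_methylight_plate({"s0": 0.0})
    assert pmr(zero, "s0").pmr == pytest.approx(0.0, abs=1e-9)


def test_methylight_negative_pmr_rejected():
    with pytest.raises(ValueError, match=">= 0"):
        generate_methylight_plate({"s1": -5.0})


def test_methylight_noisy_plates_unbiased():
    truth = 20.0
    recovered = [
        pmr(generate_methylight_plate({"s": truth}, noise_sd=0.2, seed=s), "s").pmr
        for s in range(100)
    ]
    recovered = np.asarray(recovered)
    se = recovered.std(ddof=1) / np.sqrt(len(recovered))
    assert abs(recovered.mean() - truth) < 3 * se


def test_utr_generator_plants_exactly_requested_sites(mir199b):
    utr = generate_utr_with_sites(300, mir199b, [], seed=1)
    assert find_seed_sites(utr, mir199b) == []

    utr = generate_utr_with_sites(1000, mir199b, [725], seed=1)
    sites = find_seed_sites(utr, mir199b)
    assert len(sites) == 1 and sites[0].start == 725 and sites[0].site_type == "7mer-m8"

    utr = generate_utr_with_sites(500, mir199b, [50, 400], seed=2)
    assert [s.start for s in find_seed_sites(utr, mir199b)] == [50, 400]

    with pytest.raises(ValueError, match="overlap"):
        generate_utr_with_sites(500, mir199b, [50, 52], seed=0)
    with pytest.raises(ValueError, match="fit"):
        generate_utr_with_sites(100, mir199b, [98], seed=0)


def test_expression_list_overlap_construction():
    cfg = SimulationConfig(n_probes=300, n_mirna_genes=60, frac_hyper=0.3, frac_hypo=0.1, seed=8)
    _, gt = generate_methylation_dataset(cfg)
    hyper = gt.hyper_genes

    from mirmethyl.integrate import normalize_mirna_name

    norm_hyper = {normalize_mirna_name(g) for g in hyper}

    disjoint = generate_expression_list(gt, n_downregulated=10, overlap_with_hyper=0, seed=1)
    assert {normalize_mirna_name(n) for n in disjoint} & norm_hyper == set()

    names = generate_expression_list(gt, n_downregulated=20, overlap_with_hyper=5, seed=1)
    assert len(names) == 20
    assert len({normalize_mirna_name(n) for n in names} & norm_hyper) == 5

    all_of_them = generate_expression_list(
        gt, n_downregulated=len(hyper), overlap_with_hyper=len(hyper), seed=1
    )
    assert {normalize_mirna_name(n) for n in all_of_them} == norm_hyper

    with pytest.raises(ValueError, match="infeasible"):
        generate_expression_list(gt, n_downregulated=5, overlap_with_hyper=len(hyper) + 5, seed=1)
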