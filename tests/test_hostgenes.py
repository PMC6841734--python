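import numpy as np
import pandas as pd
import pytest

from mirmethyl.diffmeth import MethylationDataset, differential_methylation, volcano_filter
from mirmethyl.hostgenes import (
    CoMethylationPair,
    find_comethylated_pairs,
    host_location_breakdown,
    select_host_probes,
)
from conftest import toy_annotation


def _results(rows):
    """rows: (probe_id, mirna_gene, coeff, direction)"""
    df = pd.DataFrame(rows, columns=["probe_id", "mirna_gene", "coeff", "direction"])
    df["log2_fc"] = df["coeff"]
    df["p_value"] = np.where(df["direction"] == "ns", 0.5, 1e-4)
    df["q_value"] = df["p_value"]
    return df.set_index("probe_id", drop=False)


def _host_annotation():
    rows = []
    # 3 host genes x 10 probes each; miR-1 -> H1, miR-2 -> H2, miR-3 (unselected) -> H3
    for g, host in (("miR-1", "H1"), ("miR-2", "H2"), ("miR-3", "H3")):
        for i in range(10):
            region = "promoter" if i < 3 else "body"
            rows.append((f"{host}_p{i}", "none", "none", host, "sense", "intronic", region))
        rows.append((f"{g}_prom", g, "promoter", host, "sense", "intronic", "body"))
    rows.append(("miR-4_prom", "miR-4", "promoter", "none", "none", "intergenic", "none"))
    return toy_annotation(rows)


def test_select_host_probes_counts():
    ann = _host_annotation()
    assert select_host_probes(ann, []) == set()
    assert select_host_probes(ann, ["miR-4"]) == set()  # intergenic miRNA has no host
    got = select_host_probes(ann, ["miR-1", "miR-2"])
    # 10 dedicated probes per host plus the miRNA's own intragenic probe, counted once
    assert len(got) == 22
    assert {"H1_p0", "H2_p9", "miR-1_prom"} <= got


def test_select_host_probes_accepts_results_frame():
    ann = _host_annotation()
    res = _results([("miR-1_prom", "miR-1", 2.0, "hyper"), ("miR-2_prom", "miR-2", 0.0, "ns")])
    assert len(select_host_probes(ann, res)) == 11


def test_host_location_breakdown_reported_percentages():
    rows, res_rows = [], []
    for i in range(188):
        region = "body" if i < 161 else "promoter"
        rows.append((f"h{i}", "none", "none", "H1", "sense", "intronic", region))
        res_rows.append((f"h{i}", "none", 2.0, "hyper"))
    for i in range(188, 239):
        region = "body" if i < 188 + 31 else "promoter"
        rows.append((f"h{i}", "none", "none", "H1", "sense", "intronic", region))
        res_rows.append((f"h{i}", "none", -2.0, "hypo"))
    ann = toy_annotation(rows)
    bd = host_location_breakdown(_results(res_rows), ann)
    assert bd["hyper"]["n"] == 188 and bd["hyper"]["pct"]["body"] == 86
    assert bd["hypo"]["n"] == 51 and bd["hypo"]["pct"]["body"] == 61
    assert bd["all"]["counts"]["body"] == 192 and bd["all"]["pct"]["body"] == 80


def test_host_location_breakdown_all_promoter_toy():
    rows = [(f"h{i}", "none", "none", "H1", "sense", "intronic", "promoter") for i in range(4)]
    bd = host_location_breakdown(_results([(f"h{i}", "none", 1.0, "hyper") for i in range(4)]),
                                 toy_annotation(rows))
    assert bd["hyper"]["pct"]["body"] == 0


def test_comethylation_requires_promoter_and_concordance():
    ann = _host_annotation()
    mirna_sel = _results([("miR-1_prom", "miR-1", 2.0, "hyper")])
    host_body_only = _results([("H1_p5", "none", 2.0, "hyper")])  # body probe
    assert find_comethylated_pairs(mirna_sel, host_body_only, ann) == []

    host_opposite = _results([("H1_p0", "none", -2.0, "hypo")])  # promoter, wrong direction
    assert find_comethylated_pairs(mirna_sel, host_opposite, ann) == []

    host_prom = _results([("H1_p0", "none", 1.8, "hyper")])
    pairs = find_comethylated_pairs(mirna_sel, host_prom, ann)
    assert len(pairs) == 1
    pair = pairs[0]
    assert (pair.mirna_gene, pair.host_gene, pair.direction) == ("miR-1", "H1", "hyper")
    assert pair.mirna_promoter_probes == ("miR-1_prom",)
    assert pair.host_promoter_probes == ("H1_p0",)
    assert pair.mean_coeff == pytest.approx(1.9)


def test_comethylation_pair_invariants():
    with pytest.raises(ValueError, match="nonempty"):
        CoMethylationPair("miR-1", "H1", (), ("h",), "hyper", 1.0)
    with pytest.raises(ValueError, match="direction"):
        CoMethylationPair("miR-1", "H1", ("m",), ("h",), "ns", 1.0)


def test_planted_comethylated_pairs_detected_in_simulation(small_cohort):
    ds, gt = small_cohort
    mirna_res, _ = volcano_filter(differential_methylation(ds))
    host_probes = select_host_probes(ds.annotation, mirna_res)
    host_ds = MethylationDataset(
        beta=ds.beta.loc[sorted(host_probes)], metadata=ds.metadata, annotation=ds.annotation
    )
    host_res, _ = volcano_filter(differential_methylation(host_ds))
    pairs = find_comethylated_pairs(mirna_res, host_res, ds.annotation)

    # every planted co-methylated miRNA/host pair with promoter probes on both sides is found
    tab = gt.table
    planted_hosts = set(
        tab.loc[(tab["label"] == "hyper") & (tab["mirna_gene"] == "none"), "host_gene"]
    )
    found = {(p.mirna_gene, p.host_gene) for p in pairs}
    ann = ds.annotation
    for host in planted_hosts:
        genes = set(ann.loc[(ann["host_gene"] == host) & (ann["mirna_gene"] != "none"), "mirna_gene"])
        planted_genes = genes & gt.hyper_genes
        with_promoter = {
            g for g in planted_genes
            if ((ann["mirna_gene"] == g) & (ann["region_class"] == "promoter")).any()
        }
        for g in with_promoter:
            assert (g, host) in found

    # referential integrity: member probes are selected with the pair's direction
    for p in pairs:
        for probe in p.mirna_promoter_probes:
            assert mirna_res.loc[probe, "direction"] == p.direction
        for probe in p.host_promoter_probes:
            assert host_res.loc[probe, "direction"] == p.direction
    assert [abs(p.mean_coeff) for p in pairs] == sorted(
        [abs(p.mean_coeff) for p in pairs], reverse=True
    )
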