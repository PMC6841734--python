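"""Host-gene differential methylation and miRNA / host promoter co-methylation.

Most miRNA genes reside in introns or exons of protein-coding host genes and
can be co-transcribed with them.  This module restricts the probe universe
to hosts of differentially methylated miRNA genes, breaks their selected
probes down by promoter vs gene body, and emits miRNA/host pairs whose
promoters are concordantly differentially methylated (same direction on at
least one promoter probe of each partner) — the qualitative co-methylation
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import LocationBreakdown, percentage


@dataclass(frozen=True)
class CoMethylationPair:
    """A miRNA gene and its host gene concordantly changed at both promoters."""

    mirna_gene: str
    host_gene: str
    mirna_promoter_probes: tuple
    host_promoter_probes: tuple
    direction: str
    mean_coeff: float

    def __post_init__(self) -> None:
        if not self.mirna_promoter_probes or not self.host_promoter_probes:
            raise ValueError("both promoter probe sets must be nonempty")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper or hypo, got {self.direction!r}")


def selected_mirna_genes(mirna_results: pd.DataFrame) -> set[str]:
    """miRNA genes with at least one volcano-selected probe."""
    sel = mirna_results[mirna_results["direction"].isin(("hyper", "hypo"))]
    return set(sel["mirna_gene"]) - {"none"}


def select_host_probes(annotation: pd.DataFrame, diffmeth_mirna_selected) -> set[str]:
    """All probes annotated to any host gene of a differentially methylated miRNA gene.

    ``diffmeth_mirna_selected`` is either a volcano-filtered miRNA results
    frame or an iterable of selected miRNA gene names.  Probes annotated
    both to a miRNA and to its host appear once (probe ids are unique).
    """
    if isinstance(diffmeth_mirna_selected, pd.DataFrame):
        genes = selected_mirna_genes(diffmeth_mirna_selected)
    else:
        genes = set(diffmeth_mirna_selected)
    hosts = set(annotation.loc[annotation["mirna_gene"].isin(genes), "host_gene"]) - {"none"}
    return set(annotation.index[annotation["host_gene"].isin(hosts)])


def host_location_breakdown(
    selected_host_results: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, dict]:
    """Promoter/body breakdown of selected host-gene probes, split by direction.

    Input is a results frame (with ``direction``) restricted to the
    host-probe universe.  For each of ``hyper`` and ``hypo`` the counts and
    integer percentages over {promoter, body} of the host gene are
    returned, plus the same breakdown over all selected probes under
    ``"all"``.
    """
    sel = selected_host_results[selected_host_results["direction"].isin(("hyper", "hypo"))]
    out: dict[str, dict] = {}
    for key, sub in (("all", sel), ("hyper", sel[sel["direction"] == "hyper"]),
                     ("hypo", sel[sel["direction"] == "hypo"])):
        if sub.empty:
            out[key] = {"n": 0, "counts": {"promoter": 0, "body": 0}, "pct": {}}
            continue
        regions = annotation.loc[sub.index, "host_region_class"]
        if (regions == "none").any():
            bad = list(regions.index[regions == "none"])[:5]
            raise ValueError(f"probes without a host gene in host breakdown: {bad}")
        counts = {c: int((regions == c).sum()) for c in ("promoter", "body")}
        out[key] = {
            "n": len(sub),
            "counts": counts,
            "pct": {c: percentage(k, len(sub)) for c, k in counts.items()},
        }
    return out


def find_comethylated_pairs(
    mirna_results: pd.DataFrame,
    host_results: pd.DataFrame,
    annotation: pd.DataFrame,
) -> list[CoMethylationPair]:
    """miRNA / host-gene pairs with same-direction selected promoter probes on both sides.

    ``mirna_results`` and ``host_results`` must both carry ``direction``
    columns computed under identical thresholds; the host frame covers the
    host-probe universe.  A pair is emitted per (miRNA, host, direction)
    whenever at least one miRNA *promoter* probe and at least one host
    *promoter* probe are selected with the same direction.  Pairs are
    sorted by descending |mean coefficient| over their member probes.
    """
    ann = annotation
    m_sel = mirna_results[mirna_results["direction"].isin(("hyper", "hypo"))]
    h_sel = host_results[host_results["direction"].isin(("hyper", "hypo"))]

    m_prom = m_sel[
        (ann.loc[m_sel.index, "region_class"] == "promoter").to_numpy()
        & (ann.loc[m_sel.index, "host_gene"] != "none").to_numpy()
    ]
    h_prom = h_sel[(ann.loc[h_sel.index, "host_region_class"] == "promoter").to_numpy()]

    pairs: list[CoMethylationPair] = []
    if m_prom.empty or h_prom.empty:
        return pairs

    host_by_dir: dict[tuple[str, str], pd.DataFrame] = {
        key: sub for key, sub in h_prom.groupby([ann.loc[h_prom.index, "host_gene"], "direction"])
    }
    grouped = m_prom.groupby(
        [ann.loc[m_prom.index, "mirna_gene"], ann.loc[m_prom.index, "host_gene"], "direction"]
    )
    for (mirna_gene, host_gene, direction), m_sub in grouped:
        h_sub = host_by_dir.get((host_gene, direction))
        if h_sub is None:
            continue
        # host promoter support must come from probes other than the miRNA's own
        h_only = h_sub.loc[~h_sub.index.isin(m_sub.index)]
        if h_only.empty:
            continue
        coeffs = np.concatenate([m_sub["coeff"].to_numpy(), h_only["coeff"].to_numpy()])
        pairs.append(
            CoMethylationPair(
                mirna_gene=mirna_gene,
                host_gene=host_gene,
                mirna_promoter_probes=tuple(m_sub.index),
                host_promoter_probes=tuple(h_only.index),
                direction=direction,
                mean_coeff=float(coeffs.mean()),
            )
        )
    return sorted(pairs, key=lambda p: (-abs(p.mean_coeff), p.mirna_gene, p.host_gene))


def pairs_table(pairs: list[CoMethylationPair]) -> pd.DataFrame:
    """Flatten co-methylation pairs into a writable table."""
    return pd.DataFrame(
        {
            "mirna_gene": [p.mirna_gene for p in pairs],
            "host_gene": [p.host_gene for p in pairs],
            "direction": [p.direction for p in pairs],
            "mean_coeff": [p.mean_coeff for p in pairs],
            "mirna_promoter_probes": [";".join(p.mirna_promoter_probes) for p in pairs],
            "host_promoter_probes": [";".join(p.host_promoter_probes) for p in pairs],
        }
    )
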