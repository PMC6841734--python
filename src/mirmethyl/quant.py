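"""Quantification formulas for the validation assays.

MethyLight: percent of methylated reference,
``PMR = 100 * (GENE/ALU)_sample / (GENE/ALU)_reference``, where GENE is a
methylation-specific reaction, ALU a methylation-independent normalisation
reaction, and the reference is M.SssI-treated fully methylated DNA.
Relative quantities are derived from Ct values as (1 + efficiency)**(-Ct)
with efficiency 1 by default, and replicates are averaged in the linear
domain before forming ratios.

qRT-PCR: the 2**(-ddCt) method against a housekeeping gene and a control
condition.  Dual luciferase: per-well firefly/beta-galactosidase ratios
normalised to the negative-control condition, which is 1 by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REACTIONS = ("GENE", "ALU")
PLATE_COLUMNS = ("sample_id", "reaction", "replicate", "ct", "is_reference")


@dataclass
class MethyLightPlate:
    """Ct values of a MethyLight plate.

    ``wells`` must have columns sample_id, reaction ('GENE'/'ALU'),
    replicate, ct; the plate must contain the fully methylated reference
    sample (``reference_sample_id``) and at least one well of each reaction
    for every sample.
    """

    wells: pd.DataFrame
    reference_sample_id: str
    gene: str = "GENE"

    def __post_init__(self) -> None:
        required = {"sample_id", "reaction", "replicate", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate wells missing columns: {sorted(missing)}")
        bad = set(self.wells["reaction"]) - set(REACTIONS)
        if bad:
            raise ValueError(f"unknown reaction label(s): {sorted(bad)}")
        if (self.wells["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for sample, sub in self.wells.groupby("sample_id"):
            have = set(sub["reaction"])
            if have != set(REACTIONS):
                raise ValueError(f"sample {sample!r} lacks reaction(s): {sorted(set(REACTIONS) - have)}")
        if self.reference_sample_id not in set(self.wells["sample_id"]):
            raise ValueError(f"reference sample {self.reference_sample_id!r} not on plate")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(set(self.wells["sample_id"]))


@dataclass(frozen=True)
class PMRValue:
    """Percent of methylated reference for one sample and assay."""

    sample_id: str
    gene: str
    pmr: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pmr) or self.pmr < 0:
            raise ValueError(f"PMR must be finite and >= 0, got {self.pmr}")


@dataclass
class QuantResult:
    """A relative-quantification result: fold change of a condition vs its control."""

    condition: str
    fold_change: float
    replicates: np.ndarray = field(repr=False)
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.fold_change) or self.fold_change <= 0:
            raise ValueError(f"fold change must be finite and > 0, got {self.fold_change}")


def _mean_quantity(cts: np.ndarray, efficiency: float) -> float:
    return float(np.mean((1.0 + efficiency) ** (-np.asarray(cts, dtype=float))))


def _gene_alu_ratio(plate: MethyLightPlate, sample_id: str, efficiency: float) -> float:
    sub = plate.wells[plate.wells["sample_id"] == sample_id]
    if sub.empty:
        raise KeyError(f"sample {sample_id!r} not on plate")
    quantities = {}
    for reaction in REACTIONS:
        cts = sub.loc[sub["reaction"] == reaction, "ct"].to_numpy()
        if cts.size == 0:
            raise ValueError(f"sample {sample_id!r} has no {reaction} wells")
        quantities[reaction] = _mean_quantity(cts, efficiency)
    if quantities["ALU"] == 0:
        raise ZeroDivisionError(f"sample {sample_id!r}: ALU quantity is zero")
    return quantities["GENE"] / quantities["ALU"]


def pmr(plate: MethyLightPlate, sample_id: str, gene: str | None = None, efficiency: float = 1.0) -> PMRValue:
    """Percent of methylated reference for one sample on a MethyLight plate.

    Replicate Cts are converted to relative quantities, averaged per
    reaction, and the sample's GENE/ALU ratio is expressed as a percentage of
    the fully methylated reference's ratio.
    """
    ref_ratio = _gene_alu_ratio(plate, plate.reference_sample_id, efficiency)
    if ref_ratio == 0:
        raise ZeroDivisionError("reference GENE/ALU ratio is zero")
    value = 100.0 * _gene_alu_ratio(plate, sample_id, efficiency) / ref_ratio
    return PMRValue(sample_id=sample_id, gene=gene or plate.gene, pmr=value)


def pmr_table(plate: MethyLightPlate, efficiency: float = 1.0) -> pd.DataFrame:
    """PMR of every sample on the plate (reference included, at 100 by construction)."""
    rows = [pmr(plate, s, efficiency=efficiency) for s in plate.sample_ids]
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in rows], "gene": [r.gene for r in rows], "pmr": [r.pmr for r in rows]}
    ).set_index("sample_id")


def compare_pmr_groups(pmr_case, pmr_control, method: str = "wilcoxon"):
    """Compare PMR values between two groups.

    Returns ``(mean_case, mean_control, p_value)``; the p-value comes from a
    two-sided Wilcoxon rank-sum (Mann-Whitney) test by default, or a Welch
    t-test with ``method="t"``.
    """
    case = np.asarray(pmr_case, dtype=float)
    control = np.asarray(pmr_control, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 PMR values per group")
    if method == "wilcoxon":
        p = float(stats.mannwhitneyu(case, control, alternative="two-sided").pvalue)
    elif method == "t":
        p = float(stats.ttest_ind(case, control, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}; use 'wilcoxon' or 't'")
    return float(case.mean()), float(control.mean()), p


def ddct_fold_change(
    ct_target,
    ct_housekeeping,
    ct_target_control,
    ct_housekeeping_control,
    condition: str = "treated",
) -> QuantResult:
    """Relative expression of a condition vs control by the 2**(-ddCt) method.

    dCt = Ct_target - Ct_housekeeping per replicate; ddCt is the difference
    of condition and control mean dCts; fold change = 2**(-ddCt).  The
    reported replicate values are per-replicate folds against the control
    mean dCt, and the p-value is a Welch t-test on the dCt replicates.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_h = np.asarray(ct_housekeeping, dtype=float)
    ct_tc = np.asarray(ct_target_control, dtype=float)
    ct_hc = np.asarray(ct_housekeeping_control, dtype=float)
    if ct_t.shape != ct_h.shape or ct_tc.shape != ct_hc.shape:
        raise ValueError("target and housekeeping Ct vectors must have matching lengths")
    dct = ct_t - ct_h
    dct_control = ct_tc - ct_hc
    ddct = dct.mean() - dct_control.mean()
    replicates = np.exp2(-(dct - dct_control.mean()))
    if len(dct) >= 2 and len(dct_control) >= 2 and (dct.var() > 0 or dct_control.var() > 0):
        p = float(stats.ttest_ind(dct, dct_control, equal_var=False).pvalue)
    else:
        p = 1.0 if ddct == 0 else float("nan")
    return QuantResult(condition=condition, fold_change=float(np.exp2(-ddct)), replicates=replicates, p_value=p)


def relative_luciferase(
    firefly,
    beta_gal,
    negctrl_firefly,
    negctrl_beta_gal,
    condition: str = "mimic",
) -> QuantResult:
    """Firefly activity normalised to beta-galactosidase and to the negative control.

    Per-well firefly/beta-gal ratios correct for transfection efficiency; the
    condition's mean ratio is divided by the negative control's mean ratio,
    so the negative control itself is exactly 1.  The p-value is a Welch
    t-test on the per-well ratios.
    """
    f = np.asarray(firefly, dtype=float)
    b = np.asarray(beta_gal, dtype=float)
    nf = np.asarray(negctrl_firefly, dtype=float)
    nb = np.asarray(negctrl_beta_gal, dtype=float)
    if f.shape != b.shape or nf.shape != nb.shape:
        raise ValueError("firefly and beta-gal vectors must have matching lengths")
    for arr, name in ((f, "firefly"), (b, "beta_gal"), (nf, "negctrl_firefly"), (nb, "negctrl_beta_gal")):
        if (arr <= 0).any():
            raise ValueError(f"{name} activities must be positive")
    ratios = f / b
    neg_ratios = nf / nb
    neg_mean = neg_ratios.mean()
    if len(ratios) >= 2 and len(neg_ratios) >= 2 and (ratios.var() > 0 or neg_ratios.var() > 0):
        p = float(stats.ttest_ind(ratios, neg_ratios, equal_var=False).pvalue)
    else:
        p = 1.0 if np.isclose(ratios.mean(), neg_mean) else float("nan")
    return QuantResult(
        condition=condition,
        fold_change=float(ratios.mean() / neg_mean),
        replicates=ratios / neg_mean,
        p_value=p,
    )
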