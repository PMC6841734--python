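"""Per-probe differential methylation between case and control groups.

Testing is done on M-values, M = log2(beta / (1 - beta)), the
variance-stabilised scale conventional for Infinium-array analysis.  The
per-probe group coefficient is the M-scale mean difference (case minus
control); the volcano fold change is 2**coeff, so a coefficient of 0.379
corresponds to the 1.3-fold boundary.  Probes are called differentially
methylated when p < p_threshold (strict) and |fold change| > fc_threshold
(strict); selection deliberately uses the raw p-value, not the
Benjamini-Hochberg q-value, which is reported alongside for context.

Global-pattern diagnostics (sample correlation, average-linkage clustering,
PCA with covariate association tests) operate on the same M-value matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from statsmodels.stats.multitest import multipletests

DEFAULT_EPS = 1e-6
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_FC_THRESHOLD = 1.3

RESULT_COLUMNS = ("probe_id", "mirna_gene", "coeff", "log2_fc", "p_value", "q_value", "direction")


@dataclass
class MethylationDataset:
    """A beta-value matrix (probes x samples) with per-sample metadata.

    ``metadata`` is indexed by sample id and must carry a ``group`` column
    with exactly the two labels ``case_label`` / ``control_label``; optional
    clinical covariates (age, sex, pachymetry, guttata_grade) ride along.
    ``annotation`` is the probe annotation table (see
    :mod:`mirmethyl.annotation`), optional for purely numerical work.
    """

    beta: pd.DataFrame
    metadata: pd.DataFrame
    annotation: pd.DataFrame | None = None
    case_label: str = "FECD"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if not self.beta.columns.equals(pd.Index(self.metadata.index)):
            missing = set(self.beta.columns) ^ set(self.metadata.index)
            if missing:
                raise ValueError(f"beta columns and metadata index disagree on: {sorted(missing)[:5]}")
            self.metadata = self.metadata.loc[self.beta.columns]
        if "group" not in self.metadata.columns:
            raise ValueError("metadata must have a 'group' column")
        groups = set(self.metadata["group"])
        if groups != {self.case_label, self.control_label}:
            raise ValueError(
                f"group labels must be exactly {{{self.case_label!r}, {self.control_label!r}}}, got {sorted(groups)}"
            )
        counts = self.metadata["group"].value_counts()
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per group")
        vals = self.beta.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("beta matrix contains non-finite values")
        if (vals <= 0).any() or (vals >= 1).any():
            raise ValueError("beta values must lie strictly inside (0, 1)")

    @property
    def case_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == self.case_label])

    @property
    def control_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == self.control_label])


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """M-value transform log2(beta/(1-beta)); beta is clipped into [eps, 1-eps] first."""
    arr = np.asarray(beta, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if arr.shape else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (1 + 2**M)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    return b if arr.shape else float(b)


def test_probe(m_case, m_control, covariates: pd.DataFrame | None = None):
    """Group test for a single probe on the M scale.

    Without covariates: coefficient = mean(case) - mean(control), two-sided
    Welch t-test.  With covariates: OLS of M on group + covariates, rows
    ordered case first then control; the returned coefficient and p-value are
    those of the group term.  Returns ``(coeff, p_value)``.
    """
    m_case = np.asarray(m_case, dtype=float)
    m_control = np.asarray(m_control, dtype=float)
    if len(m_case) < 2 or len(m_control) < 2:
        raise ValueError("need at least 2 observations per group")

    if covariates is None:
        coeff = float(m_case.mean() - m_control.mean())
        if m_case.var() == 0 and m_control.var() == 0:
            return (0.0, 1.0) if coeff == 0 else (coeff, 0.0)
        p = float(stats.ttest_ind(m_case, m_control, equal_var=False).pvalue)
        return coeff, p

    y = np.concatenate([m_case, m_control])
    group = np.r_[np.ones(len(m_case)), np.zeros(len(m_control))]
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != len(y):
        raise ValueError("covariate rows must equal n_case + n_control (case rows first)")
    X = sm.add_constant(np.column_stack([group, cov]), has_constant="add")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_methylation(dataset: MethylationDataset, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Welch-test every probe; returns a results frame indexed by probe_id.

    Columns: probe_id, mirna_gene (when annotation is attached), coeff
    (M-scale case-minus-control difference), log2_fc (identical to coeff by
    construction), p_value, q_value.  Degenerate zero-variance probes get
    p = 1 when the group means coincide and p = 0 otherwise.
    """
    m = beta_to_m(dataset.beta, eps=eps)
    mc = m[dataset.case_samples].to_numpy()
    mk = m[dataset.control_samples].to_numpy()
    coeff = mc.mean(axis=1) - mk.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(mc, mk, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad] = np.where(coeff[bad] == 0.0, 1.0, 0.0)

    res = pd.DataFrame(
        {
            "probe_id": dataset.beta.index,
            "coeff": coeff,
            "log2_fc": coeff,
            "p_value": p,
            "q_value": bh_adjust(p),
        }
    ).set_index("probe_id", drop=False)
    if dataset.annotation is not None:
        res.insert(1, "mirna_gene", dataset.annotation["mirna_gene"].reindex(res.index))
    else:
        res.insert(1, "mirna_gene", "none")
    return res


class VolcanoCounts(NamedTuple):
    total: int
    hyper: int
    hypo: int


def volcano_filter(
    results: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> tuple[pd.DataFrame, VolcanoCounts]:
    """Apply the volcano selection rule and set per-probe direction.

    A probe is selected when p_value < p_threshold (strict) and
    2**|coeff| > fc_threshold (strict); direction is ``hyper`` for positive
    coefficients, ``hypo`` for negative, ``ns`` otherwise.  Returns the
    results frame with a ``direction`` column plus (total, hyper, hypo)
    selection counts.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    res = results.copy()
    abs_fc = np.exp2(np.abs(res["coeff"].to_numpy(dtype=float)))
    selected = (res["p_value"].to_numpy(dtype=float) < p_threshold) & (abs_fc > fc_threshold)
    direction = np.where(selected, np.where(res["coeff"] > 0, "hyper", "hypo"), "ns")
    res["direction"] = direction
    counts = VolcanoCounts(
        total=int(selected.sum()),
        hyper=int((direction == "hyper").sum()),
        hypo=int((direction == "hypo").sum()),
    )
    return res, counts


def volcano_thresholds(
    p_threshold: float = DEFAULT_P_THRESHOLD, fc_threshold: float = DEFAULT_FC_THRESHOLD
) -> dict:
    """Guide-line positions for a volcano plot: horizontal -log10(p) cut and vertical +/-log2(fc) cuts."""
    return {
        "neg_log10_p": float(-np.log10(p_threshold)),
        "log2_fc": float(np.log2(fc_threshold)),
    }


def volcano_coordinates(results: pd.DataFrame) -> pd.DataFrame:
    """Per-probe volcano coordinates: x = log2 fold change, y = -log10 p."""
    with np.errstate(divide="ignore"):
        y = -np.log10(results["p_value"].to_numpy(dtype=float))
    return pd.DataFrame({"log2_fc": results["log2_fc"], "neg_log10_p": y}, index=results.index)


def rank_top(results: pd.DataFrame, k: int = 20, direction: str | None = None) -> pd.DataFrame:
    """Rank selected probes by coefficient magnitude.

    With ``direction=None`` the hypermethylated block comes first (descending
    coefficient), followed by the hypomethylated block (descending
    magnitude), mirroring how published top tables are laid out; pass
    ``direction="hyper"`` or ``"hypo"`` to rank one side only.  Ties break by
    ascending p-value then probe id.  If fewer than ``k`` probes are
    selected, all are returned with a warning.
    """
    if "direction" not in results.columns:
        raise ValueError("results must carry a direction column (run volcano_filter first)")
    if direction is None:
        sel = results[results["direction"].isin(("hyper", "hypo"))].copy()
    else:
        sel = results[results["direction"] == direction].copy()
    if sel.empty:
        warnings.warn("no selected probes to rank", stacklevel=2)
        return sel
    sel["_block"] = (sel["direction"] != "hyper").astype(int)
    sel["_mag"] = -sel["coeff"].abs()
    sel["_p"] = sel["p_value"].fillna(np.inf)
    sel.index.name = None  # probe_id stays as a column; avoid index/column ambiguity
    out = sel.sort_values(["_block", "_mag", "_p", "probe_id"]).drop(columns=["_block", "_mag", "_p"])
    out.index.name = "probe_id"
    if k > len(out):
        warnings.warn(f"requested top {k} but only {len(out)} probes selected", stacklevel=2)
        return out
    return out.head(k)


def sample_correlation_and_clustering(
    dataset: MethylationDataset, use_m: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Pearson sample correlation and average-linkage clustering.

    Correlation is computed across probes (on M-values by default); the
    dendrogram uses distance 1 - r with average linkage.  Returns the
    correlation matrix and the SciPy linkage (merge) matrix.
    """
    if dataset.beta.shape[1] < 3:
        raise ValueError("need at least 3 samples for clustering")
    X = beta_to_m(dataset.beta) if use_m else dataset.beta
    flat = [c for c in X.columns if X[c].nunique() == 1]
    if flat:
        raise ValueError(f"constant sample vector(s), correlation undefined: {flat}")
    corr = X.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return corr, Z


_CONTINUOUS_COVARIATES = ("age", "pachymetry", "guttata_grade")
_CATEGORICAL_COVARIATES = ("group", "sex")


def pca_covariate_check(dataset: MethylationDataset, n_components: int = 5) -> pd.DataFrame:
    """Associate principal components of the M-value matrix with sample covariates.

    PCA is fitted on centred M-values (samples x probes).  Continuous or
    ordinal covariates (age, pachymetry, guttata_grade) are tested per PC by
    Spearman correlation; categorical covariates (group, sex) by
    Kruskal-Wallis.  Missing covariate values are dropped per covariate;
    constant covariates yield NaN.  Returns a PC x covariate p-value table.
    """
    m = beta_to_m(dataset.beta).T  # samples x probes
    n_samples, n_probes = m.shape
    if n_components > min(n_samples - 1, n_probes):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_probes)={min(n_samples - 1, n_probes)}"
        )
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(m - m.mean(axis=0))
    meta = dataset.metadata.loc[m.index]

    rows = {}
    for j in range(n_components):
        pc = scores[:, j]
        row = {}
        for cov in _CATEGORICAL_COVARIATES + _CONTINUOUS_COVARIATES:
            if cov not in meta.columns:
                continue
            vals = meta[cov]
            mask = vals.notna().to_numpy()
            v, s = vals[mask], pc[mask]
            if mask.sum() < 3 or v.nunique() < 2:
                row[cov] = np.nan
                continue
            if cov in _CATEGORICAL_COVARIATES:
                groups = [s[(v == lvl).to_numpy()] for lvl in v.unique()]
                row[cov] = float(stats.kruskal(*groups).pvalue)
            else:
                row[cov] = float(stats.spearmanr(v.to_numpy(dtype=float), s).pvalue)
        rows[f"PC{j + 1}"] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class DifferentialMethylationSelector(SelectorMixin, BaseEstimator):
    """scikit-learn style selector keeping differentially methylated probes.

    ``fit(X, y)`` takes a beta-value matrix with samples as rows and probes
    as columns plus a two-level group label vector, Welch-tests every probe
    on the M scale and applies the volcano rule; ``transform`` then reduces a
    matrix to the selected probes.  Fitted attributes: ``results_`` (the
    per-probe results frame with direction), ``counts_`` and ``support_``.

    Parameters
    ----------
    p_threshold, fc_threshold : volcano selection cuts (strict inequalities).
    eps : beta clipping bound for the M transform.
    case_label : which of the two labels in ``y`` is the case group; by
        default the first label of ``numpy.unique(y)``.
    """

    def __init__(
        self,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        fc_threshold: float = DEFAULT_FC_THRESHOLD,
        eps: float = DEFAULT_EPS,
        case_label=None,
    ):
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.eps = eps
        self.case_label = case_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_probes)")
        if len(y) != X.shape[0]:
            raise ValueError("len(y) must equal the number of rows of X")
        labels = np.unique(y)
        if len(labels) != 2:
            raise ValueError(f"y must have exactly 2 groups, got {labels!r}")
        case = labels[0] if self.case_label is None else self.case_label
        if case not in labels:
            raise ValueError(f"case_label {case!r} not present in y")
        control = labels[labels != case][0]
        if (y == case).sum() < 2 or (y == control).sum() < 2:
            raise ValueError("need at least 2 samples per group")

        m = beta_to_m(X, eps=self.eps)
        mc, mk = m[y == case].T, m[y == control].T
        coeff = mc.mean(axis=1) - mk.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = np.asarray(stats.ttest_ind(mc, mk, axis=1, equal_var=False).pvalue, dtype=float)
        bad = ~np.isfinite(p)
        p[bad] = np.where(coeff[bad] == 0.0, 1.0, 0.0)
        res = pd.DataFrame(
            {
                "probe_id": [f"probe{i}" for i in range(X.shape[1])],
                "mirna_gene": "none",
                "coeff": coeff,
                "log2_fc": coeff,
                "p_value": p,
                "q_value": bh_adjust(p),
            }
        ).set_index("probe_id", drop=False)
        self.results_, self.counts_ = volcano_filter(res, self.p_threshold, self.fc_threshold)
        self.support_ = (self.results_["direction"] != "ns").to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_

    def _more_tags(self):
        return {"requires_y": True, "allow_nan": False}
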