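"""Probe-level annotation model: array probe -> miRNA gene -> host gene.

Each HM450-style probe record states which miRNA gene the probe interrogates,
whether it falls in the miRNA's promoter or body, and — for intragenic
miRNAs — the host protein-coding gene, the strand relationship (sense /
antisense) and the genomic context of the miRNA within that host (intronic,
exonic, intron/exon boundary).  Intergenic miRNAs carry no host fields.

Probes that interrogate a host gene directly (rather than the miRNA itself)
are carried in the same table with ``mirna_gene`` set to ``"none"``; for
those rows ``host_region_class`` says whether the probe sits in the host's
promoter or gene body.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

ANNOTATION_COLUMNS = (
    "probe_id",
    "mirna_gene",
    "region_class",
    "host_gene",
    "host_relationship",
    "host_context",
    "host_region_class",
)

REGION_CLASSES = {"promoter", "body", "none"}
HOST_RELATIONSHIPS = {"sense", "antisense", "none"}
HOST_CONTEXTS = {"intronic", "exonic", "intron_exon_boundary", "intergenic"}
HOST_REGION_CLASSES = {"promoter", "body", "none"}
INTRAGENIC_CONTEXTS = ("intronic", "exonic", "intron_exon_boundary")

_NONE_STRINGS = {"", "none", "na", "nan", "intergenic_none"}


class AnnotationError(ValueError):
    """Raised when an annotation table violates the probe annotation contract."""


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: name (e.g. miR-199b-5p), gene (e.g. MIR199B), RNA sequence 5'->3'."""

    name: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 8:
            raise ValueError(f"mature miRNA {self.name!r}: sequence shorter than 8 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(
                f"mature miRNA {self.name!r}: sequence must be RNA over ACGU, got {self.sequence!r}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe's annotation record (see module docstring for field semantics)."""

    probe_id: str
    mirna_gene: str
    region_class: str
    host_gene: str
    host_relationship: str
    host_context: str
    host_region_class: str


def _as_none(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "none"
    s = str(value).strip()
    return "none" if s.lower() in _NONE_STRINGS else s


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation table and return it indexed by probe_id.

    Enforces the category vocabularies and the host-field consistency rule:
    ``host_context == "intergenic"`` exactly when the probe has no host gene
    and no host relationship.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns and c != "probe_id"]
    if "probe_id" not in annotation.columns and annotation.index.name != "probe_id":
        missing.insert(0, "probe_id")
    if missing:
        raise AnnotationError(f"annotation table missing required columns: {missing}")

    df = annotation.reset_index() if annotation.index.name == "probe_id" else annotation.copy()
    for col in ("mirna_gene", "host_gene", "host_relationship", "host_region_class"):
        df[col] = df[col].map(_as_none)
    df["region_class"] = df["region_class"].map(_as_none)
    df["host_context"] = df["host_context"].map(_as_none)
    df["probe_id"] = df["probe_id"].astype(str)

    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise AnnotationError(f"duplicate probe_id(s): {sorted(dup.unique())[:5]}")

    for row in df.itertuples(index=False):
        where = f"probe {row.probe_id!r}"
        if row.region_class not in REGION_CLASSES:
            raise AnnotationError(f"{where}: unknown region_class {row.region_class!r}")
        if row.host_relationship not in HOST_RELATIONSHIPS:
            raise AnnotationError(f"{where}: unknown host_relationship {row.host_relationship!r}")
        if row.host_context not in HOST_CONTEXTS:
            raise AnnotationError(f"{where}: unknown host_context {row.host_context!r}")
        if row.host_region_class not in HOST_REGION_CLASSES:
            raise AnnotationError(f"{where}: unknown host_region_class {row.host_region_class!r}")
        no_host = row.host_gene == "none"
        if no_host != (row.host_context == "intergenic") or no_host != (
            row.host_relationship == "none"
        ):
            raise AnnotationError(
                f"{where}: host_gene/host_relationship/host_context inconsistent "
                f"({row.host_gene!r}, {row.host_relationship!r}, {row.host_context!r})"
            )
        if no_host != (row.host_region_class == "none"):
            raise AnnotationError(f"{where}: host_region_class inconsistent with host_gene")
        if row.mirna_gene == "none" and no_host:
            raise AnnotationError(f"{where}: probe annotates neither a miRNA nor a host gene")
        if row.mirna_gene != "none" and row.region_class == "none":
            raise AnnotationError(f"{where}: miRNA probe must be classed promoter or body")

    return df.set_index("probe_id", drop=False)


def load_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV and validate it (see :func:`validate_annotation`)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_annotation(df)


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, halves going away from zero (71.5 -> 72, -71.5 -> -72)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def percentage(k: int, n: int) -> int:
    """Integer percentage 100*k/n, rounded half away from zero; n must be positive."""
    if n <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_away_from_zero(100.0 * k / n)


@dataclass
class LocationBreakdown:
    """Counts and integer percentages of a probe set across genomic categories."""

    n: int
    region_counts: dict
    region_pct: dict
    context_counts: dict
    context_pct: dict
    intragenic_count: int
    intragenic_pct: int


def location_breakdown(
    probes, annotation: pd.DataFrame, region_key: str = "region_class"
) -> LocationBreakdown:
    """Break a probe set down by promoter/body and by genomic context.

    ``region_key`` selects the column used for the promoter/body split:
    ``region_class`` (position within the miRNA gene, the default) or
    ``host_region_class`` (position within the host gene).  Percentages use
    round-half-away-from-zero to the nearest integer, so the two halves of a
    partition sum to 100 +/- 1.
    """
    probes = list(probes)
    unknown = [p for p in probes if p not in annotation.index]
    if unknown:
        raise KeyError(f"probe_id(s) not in annotation: {unknown[:5]}")
    if not probes:
        raise ValueError("empty probe set")
    sub = annotation.loc[probes]
    n = len(sub)

    regions = sub[region_key]
    if (regions == "none").any():
        bad = sub.index[regions == "none"][:5].tolist()
        raise ValueError(f"probes without a {region_key} category: {bad}")
    region_counts = {c: int((regions == c).sum()) for c in ("promoter", "body")}
    region_pct = {c: percentage(k, n) for c, k in region_counts.items()}

    ctx = sub["host_context"]
    context_counts = {c: int((ctx == c).sum()) for c in HOST_CONTEXTS}
    context_pct = {c: percentage(k, n) for c, k in context_counts.items()}
    intragenic = sum(context_counts[c] for c in INTRAGENIC_CONTEXTS)

    return LocationBreakdown(
        n=n,
        region_counts=region_counts,
        region_pct=region_pct,
        context_counts=context_counts,
        context_pct=context_pct,
        intragenic_count=intragenic,
        intragenic_pct=percentage(intragenic, n),
    )


# --- published top-20 ranking fixtures -------------------------------------

_HOST_RE = re.compile(r"^(?P<gene>[\w.\-]+)\s*\((?P<rel>sense|antisense);\s*(?P<ctx>\w+)\)$")

_FIXTURES = {
    "mirna_top20": "top20_mirna_diffmeth.tsv",
    "host_top20": "top20_host_diffmeth.tsv",
}


def parse_host_field(text: str) -> tuple[str, str, str]:
    """Parse a ``"DNM1 (antisense; intronic)"`` style host descriptor.

    Returns (gene, relationship, context); the literal ``"intergenic"`` maps
    to ``("none", "none", "intergenic")``.
    """
    text = text.strip()
    if text.lower() == "intergenic":
        return "none", "none", "intergenic"
    m = _HOST_RE.match(text)
    if m is None:
        raise AnnotationError(f"cannot parse host descriptor {text!r}")
    ctx = m.group("ctx")
    if ctx not in HOST_CONTEXTS:
        raise AnnotationError(f"unknown context {ctx!r} in host descriptor {text!r}")
    return m.group("gene"), m.group("rel"), ctx


def load_table_fixture(which: str = "mirna_top20") -> pd.DataFrame:
    """Load a packaged top-20 differential-methylation ranking.

    ``mirna_top20``: ranked differentially methylated miRNA genes reported
    for FECD corneal endothelium (gene, array probe, host-gene descriptor,
    group coefficient, p-value category, q-value).  ``host_top20``: the
    analogous ranking over miRNA host genes.  Host/resident descriptors are
    parsed into separate columns.
    """
    if which not in _FIXTURES:
        raise ValueError(f"unknown fixture {which!r}; choose from {sorted(_FIXTURES)}")
    with resources.files("mirmethyl.data").joinpath(_FIXTURES[which]).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"coeff": float, "q_value": float})
    key = "host" if which == "mirna_top20" else "resident_mirna"
    parsed = df[key].map(parse_host_field)
    df[f"{key}_gene"] = [p[0] for p in parsed]
    df[f"{key}_relationship"] = [p[1] for p in parsed]
    df[f"{key}_context"] = [p[2] for p in parsed]
    df["direction"] = ["hyper" if c > 0 else "hypo" for c in df["coeff"]]
    return df


def fixture_as_results(fixture: pd.DataFrame) -> pd.DataFrame:
    """Convert a top-20 ranking fixture into a differential-methylation results frame.

    The published ranking reports only p-value categories, so ``p_value`` is
    left missing; ranking on such frames falls back to probe id for ties.
    """
    res = pd.DataFrame(
        {
            "probe_id": fixture["probe_id"],
            "mirna_gene": fixture["gene"],
            "coeff": fixture["coeff"],
            "log2_fc": fixture["coeff"],
            "p_value": float("nan"),
            "q_value": fixture["q_value"],
            "direction": fixture["direction"],
        }
    )
    return res.set_index("probe_id", drop=False)
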