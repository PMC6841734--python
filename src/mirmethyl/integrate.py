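"""Intersect hypermethylated miRNA genes with a down-regulated miRNA list.

Methylation results are keyed by miRNA *gene* names (e.g. miR-199B) while
expression studies report mature names (e.g. hsa-miR-199b-5p); the
normaliser maps both onto a canonical upper-cased gene key by stripping the
species prefix and the -5p/-3p arm suffix.  Irregular aliases can be
supplied as an explicit mapping.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

_ARM_SUFFIX = re.compile(r"-(5p|3p)$", re.IGNORECASE)
_SPECIES_PREFIX = re.compile(r"^hsa-", re.IGNORECASE)
_VALID_NAME = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._\-]*$")


@dataclass
class OverlapResult:
    """Overlap of hypermethylated genes with a down-regulated list.

    ``concurrent`` lists the genes in both sets, ordered by descending
    methylation coefficient, as (gene, supplied name, coeff) tuples.
    """

    n_hyper: int
    n_down: int
    n_both: int
    concurrent: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_hyper, self.n_down):
            raise ValueError("overlap exceeds one of the input set sizes")
        if len(self.concurrent) != self.n_both:
            raise ValueError("concurrent list length must equal n_both")

    @property
    def n_union(self) -> int:
        return self.n_hyper + self.n_down - self.n_both


def normalize_mirna_name(name: str) -> str:
    """Canonical gene key for a miRNA name; idempotent.

    Strips a leading ``hsa-`` and a trailing ``-5p``/``-3p`` arm suffix and
    upper-cases the remainder, so ``hsa-miR-199b-5p`` and ``miR-199B`` both
    map to ``MIR-199B``.  Numeric paralog suffixes (``miR-194-2``) are kept.
    Names that do not look like miRNA identifiers are passed through
    verbatim with a warning.
    """
    if not name or not name.strip():
        raise ValueError("empty miRNA name")
    stripped = name.strip()
    if not _VALID_NAME.match(stripped):
        warnings.warn(f"unparseable miRNA name {name!r}; passing through verbatim", stacklevel=2)
        return name
    out = _SPECIES_PREFIX.sub("", stripped)
    out = _ARM_SUFFIX.sub("", out)
    return out.upper()


def intersect(
    hyper_genes,
    down_list: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> OverlapResult:
    """Exact set intersection of hypermethylated genes and a down-regulated list.

    ``hyper_genes`` is a mapping gene -> methylation coefficient (or a bare
    iterable of names, in which case coefficients are NaN); ``down_list``
    holds one miRNA name per entry.  ``aliases`` maps irregular supplied
    names to gene names before normalisation.  Duplicates collapsing under
    normalisation trigger a warning.
    """
    if isinstance(hyper_genes, Mapping):
        coeff_by_gene = {normalize_mirna_name(k): float(v) for k, v in hyper_genes.items()}
    else:
        coeff_by_gene = {normalize_mirna_name(g): float("nan") for g in hyper_genes}
    if isinstance(hyper_genes, Mapping) and len(coeff_by_gene) != len(hyper_genes):
        warnings.warn("duplicate hypermethylated gene names collapsed under normalisation", stacklevel=2)

    aliases = {normalize_mirna_name(k): v for k, v in (aliases or {}).items()}
    down_norm: dict[str, str] = {}
    n_dups = 0
    for raw in down_list:
        key = normalize_mirna_name(raw)
        key = normalize_mirna_name(aliases.get(key, key))
        if key in down_norm:
            n_dups += 1
            continue
        down_norm[key] = raw
    if n_dups:
        warnings.warn(f"{n_dups} duplicate name(s) in the down-regulated list collapsed", stacklevel=2)

    both = set(coeff_by_gene) & set(down_norm)
    concurrent = sorted(
        ((g, down_norm[g], coeff_by_gene[g]) for g in both),
        key=lambda t: (-(t[2] if t[2] == t[2] else float("-inf")), t[0]),
    )
    return OverlapResult(
        n_hyper=len(coeff_by_gene),
        n_down=len(down_norm),
        n_both=len(both),
        concurrent=concurrent,
    )


def load_down_list(path) -> list[str]:
    """Read a one-name-per-line down-regulated miRNA list (blank lines and # comments skipped)."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
    return names


def load_aliases(path) -> dict[str, str]:
    """Read a two-column TSV mapping supplied names to gene names."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError("alias table needs two columns: supplied name, gene name")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
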