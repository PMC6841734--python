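"""miRNA seed-match scanning in 3'-UTR sequences.

A seed match is Watson-Crick complementarity between the target mRNA and
nucleotides 2-7 at the 5' end of the miRNA.  Sites are classified with the
canonical hierarchy: 6mer (positions 2-7 only), 7mer-m8 (match extends to
miRNA position 8), 7mer-A1 (an adenine in the target opposite miRNA position
1) and 8mer (both).  Coordinates are 1-based and inclusive relative to the
first base of the 3'-UTR and span the full matched window, so a 7mer-m8 site
whose core starts at 726 is reported as 725-731.

UTRs are DNA over {A, C, G, T, N}; N never matches.  miRNA sequences are RNA
and are mapped to DNA before complementing (U pairs with A).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping

from .annotation import MatureMiRNA

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# complement of an RNA base, written as DNA
_RNA_TO_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}
# transversion substitutions (purine <-> pyrimidine), tried in order
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("T", "C"), "C": ("A", "G"), "T": ("G", "A")}


@dataclass(frozen=True)
class SeedSite:
    """A located seed-match site (1-based inclusive coordinates, full window)."""

    utr_id: str
    start: int
    end: int
    site_type: str
    matched_mirna: str
    target_subsequence: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start + 1 != len(self.target_subsequence):
            raise ValueError("site coordinates do not match the target subsequence length")


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    try:
        return "".join(_DNA_COMPLEMENT[b] for b in reversed(dna.upper()))
    except KeyError as exc:
        raise ValueError(f"not a DNA base: {exc.args[0]!r}") from None


def seed_of(mirna: MatureMiRNA, from_pos: int = 2, to_pos: int = 8) -> str:
    """The miRNA seed region: 1-based inclusive positions [from_pos, to_pos] of the mature RNA."""
    if from_pos < 1 or from_pos > to_pos:
        raise ValueError(f"invalid seed window [{from_pos}, {to_pos}]")
    if len(mirna.sequence) < to_pos:
        raise ValueError(f"mature sequence of {mirna.name!r} shorter than position {to_pos}")
    return mirna.sequence[from_pos - 1 : to_pos]


def _core_match(mirna: MatureMiRNA) -> str:
    """DNA string a target must contain to pair with miRNA positions 2-7 (5'->3' in the target)."""
    seed = seed_of(mirna, 2, 7)
    return "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(seed))


def _m8_base(mirna: MatureMiRNA) -> str | None:
    if len(mirna.sequence) < 8:
        return None
    return _RNA_TO_DNA_COMPLEMENT[mirna.sequence[7]]


def site_window(mirna: MatureMiRNA, site_type: str) -> str:
    """The exact target window (DNA, 5'->3') that realises ``site_type`` for this miRNA."""
    core = _core_match(mirna)
    m8 = _m8_base(mirna)
    if site_type == "6mer":
        return core
    if site_type == "7mer-A1":
        return core + "A"
    if m8 is None:
        raise ValueError(f"{mirna.name!r} has no position 8; cannot build {site_type} window")
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "8mer":
        return m8 + core + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def _validate_utr(utr: str) -> str:
    utr = utr.upper()
    bad = set(utr) - set("ACGTN")
    if bad:
        raise ValueError(f"UTR must be DNA over ACGTN, found {sorted(bad)}")
    return utr


def find_seed_sites(utr: str, mirna: MatureMiRNA, utr_id: str = "utr") -> list[SeedSite]:
    """Locate every seed-match site of ``mirna`` in a 3'-UTR.

    Each position whose 6-nt window complements miRNA positions 2-7 is
    reported once, upgraded to the best site class it supports; the reported
    interval covers the full matched window.  Sites are sorted by start.
    """
    utr = _validate_utr(utr)
    core = _core_match(mirna)
    m8 = _m8_base(mirna)
    sites: list[SeedSite] = []
    pos = utr.find(core)
    while pos != -1:
        i0, i1 = pos, pos + len(core) - 1  # 0-based core interval
        has_m8 = m8 is not None and i0 >= 1 and utr[i0 - 1] == m8
        has_a1 = i1 + 1 < len(utr) and utr[i1 + 1] == "A"
        if has_m8 and has_a1:
            stype, w0, w1 = "8mer", i0 - 1, i1 + 1
        elif has_m8:
            stype, w0, w1 = "7mer-m8", i0 - 1, i1
        elif has_a1:
            stype, w0, w1 = "7mer-A1", i0, i1 + 1
        else:
            stype, w0, w1 = "6mer", i0, i1
        sites.append(
            SeedSite(
                utr_id=utr_id,
                start=w0 + 1,
                end=w1 + 1,
                site_type=stype,
                matched_mirna=mirna.name,
                target_subsequence=utr[w0 : w1 + 1],
            )
        )
        pos = utr.find(core, pos + 1)
    return sorted(sites, key=lambda s: s.start)


def design_mutant_utr(utr: str, site: SeedSite, mirna: MatureMiRNA, n_mut: int = 3) -> str:
    """Disrupt a seed site with exactly ``n_mut`` transversions inside its pairing window.

    Mutations are placed within the 6-nt seed-pairing core of ``site``.
    Candidate mutants are tried deterministically (position combinations,
    then alternative transversions) until a rescan shows no site overlapping
    the original interval and no new site anywhere else; raises RuntimeError
    if every candidate fails.  The returned sequence has the same length as
    the input and Hamming distance exactly ``n_mut`` from it.
    """
    utr = _validate_utr(utr)
    if not (1 <= site.start <= site.end <= len(utr)):
        raise ValueError("site lies outside the UTR")
    if not 1 <= n_mut <= 6:
        raise ValueError("n_mut must be between 1 and 6")

    # 0-based interval of the 6-nt core within the full matched window
    core0 = site.start - 1 + (1 if site.site_type in ("7mer-m8", "8mer") else 0)
    core_positions = list(range(core0, core0 + 6))
    original = find_seed_sites(utr, mirna)
    kept = [(s.start, s.end, s.site_type) for s in original if not (s.start <= site.end and s.end >= site.start)]

    for positions in combinations(core_positions, n_mut):
        for choice in product((0, 1), repeat=n_mut):
            mutant = list(utr)
            for p, c in zip(positions, choice):
                mutant[p] = _TRANSVERSIONS[utr[p]][c]
            candidate = "".join(mutant)
            rescanned = find_seed_sites(candidate, mirna)
            if any(s.start <= site.end and s.end >= site.start for s in rescanned):
                continue
            if [(s.start, s.end, s.site_type) for s in rescanned] == kept:
                return candidate
    raise RuntimeError("could not disrupt the site without creating a new one")


def site_conservation(aligned_site_blocks: Mapping[str, str], mirna: MatureMiRNA) -> float:
    """Fraction of species whose aligned block contains an intact seed match.

    Blocks must be equal length (an alignment slice around the site);
    gap characters '-' are removed before searching for the exact 6-nt
    seed complement.
    """
    blocks = dict(aligned_site_blocks)
    if not blocks:
        raise ValueError("no alignment blocks given")
    lengths = {len(b) for b in blocks.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment blocks have ragged lengths: {sorted(lengths)}")
    core = _core_match(mirna)
    hits = sum(1 for b in blocks.values() if core in _validate_utr(b.replace("-", "")))
    return hits / len(blocks)
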