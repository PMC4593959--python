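"""Protein–spectrum-match metrics, PTM localization and decoy FDR.

Identification uses matching b/y ions only.  A product ion observed at
several charge states counts once everywhere (charge-collapsed on its
(series, index) backbone key).  The ranking score is the matching b/y ion
count with a bond-coverage tie-break; it is a documented stand-in ranking
statistic, not the published P Score of the original search engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentIon, IonDatabase, Proteoform
from .matching import CentroidSpectrum, EnvelopeMatch

__all__ = [
    "PrSM",
    "PtmLocalization",
    "sequence_coverage",
    "bond_coverage",
    "pmp",
    "interpreted_fractions",
    "ptm_score",
    "make_decoy",
    "fdr_filter",
    "group_proteoforms",
    "score_prsm",
]


def sequence_coverage(max_b_index: int, max_y_index: int, length: int) -> float:
    """Percent of the sequence spanned by the largest matching b and y ions.

    With largest matching ions b_j and y_k on an n-residue protein the
    coverage is 100 if j + k >= n, else (j + k) * 100 / n.  Pass 0 for an
    absent series.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    j, k = max_b_index, max_y_index
    if not (0 <= j <= length and 0 <= k <= length):
        raise ValueError("ion indices outside 0..n")
    if j + k >= length:
        return 100.0
    return (j + k) * 100.0 / length


def bond_coverage(matching_ions: list[FragmentIon], length: int) -> float:
    """Percent of peptide bonds with at least one matching b or y ion.

    Bond i sits between residues i and i+1 (1-based, i in 1..n-1); b_i and
    y_{n-i} both witness it.
    """
    if length < 2:
        raise ValueError("need at least 2 residues")
    bonds = set()
    for ion in matching_ions:
        if ion.series == "b":
            bonds.add(ion.index)
        elif ion.series == "y":
            bonds.add(length - ion.index)
    bonds = {b for b in bonds if 1 <= b <= length - 1}
    return len(bonds) * 100.0 / (length - 1)


def _backbone_keys(ions: list[FragmentIon], series=("b", "y")) -> set:
    return {i.backbone_key for i in ions if i.series in series and not i.neutral_loss}


def pmp(matching_ions: list[FragmentIon], theoretical_count: int) -> float:
    """Percentage of matching product ions (charge-collapsed b/y backbone).

    ``theoretical_count`` is the number of distinct theoretical b/y
    (series, index) pairs for the proteoform; neutral-loss variants are
    excluded from both sides.
    """
    if theoretical_count <= 0:
        raise ValueError("theoretical ion count must be > 0")
    return len(_backbone_keys(matching_ions)) * 100.0 / theoretical_count


def interpreted_fractions(
    matches: list[EnvelopeMatch], spectrum: CentroidSpectrum
) -> tuple[float, float]:
    """(percent of peaks, percent of abundance) linked by any fished ion."""
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    linked: set[int] = set()
    for m in matches:
        linked.update(int(j) for j in m.links[m.linked])
    idx = sorted(linked)
    peak_pct = len(idx) * 100.0 / len(spectrum)
    abun_pct = float(spectrum.abundance[idx].sum()) * 100.0 / spectrum.total_abundance()
    return peak_pct, abun_pct


@dataclass
class PrSM:
    """One proteoform matched to one tandem spectrum, with its metrics."""

    proteoform: Proteoform
    spectrum_id: str
    matching_ions: list[FragmentIon]
    fished_ions: list[FragmentIon]
    sequence_coverage: float
    bond_coverage: float
    pmp: float
    interpreted_peak_pct: float
    interpreted_abundance_pct: float
    is_decoy: bool = False

    def __post_init__(self) -> None:
        fished = {id(i) for i in self.fished_ions}
        if not {id(i) for i in self.matching_ions} <= fished:
            raise ValueError("matching ions must be a subset of fished ions")

    @property
    def rank_score(self) -> int:
        """Matching b/y ion count (charge-collapsed); stand-in ranking
        statistic, not the published P Score."""
        return len(_backbone_keys(self.matching_ions))

    @property
    def sort_key(self) -> tuple:
        return (self.rank_score, self.bond_coverage)


@dataclass(frozen=True)
class PtmLocalization:
    site: int
    name: str
    score: int


def ptm_score(
    matching_ions: list[FragmentIon],
    length: int,
    site: int,
    candidate_sites: list[int],
    name: str = "",
) -> PtmLocalization:
    """Count charge-collapsed matching b/y ions that pin a PTM to ``site``.

    An ion discriminates the localization when its residue span contains the
    annotated site but excludes at least one alternative candidate (or there
    is no alternative, in which case containing the site suffices).
    """
    if site not in candidate_sites:
        raise ValueError("site must be among candidate_sites")
    alternatives = [s for s in candidate_sites if s != site]
    seen: set[tuple[str, int]] = set()
    for ion in matching_ions:
        if ion.series not in ("b", "y") or ion.backbone_key in seen:
            continue
        if ion.series == "b":
            span = range(1, ion.index + 1)
        else:
            span = range(length - ion.index + 1, length + 1)
        if site not in span:
            continue
        if alternatives and all(a in span for a in alternatives):
            continue
        seen.add(ion.backbone_key)
    return PtmLocalization(site=site, name=name, score=len(seen))


def make_decoy(
    protein_id: str, sequence: str, mode: str = "random", seed: int = 0
) -> tuple[str, str]:
    """Reverse or seeded-shuffle decoy; accession prefixed ``DECOY_``."""
    if not sequence:
        raise ValueError("empty sequence")
    if mode == "reverse":
        decoy = sequence[::-1]
    elif mode == "random":
        chars = list(sequence)
        random.Random(seed).shuffle(chars)
        decoy = "".join(chars)
    else:
        raise ValueError(f"unknown decoy mode: {mode!r}")
    return f"DECOY_{protein_id}", decoy


def fdr_filter(
    targets: list[PrSM], decoys: list[PrSM], alpha: float
) -> tuple[list[PrSM], float | None]:
    """Accept targets above the loosest score cutoff controlling the FDR.

    The FDR estimate at cutoff c is (#decoys >= c) / (#targets >= c).  The
    loosest target-score cutoff whose estimate is strictly below ``alpha``
    is chosen (equality steps to the stricter cutoff); if no cutoff
    qualifies the accept set is empty.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not targets:
        return [], None
    t_scores = np.array(sorted((p.rank_score for p in targets), reverse=True))
    d_scores = np.array(sorted((p.rank_score for p in decoys), reverse=True))
    best_cut = None
    for c in sorted(set(t_scores)):  # ascending: loosest qualifying wins
        n_t = int((t_scores >= c).sum())
        n_d = int((d_scores >= c).sum())
        if n_d / n_t < alpha:
            best_cut = float(c)
            break
    if best_cut is None:
        return [], None
    return [p for p in targets if p.rank_score >= best_cut], best_cut


def group_proteoforms(prsms: list[PrSM]) -> list[PrSM]:
    """Collapse PrSMs to unique proteoforms.

    Grouping key is (sequence, PTM set); the PrSM with the most matching
    b/y ions is kept (ties: higher rank score then lower scan id).
    """
    groups: dict[tuple, PrSM] = {}
    for p in prsms:
        key = (p.proteoform.sequence, p.proteoform.ptm_string())
        cur = groups.get(key)
        if cur is None:
            groups[key] = p
            continue
        p_key = (len(_backbone_keys(p.matching_ions)), p.rank_score)
        c_key = (len(_backbone_keys(cur.matching_ions)), cur.rank_score)
        if p_key > c_key or (p_key == c_key and p.spectrum_id < cur.spectrum_id):
            groups[key] = p
    return list(groups.values())


def score_prsm(
    proteoform: Proteoform,
    db: IonDatabase,
    matches: list[EnvelopeMatch],
    spectrum: CentroidSpectrum,
    is_decoy: bool = False,
) -> PrSM:
    """Assemble a PrSM from classified matches of one proteoform."""
    matching = [m.ion for m in matches if m.verdict == "matching"]
    fished = [m.ion for m in matches]
    n = len(proteoform.sequence)
    by_matching = [i for i in matching if i.series in ("b", "y") and not i.neutral_loss]
    max_b = max((i.index for i in by_matching if i.series == "b"), default=0)
    max_y = max((i.index for i in by_matching if i.series == "y"), default=0)
    peak_pct, abun_pct = interpreted_fractions(matches, spectrum)
    theo_by = db.backbone_count(("b", "y"))
    return PrSM(
        proteoform=proteoform,
        spectrum_id=spectrum.scan_id,
        matching_ions=matching,
        fished_ions=fished,
        sequence_coverage=sequence_coverage(max_b, max_y, n),
        bond_coverage=bond_coverage(by_matching, n) if n >= 2 else 0.0,
        pmp=pmp(matching, theo_by) if theo_by else 0.0,
        interpreted_peak_pct=peak_pct,
        interpreted_abundance_pct=abun_pct,
        is_decoy=is_decoy,
    )
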