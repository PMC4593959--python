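"""Proteoform expansion and theoretical product-ion generation.

A proteoform is a protein sequence plus a concrete set of PTMs.  From each
proteoform the a/b/y backbone ion series and their neutral-loss variants are
generated with exact isotopic envelopes, indexed by the m/z of each ion's
most-abundant (100%) isotopic peak for range lookup during spectrum matching.

Neutral-loss eligibility follows the residue chemistry of HCD product ions:
water losses require at least one of D/E/S/T in the fragment, ammonia losses
at least one of K/N/Q/R; the combined NH3+H2O loss requires both classes.
"""

from __future__ import annotations

import bisect
import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .isotopes import (
    ElementalComposition,
    TheoreticalEnvelope,
    aggregate_distribution,
    charge_mz,
    parse_formula,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RESIDUE_COMPOSITIONS",
    "NEUTRAL_LOSSES",
    "Proteoform",
    "FragmentIon",
    "IonDatabase",
    "expand_proteoforms",
    "generate_fragments",
    "complementary_mass_check",
    "parse_label",
]

# Elemental compositions of the 20 standard amino-acid residues (in-chain,
# i.e. minus one water relative to the free amino acid).
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    aa: parse_formula(f)
    for aa, f in {
        "G": "C2H3NO",
        "A": "C3H5NO",
        "S": "C3H5NO2",
        "P": "C5H7NO",
        "V": "C5H9NO",
        "T": "C4H7NO2",
        "C": "C3H5NOS",
        "L": "C6H11NO",
        "I": "C6H11NO",
        "N": "C4H6N2O2",
        "D": "C4H5NO3",
        "Q": "C5H8N2O2",
        "K": "C6H12N2O",
        "E": "C5H7NO3",
        "M": "C5H9NOS",
        "H": "C6H7N3O",
        "F": "C9H9NO",
        "R": "C6H12N4O",
        "Y": "C9H9NO2",
        "W": "C11H10N2O",
    }.items()
}

WATER = parse_formula("H2O")
AMMONIA = parse_formula("NH3")
CARBON_MONOXIDE = parse_formula("CO")

#: Canonical neutral-loss keys -> (loss composition, needs {D,E,S,T}, needs {K,N,Q,R})
NEUTRAL_LOSSES: dict[str, tuple[ElementalComposition, bool, bool]] = {
    "NH3": (AMMONIA, False, True),
    "H2O": (WATER, True, False),
    "NH3-H2O": (AMMONIA + WATER, True, True),
    "2NH3": (AMMONIA * 2, False, True),
    "2H2O": (WATER * 2, True, False),
}

_WATER_LOSS_RESIDUES = frozenset("DEST")
_AMMONIA_LOSS_RESIDUES = frozenset("KNQR")


@dataclass(frozen=True)
class Proteoform:
    """A protein sequence plus a concrete PTM set.

    ``ptms`` holds (site, name, delta_composition) with 1-based sites, at
    most one PTM per site.
    """

    protein_id: str
    sequence: str
    ptms: tuple[tuple[int, str, ElementalComposition], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(RESIDUE_COMPOSITIONS)
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
        sites = [s for s, _, _ in self.ptms]
        if len(sites) != len(set(sites)):
            raise ValueError("duplicate PTM site")
        for s in sites:
            if not 1 <= s <= len(self.sequence):
                raise ValueError(f"PTM site {s} outside 1..{len(self.sequence)}")

    def neutral_composition(self) -> ElementalComposition:
        comp = WATER
        for aa in self.sequence:
            comp = comp + RESIDUE_COMPOSITIONS[aa]
        for _, _, delta in self.ptms:
            comp = comp + delta
        return comp

    def ptm_string(self) -> str:
        """Canonical PTM summary like ``"K37ac,K105ac"`` (empty if none)."""
        return ",".join(
            f"{self.sequence[s - 1]}{s}{name}" for s, name, _ in sorted(self.ptms)
        )


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical product ion at one charge, with its envelope."""

    series: str
    index: int
    neutral_loss: str  # "" or a NEUTRAL_LOSSES key
    charge: int
    composition: ElementalComposition
    envelope: TheoreticalEnvelope

    @property
    def label(self) -> str:
        nl = f"-{self.neutral_loss}" if self.neutral_loss else ""
        return f"{self.series}{self.index}{nl}-{self.charge}+"

    @property
    def base_mz(self) -> float:
        return self.envelope.base_mz

    @property
    def backbone_key(self) -> tuple[str, int]:
        """(series, index) identity ignoring charge and neutral loss."""
        return (self.series, self.index)


_LABEL_RE = re.compile(
    r"^([aby])(\d+)(?:-(NH3-H2O|2NH3|2H2O|NH3|H2O))?-(\d+)\+$"
)


def parse_label(label: str) -> tuple[str, int, str, int]:
    """Parse an ion label like ``"y72-7+"`` or ``"b111-2H2O-11+"``.

    Returns (series, index, neutral_loss, charge); inverse of
    :attr:`FragmentIon.label`.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed ion label: {label!r}")
    series, index, nl, charge = m.groups()
    return series, int(index), nl or "", int(charge)


class IonDatabase:
    """Fragment ions of one proteoform, indexed by base-peak m/z."""

    def __init__(self, proteoform: Proteoform, ions: list[FragmentIon]):
        self.proteoform = proteoform
        self.ions = sorted(ions, key=lambda i: i.base_mz)
        self._base_mzs = [i.base_mz for i in self.ions]

    def __len__(self) -> int:
        return len(self.ions)

    def __iter__(self):
        return iter(self.ions)

    def query(self, lo: float, hi: float) -> list[FragmentIon]:
        """Ions whose 100% isotopic peak m/z lies in [lo, hi]."""
        i = bisect.bisect_left(self._base_mzs, lo)
        j = bisect.bisect_right(self._base_mzs, hi)
        return self.ions[i:j]

    def backbone_count(self, series: tuple[str, ...] = ("b", "y")) -> int:
        """Distinct (series, index) pairs, ignoring charge and NL."""
        return len({i.backbone_key for i in self.ions if i.series in series})


def expand_proteoforms(
    protein_id: str,
    sequence: str,
    annotations: list[tuple[int, str, ElementalComposition]],
    k_max: int = 10,
) -> list[Proteoform]:
    """All 2^k on/off combinations of k annotated PTM sites.

    The unmodified form comes first, then combinations by increasing size.
    Raises if more than ``k_max`` sites are annotated (2^k blow-up guard) or
    if annotations are invalid for the sequence.
    """
    sites = [s for s, _, _ in annotations]
    if len(sites) != len(set(sites)):
        raise ValueError("duplicate PTM site in annotations")
    if len(annotations) > k_max:
        raise ValueError(
            f"{len(annotations)} annotated sites exceeds k_max={k_max}"
        )
    anns = sorted(annotations)
    forms = []
    for r in range(len(anns) + 1):
        for subset in itertools.combinations(anns, r):
            forms.append(Proteoform(protein_id, sequence, tuple(subset)))
    return forms


def _fragment_compositions(
    pf: Proteoform,
) -> tuple[list[ElementalComposition], list[ElementalComposition]]:
    """Neutral compositions of b_1..b_{n-1} and y_1..y_{n-1}."""
    n = len(pf.sequence)
    deltas: dict[int, ElementalComposition] = {s: d for s, _, d in pf.ptms}
    b: list[ElementalComposition] = []
    acc = ElementalComposition()
    for j in range(1, n):
        acc = acc + RESIDUE_COMPOSITIONS[pf.sequence[j - 1]]
        if j in deltas:
            acc = acc + deltas[j]
        b.append(acc)
    y: list[ElementalComposition] = []
    acc = WATER
    for k in range(1, n):
        pos = n - k + 1
        acc = acc + RESIDUE_COMPOSITIONS[pf.sequence[pos - 1]]
        if pos in deltas:
            acc = acc + deltas[pos]
        y.append(acc)
    return b, y


def _eligible_losses(residues: str) -> list[str]:
    has_water = bool(_WATER_LOSS_RESIDUES & set(residues))
    has_ammonia = bool(_AMMONIA_LOSS_RESIDUES & set(residues))
    out = []
    for key, (_, need_w, need_a) in NEUTRAL_LOSSES.items():
        if (not need_w or has_water) and (not need_a or has_ammonia):
            out.append(key)
    return out


def generate_fragments(
    pf: Proteoform,
    series_set: set[str] = frozenset({"b", "y"}),
    nl_set: set[str] = frozenset(),
    max_charge: int = 1,
    mz_window: tuple[float, float] = (0.0, float("inf")),
    ipaco: float = 20.0,
) -> IonDatabase:
    """Theoretical a/b/y (+NL) ions of ``pf`` with exact envelopes.

    Every eligible series/loss variant is emitted at charges 1..max_charge
    whose 100%-peak m/z falls inside ``mz_window``.  The isotopic aggregate
    distribution is computed once per neutral composition and shared across
    charge states.
    """
    if not series_set <= {"a", "b", "y"}:
        raise ValueError(f"unknown series in {series_set}")
    if not nl_set <= set(NEUTRAL_LOSSES):
        raise ValueError(f"unknown neutral losses in {nl_set}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(pf.sequence)
    b_comps, y_comps = _fragment_compositions(pf)
    lo, hi = mz_window
    ions: list[FragmentIon] = []
    for idx in range(1, n):
        for series in sorted(series_set):
            if series in ("a", "b"):
                comp = b_comps[idx - 1]
                residues = pf.sequence[:idx]
                if series == "a":
                    try:
                        comp = comp - CARBON_MONOXIDE
                    except ValueError:
                        logger.warning("skipping %s%d: CO subtraction", series, idx)
                        continue
            else:
                comp = y_comps[idx - 1]
                residues = pf.sequence[n - idx:]
            variants = [("", comp)]
            for nl_key in _eligible_losses(residues):
                if nl_key not in nl_set:
                    continue
                loss = NEUTRAL_LOSSES[nl_key][0]
                try:
                    variants.append((nl_key, comp - loss))
                except ValueError:
                    logger.warning(
                        "skipping %s%d-%s: loss exceeds composition",
                        series, idx, nl_key,
                    )
            for nl_key, vcomp in variants:
                prob, mass = aggregate_distribution(vcomp)
                rel = prob / prob.max() * 100.0
                keep = np.nonzero(rel >= ipaco)[0]
                mono = vcomp.monoisotopic_mass()
                base_mass = mass[int(np.argmax(rel))]
                for charge in range(1, max_charge + 1):
                    if not lo <= charge_mz(base_mass, charge) <= hi:
                        continue
                    env = TheoreticalEnvelope(
                        mz=np.array(
                            [charge_mz(m, charge) for m in mass[keep]]
                        ),
                        rel_abundance=rel[keep],
                        charge=charge,
                        monoisotopic_mz=charge_mz(mono, charge),
                        base_index=int(np.argmax(rel[keep])),
                    )
                    ions.append(
                        FragmentIon(
                            series=series,
                            index=idx,
                            neutral_loss=nl_key,
                            charge=charge,
                            composition=vcomp,
                            envelope=env,
                        )
                    )
    return IonDatabase(pf, ions)


def complementary_mass_check(pf: Proteoform, tol: float = 1e-6) -> bool:
    """Verify b_j + y_{n-j} neutral masses equal the proteoform mass.

    Mass-conservation self-test of the fragment arithmetic; returns False
    (with a log record of the first offending cleavage) instead of raising.
    """
    n = len(pf.sequence)
    if n < 2:
        return True
    b_comps, y_comps = _fragment_compositions(pf)
    total = pf.neutral_composition().monoisotopic_mass()
    for j in range(1, n):
        got = (
            b_comps[j - 1].monoisotopic_mass()
            + y_comps[n - j - 1].monoisotopic_mass()
        )
        if abs(got - total) > tol:
            logger.error(
                "complementarity failed at j=%d: %.8f vs %.8f", j, got, total
            )
            return False
    return True
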