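"""Elemental compositions and exact isotopic envelopes.

Theoretical envelopes are computed directly from the elemental composition of
an ion by convolving the natural isotope distributions of its atoms, rather
than from an average-residue (Averagine) model.  Isotopologues are aggregated
by nucleon-number offset from the monoisotopic species (A+0, A+1, ...), which
matches the one-centroid-per-isotopic-peak structure of centroided
high-resolution spectra; the centroid mass of each aggregate is the
abundance-weighted mean of its isotopologue masses.

The isotope masses and abundances are embedded as a fixed, versioned table so
that envelope values are bit-stable across installations.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ISOTOPE_TABLE",
    "PROTON_MASS",
    "ElementalComposition",
    "TheoreticalEnvelope",
    "parse_formula",
    "aggregate_envelope",
    "charge_mz",
    "enumerate_isotopologues",
]

#: Mass of a proton in Da (positive-mode ESI protonation convention; the
#: electron mass is neglected, well inside typical 15 ppm tolerances).
PROTON_MASS = 1.007276466

#: Relative probability below which intermediate convolution states are
#: dropped.  Far below any reportable abundance cutoff; small enough that
#: even far-tail aggregate centroid masses stay exact to ~1e-10 Da.
_PRUNE = 1e-14


@dataclass(frozen=True)
class IsotopeTable:
    """Fixed table of isotope masses (Da) and natural abundances (fractions).

    ``isotopes`` maps element symbol -> list of (mass, abundance) with masses
    strictly increasing; abundances per element sum to 1 within 1e-6.
    """

    isotopes: dict[str, tuple[tuple[float, float], ...]]
    version: str

    def __post_init__(self) -> None:
        for el, iso in self.isotopes.items():
            total = sum(a for _, a in iso)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances for {el} sum to {total}")
            masses = [m for m, _ in iso]
            if masses != sorted(masses) or len(set(masses)) != len(masses):
                raise ValueError(f"masses for {el} not strictly increasing")


# IUPAC/CIAAW isotopic compositions as tabulated by NIST (2013 compilation);
# identical to the values shipped by common proteomics toolkits.
ISOTOPE_TABLE = IsotopeTable(
    isotopes={
        "H": ((1.00782503207, 0.999885), (2.0141017778, 0.000115)),
        "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
        "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
        "O": (
            (15.99491461956, 0.99757),
            (16.99913170, 0.00038),
            (17.9991610, 0.00205),
        ),
        "P": ((30.97376163, 1.0),),
        "S": (
            (31.97207100, 0.9499),
            (32.97145876, 0.0075),
            (33.96786690, 0.0425),
            (35.96708076, 0.0001),
        ),
    },
    version="NIST-2013",
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Map element symbol -> non-negative atom count.

    Immutable; supports ``+``, ``-`` (subtraction raises if any count would go
    negative) and integer ``*``.  Zero counts are dropped on construction.
    """

    counts: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def from_dict(counts: dict[str, int]) -> "ElementalComposition":
        for el, n in counts.items():
            if el not in ISOTOPE_TABLE.isotopes:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return ElementalComposition(items)

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = self.to_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition.from_dict(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = self.to_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({merged[el]})"
                )
        return ElementalComposition.from_dict(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalComposition.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def total_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def monoisotopic_mass(self) -> float:
        """Mass in Da using the lightest isotope of every element."""
        return sum(ISOTOPE_TABLE.isotopes[el][0][0] * n for el, n in self.counts)

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        d = self.to_dict()
        parts = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if el in d:
                n = d[el]
                parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.formula()


def parse_formula(text: str) -> ElementalComposition:
    """Parse a chemical formula like ``"C34H53N9O15"``.

    Zero counts are dropped; repeated symbols accumulate.  Raises
    ``ValueError`` on malformed input or unknown element symbols.
    """
    if not text:
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula at {text[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPE_TABLE.isotopes:
            raise ValueError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"malformed formula at {text[pos:]!r}")
    return ElementalComposition.from_dict(counts)


def charge_mz(neutral_mass: float, charge: int) -> float:
    """m/z of an [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class TheoreticalEnvelope:
    """Aggregated isotopic envelope of one ion at one charge.

    ``mz`` ascending; ``rel_abundance`` in percent with the base peak exactly
    100.  ``base_index`` points at the 100% peak, ``monoisotopic_mz`` at the
    A+0 species (kept even if the A+0 aggregate fell below the abundance
    cutoff).
    """

    mz: np.ndarray
    rel_abundance: np.ndarray
    charge: int
    monoisotopic_mz: float
    base_index: int

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def base_mz(self) -> float:
        return float(self.mz[self.base_index])


def _single_atom_arrays(el: str) -> tuple[np.ndarray, np.ndarray]:
    """(probability, probability-weighted mass) arrays over nucleon offsets."""
    iso = ISOTOPE_TABLE.isotopes[el]
    base_nucleons = round(iso[0][0])
    size = round(iso[-1][0]) - base_nucleons + 1
    p = np.zeros(size)
    pm = np.zeros(size)
    for mass, abun in iso:
        k = round(mass) - base_nucleons
        p[k] += abun
        pm[k] += abun * mass
    return p, pm


def _convolve(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    p = np.convolve(a[0], b[0])
    pm = np.convolve(a[1], b[0]) + np.convolve(a[0], b[1])
    # prune negligible trailing states to bound cost for protein-sized ions
    keep = np.nonzero(p > _PRUNE * p.max())[0]
    hi = keep[-1] + 1
    return p[:hi], pm[:hi]


def _element_power(el: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n atoms of one element, by repeated squaring."""
    result: tuple[np.ndarray, np.ndarray] | None = None
    square = _single_atom_arrays(el)
    while n:
        if n & 1:
            result = square if result is None else _convolve(result, square)
        n >>= 1
        if n:
            square = _convolve(square, square)
    assert result is not None
    return result


def aggregate_distribution(
    comp: ElementalComposition,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and centroid masses of the A+0, A+1, ... aggregates.

    Returns ``(prob, mass)`` arrays indexed by nucleon offset; ``prob`` sums
    to ~1, ``mass[k]`` is the abundance-weighted mean mass of offset ``k``.
    Charge-independent, so callers can reuse it across charge states.
    """
    if not comp:
        raise ValueError("empty composition")
    acc: tuple[np.ndarray, np.ndarray] | None = None
    for el, n in comp.counts:
        dist = _element_power(el, n)
        acc = dist if acc is None else _convolve(acc, dist)
    assert acc is not None
    p, pm = acc
    with np.errstate(invalid="ignore", divide="ignore"):
        mass = np.where(p > 0, pm / np.where(p > 0, p, 1.0), 0.0)
    return p, mass


def aggregate_envelope(
    comp: ElementalComposition, charge: int, ipaco: float = 0.0
) -> TheoreticalEnvelope:
    """Exact theoretical envelope of ``comp`` at ``charge``.

    ``ipaco`` is the isotopic peak abundance cutoff in percent: aggregates
    whose relative abundance falls below it are removed after normalizing the
    most abundant aggregate to 100.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if not 0 <= ipaco < 100:
        raise ValueError("ipaco must be in [0, 100)")
    prob, mass = aggregate_distribution(comp)
    rel = prob / prob.max() * 100.0
    mz = np.array([charge_mz(m, charge) for m in mass])
    mono_mz = charge_mz(comp.monoisotopic_mass(), charge)
    keep = np.nonzero((rel >= ipaco) & (prob > 0))[0]
    rel = rel[keep]
    mz = mz[keep]
    base = int(np.argmax(rel))
    return TheoreticalEnvelope(
        mz=mz,
        rel_abundance=rel,
        charge=charge,
        monoisotopic_mz=mono_mz,
        base_index=base,
    )


def enumerate_isotopologues(
    comp: ElementalComposition,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force isotopologue enumeration, aggregated by nucleon offset.

    Exhaustive multinomial enumeration over every element's isotope
    assignment; intended as an independent oracle for small compositions
    (cost is exponential in element diversity, fine up to ~60 atoms).
    Returns the same ``(prob, mass)`` arrays as :func:`aggregate_distribution`.
    """
    if not comp:
        raise ValueError("empty composition")
    # states: offset -> [total probability, probability-weighted mass sum]
    states: dict[int, list[float]] = {0: [1.0, 0.0]}
    for el, n in comp.counts:
        iso = ISOTOPE_TABLE.isotopes[el]
        offsets = [round(m) - round(iso[0][0]) for m, _ in iso]
        element_states: dict[int, list[float]] = {}
        for combo in _compositions(n, len(iso)):
            logp = math.lgamma(n + 1)
            mass = 0.0
            off = 0
            ok = True
            for k, (m_iso, a_iso), d_off in zip(combo, iso, offsets):
                logp -= math.lgamma(k + 1)
                if k:
                    if a_iso == 0.0:
                        ok = False
                        break
                    logp += k * math.log(a_iso)
                    mass += k * m_iso
                    off += k * d_off
            if not ok:
                continue
            p = math.exp(logp)
            entry = element_states.setdefault(off, [0.0, 0.0])
            entry[0] += p
            entry[1] += p * mass
        new: dict[int, list[float]] = {}
        for off_a, (p_a, pm_a) in states.items():
            for off_b, (p_b, pm_b) in element_states.items():
                entry = new.setdefault(off_a + off_b, [0.0, 0.0])
                entry[0] += p_a * p_b
                entry[1] += pm_a * p_b + p_a * pm_b
        states = new
    max_off = max(states)
    prob = np.zeros(max_off + 1)
    mass = np.zeros(max_off + 1)
    for off, (p, pm) in states.items():
        prob[off] = p
        mass[off] = pm / p if p > 0 else 0.0
    return prob, mass


def _compositions(n: int, k: int):
    """All ways to place n identical atoms into k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest
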