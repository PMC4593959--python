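"""Envelope fingerprinting: aligning theoretical envelopes to centroid peaks.

An ion is "fished" from a spectrum when its most-abundant (100%) theoretical
isotopic peak finds an experimental peak within the m/z tolerance (IPMD, in
ppm).  Every other theoretical peak surviving the abundance cutoff (IPACO) is
then linked to its nearest experimental peak within tolerance.  A reference
isotopic peak — ideally one not shared with any other ion — maps the ion's
absolute experimental abundances onto the theoretical relative scale; the
per-peak abundance deviation (IPAD, in percentage points) is measured on that
scale.  An ion whose envelope is fully observed within all three tolerances
is a matching product ion; anything else is non-matching.

An experimental peak claimed by two or more ions is an overlapping isotopic
peak (OIP); the groups assembled here are the input to the abundance
partitioning in :mod:`oiecare.resolve`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentIon

__all__ = [
    "SearchParams",
    "CentroidSpectrum",
    "EnvelopeMatch",
    "OIPGroup",
    "ipmd",
    "ipad",
    "round_half_away",
    "fish_ion",
    "select_reference",
    "assign_references",
    "classify",
    "find_oips",
]

UNLINKED = -1


@dataclass(frozen=True)
class SearchParams:
    """IPACO/IPMD/IPAD tolerance triplet for one search scope.

    ipaco: abundance cutoff in percent — theoretical peaks below it are
    dropped before matching.  ipmd_tol: m/z tolerance in ppm.  ipad_tol:
    abundance tolerance in percentage points.
    """

    ipaco: float = 20.0
    ipmd_tol: float = 15.0
    ipad_tol: float = 50.0
    scope: str = "product"

    def __post_init__(self) -> None:
        if not 0 <= self.ipaco < 100:
            raise ValueError("ipaco must be in [0, 100)")
        if self.ipmd_tol <= 0:
            raise ValueError("ipmd_tol must be > 0")
        if self.ipad_tol < 0:
            raise ValueError("ipad_tol must be >= 0")
        if self.scope not in ("precursor", "product"):
            raise ValueError("scope must be 'precursor' or 'product'")


@dataclass
class CentroidSpectrum:
    """Centroided peak list with precursor metadata.

    m/z strictly increasing, abundances positive (absolute counts).
    """

    mz: np.ndarray
    abundance: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    scan_id: str = ""
    retention_time: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.shape != self.abundance.shape:
            raise ValueError("mz and abundance length mismatch")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z must be strictly increasing")
        if np.any(self.abundance <= 0):
            raise ValueError("abundances must be positive")

    def __len__(self) -> int:
        return len(self.mz)

    def total_abundance(self) -> float:
        return float(self.abundance.sum())


def ipmd(theo_mz: float, exp_mz: float) -> float:
    """Signed isotopic peak m/z deviation in ppm."""
    if theo_mz <= 0:
        raise ValueError("theo_mz must be > 0")
    return 1e6 * (exp_mz - theo_mz) / theo_mz


def ipad(theo_rel: float, exp_rel: float) -> float:
    """Signed isotopic peak abundance deviation in percentage points."""
    return exp_rel - theo_rel


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(np.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class EnvelopeMatch:
    """Alignment of one ion's theoretical envelope to a spectrum.

    ``links[i]`` is the experimental-peak index linked to theoretical peak i
    (``UNLINKED`` if none within tolerance).  ``assigned_abundance[i]`` is
    the absolute abundance credited to this ion at peak i — the raw
    experimental abundance before OIP resolution, the partitioned share
    after.  Relative abundances and IPADs are normalized through the
    reference peak; the reference IPAD is 0 by construction.
    """

    ion: FragmentIon
    links: np.ndarray
    assigned_abundance: np.ndarray
    reference_index: int
    reference_degenerate: bool = False
    verdict: str = "unclassified"

    @property
    def theo_rel(self) -> np.ndarray:
        return self.ion.envelope.rel_abundance

    @property
    def linked(self) -> np.ndarray:
        return self.links != UNLINKED

    def reference_abundance(self) -> float:
        return float(self.assigned_abundance[self.reference_index])

    def reference_theo_rel(self) -> float:
        return float(self.theo_rel[self.reference_index])

    def exp_rel(self) -> np.ndarray:
        """Experimental relative abundances (percent), NaN where unlinked."""
        ea_r = self.reference_abundance()
        ta_r = self.reference_theo_rel()
        out = np.full(len(self.links), np.nan)
        m = self.linked
        out[m] = self.assigned_abundance[m] * ta_r / ea_r
        return out

    def ipads(self) -> np.ndarray:
        """Signed IPAD per theoretical peak (NaN where unlinked)."""
        return self.exp_rel() - self.theo_rel

    def ipmds(self, spectrum: CentroidSpectrum) -> np.ndarray:
        out = np.full(len(self.links), np.nan)
        m = self.linked
        theo = self.ion.envelope.mz[m]
        out[m] = 1e6 * (spectrum.mz[self.links[m]] - theo) / theo
        return out


@dataclass
class OIPGroup:
    """One experimental peak claimed by two or more ions.

    Claimants are (match, theoretical-peak-index) pairs that all link the
    same experimental peak; ``observed_abundance`` is that peak's raw
    abundance (EA_OIP).  Groups emitted by :func:`find_oips` always have
    >= 2 distinct claimant ions; a single-claimant group is legal (its
    partition reduces to the identity).
    """

    exp_index: int
    observed_abundance: float
    claimants: list[tuple[EnvelopeMatch, int]]

    def __post_init__(self) -> None:
        if not self.claimants:
            raise ValueError("an OIP group needs at least one claimant")


def fish_ion(
    ion: FragmentIon,
    spectrum: CentroidSpectrum,
    params: SearchParams,
    require_base: bool = True,
) -> EnvelopeMatch | None:
    """Link an ion's theoretical peaks to experimental peaks.

    Returns ``None`` unless the 100% theoretical peak is observed within the
    IPMD tolerance (``require_base=False`` drops the gate, for fixtures whose
    envelopes are printed excerpts without the base peak).  Each theoretical
    peak links to the nearest experimental peak within tolerance (tie: lower
    m/z).  The reference is provisionally the highest-abundance linked peak;
    call :func:`assign_references` after OIP detection to finalize it.
    """
    env = ion.envelope
    if len(spectrum) == 0:
        return None
    links = np.full(len(env.mz), UNLINKED, dtype=int)
    for i, tmz in enumerate(env.mz):
        j = int(np.searchsorted(spectrum.mz, tmz))
        best, best_err = UNLINKED, np.inf
        for cand in (j - 1, j):
            if 0 <= cand < len(spectrum):
                err = abs(spectrum.mz[cand] - tmz)
                if err < best_err:  # strict: tie keeps the lower-m/z peak
                    best, best_err = cand, err
        if best != UNLINKED and abs(ipmd(tmz, spectrum.mz[best])) <= params.ipmd_tol:
            links[i] = best
    if require_base and links[env.base_index] == UNLINKED:
        return None
    if not np.any(links != UNLINKED):
        return None
    assigned = np.zeros(len(links))
    m = links != UNLINKED
    assigned[m] = spectrum.abundance[links[m]]
    linked_idx = np.nonzero(m)[0]
    ref = int(linked_idx[np.argmax(env.rel_abundance[linked_idx])])
    return EnvelopeMatch(
        ion=ion, links=links, assigned_abundance=assigned, reference_index=ref
    )


def select_reference(match: EnvelopeMatch, oip_peaks: set[int]) -> int:
    """Choose the normalization (reference) isotopic peak.

    Among linked theoretical peaks whose experimental peak is not shared
    with another ion, the one with the highest theoretical abundance wins
    (tie: lower m/z).  If every linked peak is an OIP the match is flagged
    ``reference_degenerate`` and the peak with the smallest |IPAD| under a
    provisional base-peak normalization is used.
    """
    linked_idx = np.nonzero(match.linked)[0]
    if len(linked_idx) == 0:
        raise ValueError("match has no linked peaks")
    clean = [i for i in linked_idx if match.links[i] not in oip_peaks]
    if clean:
        match.reference_degenerate = False
        rel = match.theo_rel
        return int(max(clean, key=lambda i: (rel[i], -match.ion.envelope.mz[i])))
    # degenerate: normalize provisionally on the most abundant linked peak
    match.reference_degenerate = True
    prov = int(linked_idx[np.argmax(match.theo_rel[linked_idx])])
    ea_r = match.assigned_abundance[prov]
    ta_r = match.theo_rel[prov]
    ipads = np.abs(
        match.assigned_abundance[linked_idx] * ta_r / ea_r
        - match.theo_rel[linked_idx]
    )
    return int(linked_idx[np.argmin(ipads)])


def assign_references(
    matches: list[EnvelopeMatch], groups: list["OIPGroup"]
) -> None:
    """Finalize every match's reference peak given the detected OIPs."""
    oip_peaks = {g.exp_index for g in groups}
    for m in matches:
        m.reference_index = select_reference(m, oip_peaks)


def classify(
    match: EnvelopeMatch,
    params: SearchParams,
    spectrum: CentroidSpectrum,
) -> str:
    """Label a match ``"matching"`` or ``"non-matching"``.

    Matching requires an ideal envelope: every theoretical peak above IPACO
    observed, all |IPMD| within tolerance and all |IPAD| within tolerance
    (on the current — possibly OIP-resolved — abundances).  Tolerances are
    checked on unrounded values.
    """
    if not np.all(match.linked):
        match.verdict = "non-matching"
        return match.verdict
    if np.any(np.abs(match.ipmds(spectrum)) > params.ipmd_tol):
        match.verdict = "non-matching"
        return match.verdict
    if np.any(np.abs(match.ipads()) > params.ipad_tol):
        match.verdict = "non-matching"
        return match.verdict
    match.verdict = "matching"
    return match.verdict


def find_oips(
    matches: list[EnvelopeMatch], spectrum: CentroidSpectrum
) -> list[OIPGroup]:
    """Group experimental peaks claimed by two or more distinct ions."""
    claims: dict[int, list[tuple[EnvelopeMatch, int]]] = {}
    for m in matches:
        for theo_idx in np.nonzero(m.linked)[0]:
            claims.setdefault(int(m.links[theo_idx]), []).append((m, int(theo_idx)))
    groups = []
    for exp_idx in sorted(claims):
        claimants = claims[exp_idx]
        if len({id(m) for m, _ in claimants}) >= 2:
            groups.append(
                OIPGroup(
                    exp_index=exp_idx,
                    observed_abundance=float(spectrum.abundance[exp_idx]),
                    claimants=claimants,
                )
            )
    return groups
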