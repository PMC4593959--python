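"""Synthetic HCD-like spectra with ground truth.

Emulates centroided tandem spectra of intact-protein fragments: several
co-occurring b/y-ion envelopes whose isotopic peaks collide within a ppm
tolerance, multiplicative log-normal abundance noise, uniform m/z jitter
and uniform-random chemical-noise peaks.  Overlaps are engineered by
choosing real fragment ions whose exact envelope peaks already fall within
the merge tolerance of one another — theoretical envelopes are never edited,
so the simulated OIPs are honest.

The ground truth records each ion's per-peak contribution before merging,
which is what the abundance partitioning is later judged against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragments import FragmentIon, Proteoform
from .matching import CentroidSpectrum

__all__ = ["SimTruth", "simulate_spectrum", "write_truth_tsv", "write_mgf"]

#: Horse myoglobin, mature 153-residue chain (UniProt P68082 minus the
#: initiator Met) — the direct-infusion HCD reference protein.  Its
#: y10-1+/y20-2+/y72-7+ envelopes collide near m/z 1142.61 within ~4 ppm.
MYOGLOBIN_SEQUENCE = (
    "GLSDGEWQQVLNVWGKVEADIAGHGQEVLIRLFTGHPETLEKFDKFKHLKTEAEMKASEDLKKHGTVVLT"
    "ALGGILKKKGHHEAELKPLAQSHATKHKIPIKYLEFISDAIIHVLHSKHPGDFGADAQGAMTKALELFRN"
    "DIAAKYKELGFQG"
)


@dataclass
class SimTruth:
    """Ground truth for one simulated spectrum.

    ``peak_contributions[j]`` lists (ion label, noiseless contribution) for
    merged peak j; ``overlaps`` indexes the peaks with >= 2 contributors.
    ``ion_totals`` maps label -> true total (noiseless) envelope abundance.
    """

    ion_totals: dict[str, float]
    peak_contributions: list[list[tuple[str, float]]]
    overlaps: list[int]
    noise_cv: float
    ppm_jitter: float
    n_noise_peaks: int
    seed: int

    def contribution(self, peak_index: int, label: str) -> float:
        for lab, val in self.peak_contributions[peak_index]:
            if lab == label:
                return val
        raise KeyError(f"{label} does not contribute to peak {peak_index}")


def simulate_spectrum(
    pf: Proteoform,
    ions: list[FragmentIon],
    abundances: dict[str, float],
    noise_cv: float = 0.05,
    ppm_jitter: float = 3.0,
    n_noise_peaks: int = 0,
    merge_tol_ppm: float = 15.0,
    seed: int = 0,
    mz_range: tuple[float, float] = (200.0, 2000.0),
) -> tuple[CentroidSpectrum, SimTruth]:
    """Place ion envelopes into a centroided spectrum with known truth.

    Each ion's IPACO-truncated envelope is scaled so its reference (100%)
    peak carries ``abundances[label]`` counts.  Peaks from different ions
    closer than ``merge_tol_ppm`` are merged by abundance summation — these
    are the true OIPs.  Multiplicative log-normal noise (CV ``noise_cv``)
    and uniform m/z jitter within ``ppm_jitter`` are applied to the merged
    peaks; ``n_noise_peaks`` uniform-random chemical-noise peaks are added
    at 0.1–2% of the largest signal peak.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    for ion in ions:
        if abundances.get(ion.label, 0.0) <= 0:
            raise ValueError(f"abundance for {ion.label} must be > 0")
    rng = np.random.default_rng(seed)

    raw: list[tuple[float, float, str]] = []  # (mz, contribution, label)
    ion_totals: dict[str, float] = {}
    for ion in ions:
        env = ion.envelope
        scale = abundances[ion.label] / 100.0
        contrib = env.rel_abundance * scale
        ion_totals[ion.label] = float(contrib.sum())
        for mz, c in zip(env.mz, contrib):
            raw.append((float(mz), float(c), ion.label))
    raw.sort()

    merged: list[list] = []  # [mz_centroid, total, [(label, contrib), ...]]
    for mz, c, label in raw:
        if merged and (mz - merged[-1][0]) / merged[-1][0] * 1e6 <= merge_tol_ppm:
            cluster = merged[-1]
            total = cluster[1] + c
            cluster[0] = (cluster[0] * cluster[1] + mz * c) / total
            cluster[1] = total
            cluster[2].append((label, c))
        else:
            merged.append([mz, c, [(label, c)]])

    true_mz = np.array([m[0] for m in merged])
    true_ab = np.array([m[1] for m in merged])
    contributions = [m[2] for m in merged]
    overlaps = [j for j, c in enumerate(contributions) if len(c) >= 2]

    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noisy_ab = true_ab * rng.lognormal(-0.5 * sigma**2, sigma, len(true_ab))
    else:
        noisy_ab = true_ab.copy()
    jitter = rng.uniform(-ppm_jitter, ppm_jitter, len(true_mz)) * 1e-6
    noisy_mz = true_mz * (1.0 + jitter)

    if n_noise_peaks:
        floor = noisy_ab.max()
        noise_mz = rng.uniform(*mz_range, n_noise_peaks)
        noise_ab = rng.uniform(0.001, 0.02, n_noise_peaks) * floor
        noisy_mz = np.concatenate([noisy_mz, noise_mz])
        noisy_ab = np.concatenate([noisy_ab, noise_ab])
        contributions = contributions + [[] for _ in range(n_noise_peaks)]

    order = np.argsort(noisy_mz)
    spectrum = CentroidSpectrum(
        mz=noisy_mz[order],
        abundance=noisy_ab[order],
        scan_id=f"sim-{seed}",
    )
    truth = SimTruth(
        ion_totals=ion_totals,
        peak_contributions=[contributions[i] for i in order],
        overlaps=[int(np.nonzero(order == j)[0][0]) for j in overlaps],
        noise_cv=noise_cv,
        ppm_jitter=ppm_jitter,
        n_noise_peaks=n_noise_peaks,
        seed=seed,
    )
    return spectrum, truth


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    """Per-peak ground-truth contributions as TSV."""
    lines = ["peak_index\tion\tcontribution\tis_overlap"]
    for j, contribs in enumerate(truth.peak_contributions):
        flag = int(j in truth.overlaps)
        for label, c in contribs:
            lines.append(f"{j}\t{label}\t{c:.6f}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mgf(
    spectrum: CentroidSpectrum, path: str | Path, title: str | None = None
) -> None:
    """Minimal MGF writer (one BEGIN IONS block)."""
    lines = ["BEGIN IONS", f"TITLE={title or spectrum.scan_id}"]
    if spectrum.precursor_mz is not None:
        lines.append(f"PEPMASS={spectrum.precursor_mz}")
    if spectrum.precursor_charge is not None:
        lines.append(f"CHARGE={spectrum.precursor_charge}+")
    for mz, ab in zip(spectrum.mz, spectrum.abundance):
        lines.append(f"{mz:.6f} {ab:.6f}")
    lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")
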