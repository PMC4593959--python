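"""Readers, writers and run configuration.

Spectrum input goes through pyteomics for mzML and MGF; plain two-column TSV
peak lists are supported for fixtures.  Protein input is FASTA plus an
optional PTM sidecar TSV (accession, site, name, delta_formula).  All report
writers use the same TSV dialect: absolute abundances to 6 decimals,
relative abundances to 2, IPMD/IPAD as nearest integers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml

from .fragments import FragmentIon, IonDatabase, Proteoform, parse_label
from .isotopes import ElementalComposition, TheoreticalEnvelope, parse_formula
from .matching import (
    CentroidSpectrum,
    EnvelopeMatch,
    SearchParams,
    round_half_away,
)
from .resolve import ResolutionResult

__all__ = [
    "RunConfig",
    "read_spectra",
    "read_fasta",
    "read_ptm_sidecar",
    "load_worked_example",
    "write_ion_database",
    "read_ion_database",
    "write_match_report",
    "write_resolution_report",
    "write_prsm_report",
    "write_proteoform_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Search parameters; defaults are the pre-optimized tolerance sets
    (precursor 40/15/100, product 20/15/50), PMP >= 5 and 1% spectrum FDR."""

    precursor: SearchParams = field(
        default_factory=lambda: SearchParams(40.0, 15.0, 100.0, "precursor")
    )
    product: SearchParams = field(
        default_factory=lambda: SearchParams(20.0, 15.0, 50.0, "product")
    )
    series: tuple[str, ...] = ("a", "b", "y")
    neutral_losses: tuple[str, ...] = ("NH3", "H2O", "NH3-H2O", "2NH3", "2H2O")
    max_charge: int = 15
    pmp_threshold: float = 5.0
    fdr_alpha: float = 0.01
    decoy_mode: str = "random"
    seed: int = 0
    resolve_oips: bool = True
    k_max_ptm_sites: int = 10

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        """Load from a flat key=value file (unknown keys rejected)."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
        cfg = RunConfig()
        params = {"precursor": cfg.precursor, "product": cfg.product}
        for scope in ("precursor", "product"):
            triplet = [
                kv.pop(f"{scope}_{name}", None)
                for name in ("ipaco", "ipmd", "ipad")
            ]
            if any(v is not None for v in triplet):
                base = params[scope]
                params[scope] = SearchParams(
                    float(triplet[0]) if triplet[0] else base.ipaco,
                    float(triplet[1]) if triplet[1] else base.ipmd_tol,
                    float(triplet[2]) if triplet[2] else base.ipad_tol,
                    scope,
                )
        simple = {
            "series": lambda v: tuple(v.split(",")),
            "neutral_losses": lambda v: tuple(x for x in v.split(",") if x),
            "max_charge": int,
            "pmp_threshold": float,
            "fdr_alpha": float,
            "decoy_mode": str,
            "seed": int,
            "resolve_oips": lambda v: v.lower() in ("1", "true", "yes"),
            "k_max_ptm_sites": int,
        }
        updates: dict = dict(params)
        for key, conv in simple.items():
            if key in kv:
                updates[key] = conv(kv.pop(key))
        if kv:
            raise ValueError(f"unknown config keys: {sorted(kv)}")
        return replace(cfg, **updates)


def _spectrum_from_arrays(mz, intensity, **meta) -> CentroidSpectrum:
    order = np.argsort(mz)
    mz = np.asarray(mz, dtype=float)[order]
    inten = np.asarray(intensity, dtype=float)[order]
    keep = inten > 0
    return CentroidSpectrum(mz[keep], inten[keep], **meta)


def read_spectra(path: str | Path, format: str | None = None) -> list[CentroidSpectrum]:
    """Read centroided spectra from mzML, MGF or a two-column TSV.

    The format is inferred from the extension unless given.  Profile-mode
    mzML spectra are rejected.  An empty file is an error.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "mzml":
        out = []
        with _mzml.MzML(str(path)) as reader:
            for s in reader:
                if "profile spectrum" in s:
                    raise ValueError(
                        f"profile-mode spectrum {s.get('id')} — centroid data required"
                    )
                prec_mz = prec_z = None
                try:
                    ion = s["precursorList"]["precursor"][0][
                        "selectedIonList"
                    ]["selectedIon"][0]
                    prec_mz = float(ion.get("selected ion m/z"))
                    if "charge state" in ion:
                        prec_z = int(ion["charge state"])
                except (KeyError, IndexError, TypeError):
                    pass
                out.append(
                    _spectrum_from_arrays(
                        s["m/z array"],
                        s["intensity array"],
                        precursor_mz=prec_mz,
                        precursor_charge=prec_z,
                        scan_id=str(s.get("id", "")),
                        retention_time=_mzml_rt(s),
                    )
                )
    elif fmt == "mgf":
        out = []
        with _mgf.MGF(str(path)) as reader:
            for s in reader:
                p = s.get("params", {})
                pep = p.get("pepmass")
                charge = p.get("charge")
                out.append(
                    _spectrum_from_arrays(
                        s["m/z array"],
                        s["intensity array"],
                        precursor_mz=float(pep[0]) if pep else None,
                        precursor_charge=int(charge[0]) if charge else None,
                        scan_id=str(p.get("title", "")),
                        retention_time=float(p["rtinseconds"])
                        if "rtinseconds" in p
                        else None,
                    )
                )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        if not {"mz", "abundance"} <= set(df.columns):
            raise ValueError("TSV peak list needs 'mz' and 'abundance' columns")
        out = [
            _spectrum_from_arrays(
                df["mz"].to_numpy(), df["abundance"].to_numpy(), scan_id=path.stem
            )
        ]
    else:
        raise ValueError(f"unsupported spectrum format: {fmt!r}")
    if not out:
        raise ValueError(f"no spectra found in {path}")
    return out


def _mzml_rt(s) -> float | None:
    try:
        return float(s["scanList"]["scan"][0]["scan start time"]) * 60.0
    except (KeyError, IndexError, TypeError):
        return None


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(protein_id, sequence) pairs; the id is the first header token."""
    out = []
    for header, seq in _fasta.read(str(path)):
        out.append((header.split()[0], seq.upper()))
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def read_ptm_sidecar(
    path: str | Path,
) -> dict[str, list[tuple[int, str, ElementalComposition]]]:
    """PTM annotations keyed by accession.

    TSV columns: accession, site (1-based), name, delta_formula (an
    elemental-composition string such as ``C2H2O`` for acetylation).
    """
    df = pd.read_csv(path, sep="\t")
    need = {"accession", "site", "name", "delta_formula"}
    if not need <= set(df.columns):
        raise ValueError(f"PTM sidecar needs columns {sorted(need)}")
    out: dict[str, list[tuple[int, str, ElementalComposition]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.accession), []).append(
            (int(row.site), str(row.name), parse_formula(str(row.delta_formula)))
        )
    return out


# ---------------------------------------------------------------------------
# Packaged worked-example fixture (printed-table excerpt)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("oiecare.data") / name)


def load_worked_example() -> tuple[list[FragmentIon], CentroidSpectrum]:
    """The packaged three-ion overlap fixture.

    The theoretical envelopes are printed excerpts (only the shared peak and
    each ion's normalization peak), so they must be fished with
    ``require_base=False``.
    """
    df = pd.read_csv(_data_path("worked_example_ions.tsv"), sep="\t")
    ions = _worked_style_ions(df)
    spectrum = read_spectra(_data_path("worked_example_spectrum.tsv"), "tsv")[0]
    return ions, spectrum


def _worked_style_ions(df: pd.DataFrame) -> list[FragmentIon]:
    """Build ions from an envelope-excerpt table (ion, theo_mz, theo_rel)."""
    ions = []
    for label, sub in df.groupby("ion", sort=False):
        series, index, nl, charge = parse_label(label)
        mz = sub["theo_mz"].to_numpy(dtype=float)
        rel = sub["theo_rel"].to_numpy(dtype=float)
        order = np.argsort(mz)
        env = TheoreticalEnvelope(
            mz=mz[order],
            rel_abundance=rel[order],
            charge=charge,
            monoisotopic_mz=float(mz[order][0]),
            base_index=int(np.argmax(rel[order])),
        )
        ions.append(
            FragmentIon(
                series=series,
                index=index,
                neutral_loss=nl,
                charge=charge,
                composition=ElementalComposition(),
                envelope=env,
            )
        )
    return ions


def write_ion_database(db: IonDatabase, path: str | Path) -> None:
    """Columnar TSV: label, series, index, nl, charge, formula, base_mz,
    peaks serialized as ``mz:rel;...`` (m/z to 6 decimals, rel to 6)."""
    lines = [
        "# proteoform\t{}\t{}\t{}".format(
            db.proteoform.protein_id,
            db.proteoform.sequence,
            db.proteoform.ptm_string(),
        ),
        "label\tseries\tindex\tnl\tcharge\tformula\tbase_mz\tpeaks",
    ]
    for ion in db:
        peaks = ";".join(
            f"{mz:.6f}:{rel:.6f}"
            for mz, rel in zip(ion.envelope.mz, ion.envelope.rel_abundance)
        )
        lines.append(
            f"{ion.label}\t{ion.series}\t{ion.index}\t{ion.neutral_loss}\t"
            f"{ion.charge}\t{ion.composition.formula()}\t"
            f"{ion.base_mz:.6f}\t{peaks}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ion_database(
    path: str | Path, ptms: tuple = ()
) -> IonDatabase:
    """Inverse of :func:`write_ion_database` (PTM deltas not round-tripped;
    pass ``ptms`` to restore them on the proteoform)."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# proteoform\t"):
        raise ValueError("missing proteoform header line")
    _, pid, seq, _ptm_str = text[0].split("\t")
    pf = Proteoform(pid, seq, ptms)
    ions = []
    for line in text[2:]:
        label, series, index, nl, charge, formula, base_mz, peaks = line.split("\t")
        mz, rel = zip(
            *(tuple(map(float, p.split(":"))) for p in peaks.split(";"))
        )
        mz = np.array(mz)
        rel = np.array(rel)
        env = TheoreticalEnvelope(
            mz=mz,
            rel_abundance=rel,
            charge=int(charge),
            monoisotopic_mz=float(mz[0]),
            base_index=int(np.argmax(rel)),
        )
        ions.append(
            FragmentIon(
                series=series,
                index=int(index),
                neutral_loss=nl,
                charge=int(charge),
                composition=parse_formula(formula),
                envelope=env,
            )
        )
    return IonDatabase(pf, ions)


# ---------------------------------------------------------------------------
# Report writers (abundances %.6f, relative abundances %.2f,
# IPMD/IPAD nearest integer)


def _fmt_int(x: float) -> str:
    return "" if np.isnan(x) else str(round_half_away(x))


def write_match_report(
    matches: list[EnvelopeMatch],
    spectrum: CentroidSpectrum,
    path: str | Path,
    oip_peaks: set[int] | None = None,
) -> pd.DataFrame:
    """One row per theoretical peak per ion (column order is the contract)."""
    oip_peaks = oip_peaks or set()
    rows = []
    for m in matches:
        ipmds = m.ipmds(spectrum)
        exp_rel = m.exp_rel()
        ipads = m.ipads()
        for i in range(len(m.links)):
            linked = m.links[i] >= 0
            rows.append(
                {
                    "ion": m.ion.label,
                    "theo_mz": f"{m.ion.envelope.mz[i]:.6f}",
                    "theo_rel": f"{m.theo_rel[i]:.2f}",
                    "exp_mz": f"{spectrum.mz[m.links[i]]:.6f}" if linked else "",
                    "exp_abs": f"{m.assigned_abundance[i]:.6f}" if linked else "",
                    "exp_rel": f"{exp_rel[i]:.2f}" if linked else "",
                    "IPMD": _fmt_int(ipmds[i]),
                    "IPAD": _fmt_int(ipads[i]),
                    "is_OIP": int(linked and m.links[i] in oip_peaks),
                    "verdict": m.verdict,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "ion", "theo_mz", "theo_rel", "exp_mz", "exp_abs", "exp_rel",
            "IPMD", "IPAD", "is_OIP", "verdict",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_resolution_report(
    results: list[ResolutionResult],
    spectrum: CentroidSpectrum,
    path: str | Path,
) -> pd.DataFrame:
    """One row per claimant per resolved OIP group."""
    rows = []
    for gid, res in enumerate(results):
        g = res.group
        for (match, theo_idx), dea, final, before, after in zip(
            g.claimants,
            res.dea,
            res.final_abundance,
            res.ipad_before,
            res.ipad_after,
        ):
            rows.append(
                {
                    "group": gid,
                    "exp_mz": f"{spectrum.mz[g.exp_index]:.6f}",
                    "EA_OIP": f"{g.observed_abundance:.6f}",
                    "ion": match.ion.label,
                    "TA_i": f"{match.theo_rel[theo_idx]:.2f}",
                    "EA_r": f"{match.reference_abundance():.6f}",
                    "TA_r": f"{match.reference_theo_rel():.2f}",
                    "DEA_i": f"{dea:.6f}",
                    "final": f"{final:.6f}",
                    "IPAD_before": _fmt_int(before),
                    "IPAD_after": _fmt_int(after),
                    "RD": f"{res.rd:.2f}",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "group", "exp_mz", "EA_OIP", "ion", "TA_i", "EA_r", "TA_r",
            "DEA_i", "final", "IPAD_before", "IPAD_after", "RD",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_prsm_report(prsms, path: str | Path) -> pd.DataFrame:
    rows = [
        {
            "scan": p.spectrum_id,
            "accession": p.proteoform.protein_id,
            "proteoform": f"{p.proteoform.sequence}"
            + (f" [{p.proteoform.ptm_string()}]" if p.proteoform.ptms else ""),
            "rank_score": p.rank_score,
            "pmp": f"{p.pmp:.2f}",
            "sequence_coverage": f"{p.sequence_coverage:.2f}",
            "bond_coverage": f"{p.bond_coverage:.2f}",
            "interpreted_peak_pct": f"{p.interpreted_peak_pct:.2f}",
            "interpreted_abundance_pct": f"{p.interpreted_abundance_pct:.2f}",
            "is_decoy": int(p.is_decoy),
        }
        for p in prsms
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "scan", "accession", "proteoform", "rank_score", "pmp",
            "sequence_coverage", "bond_coverage", "interpreted_peak_pct",
            "interpreted_abundance_pct", "is_decoy",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_proteoform_report(prsms, path: str | Path) -> pd.DataFrame:
    rows = [
        {
            "accession": p.proteoform.protein_id,
            "sequence_length": len(p.proteoform.sequence),
            "ptms": p.proteoform.ptm_string(),
            "best_scan": p.spectrum_id,
            "matching_by_ions": p.rank_score,
            "sequence_coverage": f"{p.sequence_coverage:.2f}",
            "bond_coverage": f"{p.bond_coverage:.2f}",
            "interpreted_peak_pct": f"{p.interpreted_peak_pct:.2f}",
            "interpreted_abundance_pct": f"{p.interpreted_abundance_pct:.2f}",
        }
        for p in prsms
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "accession", "sequence_length", "ptms", "best_scan",
            "matching_by_ions", "sequence_coverage", "bond_coverage",
            "interpreted_peak_pct", "interpreted_abundance_pct",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
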