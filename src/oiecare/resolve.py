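"""OIE_CARE: partitioning shared isotopic-peak abundance among ions.

When several product-ion envelopes claim one experimental peak (an OIP), its
observed abundance is the sum of every ion's true contribution.  OIE_CARE
splits it in three arithmetic steps, per group, independently:

1. For each claimant ion i, the *ideal* experimental abundance of the shared
   peak is what the peak would carry if the ion's envelope were exactly
   theoretical::

       DEA_i = TA_i * EA_r / TA_r

   where TA_i is the shared peak's theoretical relative abundance in ion i
   and (EA_r, TA_r) are the absolute experimental and theoretical relative
   abundances of the ion's reference isotopic peak.

2. The relative deviation of the observed shared-peak abundance EA_OIP from
   the summed ideal value::

       RD = (EA_OIP - sum_i DEA_i) / sum_i DEA_i

3. The final partitioned abundance of the shared peak in ion i::

       final_i = DEA_i * (1 + RD)

which is algebraically the proportional allocation
``EA_OIP * DEA_i / sum DEA`` — so the observed abundance is conserved
exactly, at a cost linear in the number of claimants.  RD is kept at full
precision throughout; the two-decimal RD in reports is display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matching import (
    CentroidSpectrum,
    EnvelopeMatch,
    OIPGroup,
    SearchParams,
    assign_references,
    classify,
    find_oips,
)

__all__ = [
    "ResolutionResult",
    "ideal_abundance",
    "relative_deviation",
    "partition_oip",
    "resolve_spectrum",
]


def ideal_abundance(ta_i: float, ea_r: float, ta_r: float) -> float:
    """Ideal experimental abundance DEA_i = TA_i * EA_r / TA_r."""
    if ta_r <= 0:
        raise ValueError("reference theoretical abundance must be > 0")
    return ta_i * ea_r / ta_r


def relative_deviation(ea_oip: float, deas: list[float]) -> float:
    """RD = (EA_OIP - sum DEA) / sum DEA, full precision."""
    total = float(sum(deas))
    if total <= 0:
        raise ValueError("summed ideal abundance must be > 0")
    return (ea_oip - total) / total


@dataclass
class ResolutionResult:
    """Outcome of partitioning one OIP group.

    Parallel lists over claimants; ``final_abundance`` sums to the observed
    shared-peak abundance.  ``op_count`` tallies the scalar arithmetic
    operations spent (linear in claimant count).
    """

    group: OIPGroup
    dea: list[float]
    rd: float
    final_abundance: list[float]
    ipad_before: list[float]
    ipad_after: list[float]
    op_count: int

    @property
    def labels(self) -> list[str]:
        return [m.ion.label for m, _ in self.group.claimants]


def partition_oip(group: OIPGroup) -> ResolutionResult:
    """Partition one shared peak's abundance among its claimant ions.

    Each claimant must have a non-degenerate reference peak (raises
    ``ValueError`` otherwise; the caller skips such groups).  Reads nothing
    outside the group, so groups resolve independently and in any order.
    """
    ops = 0
    dea: list[float] = []
    ipad_before: list[float] = []
    for match, theo_idx in group.claimants:
        if match.reference_degenerate:
            raise ValueError(
                f"degenerate reference on {match.ion.label}: group skipped"
            )
        ta_i = float(match.theo_rel[theo_idx])
        ea_r = match.reference_abundance()
        ta_r = match.reference_theo_rel()
        dea.append(ideal_abundance(ta_i, ea_r, ta_r))
        ops += 2  # one multiply + one divide per claimant (Eq. 1)
        ipad_before.append(
            group.observed_abundance * ta_r / ea_r - ta_i
        )
    rd = relative_deviation(group.observed_abundance, dea)
    ops += 2  # subtract + divide (Eq. 2; the sum reuses Eq. 1 outputs)
    final = []
    ipad_after = []
    for (match, theo_idx), d in zip(group.claimants, dea):
        f = d * (1.0 + rd)
        ops += 1  # one multiply per claimant (Eq. 3)
        final.append(f)
        ta_r = match.reference_theo_rel()
        ea_r = match.reference_abundance()
        ipad_after.append(f * ta_r / ea_r - float(match.theo_rel[theo_idx]))
    return ResolutionResult(
        group=group,
        dea=dea,
        rd=rd,
        final_abundance=final,
        ipad_before=ipad_before,
        ipad_after=ipad_after,
        op_count=ops,
    )


def resolve_spectrum(
    matches: list[EnvelopeMatch],
    spectrum: CentroidSpectrum,
    params: SearchParams,
    gate_nonneg: bool = True,
) -> list[ResolutionResult]:
    """Partition every OIP group in a spectrum and re-classify the ions.

    Groups are partitioned when at least one claimant sees the shared peak
    with a provisional IPAD >= 0 (``gate_nonneg=False`` partitions all);
    groups with a degenerate reference on any claimant are skipped.  Each
    claimant's assigned abundance at the shared peak is replaced by its
    partitioned share, relative abundances and verdicts recomputed.  The set
    of fished ions is never changed — resolution flips verdicts only.
    """
    groups = find_oips(matches, spectrum)
    assign_references(matches, groups)
    results: list[ResolutionResult] = []
    for group in groups:
        if gate_nonneg:
            provisional = []
            for match, theo_idx in group.claimants:
                if match.reference_degenerate:
                    continue
                ea_r = match.reference_abundance()
                ta_r = match.reference_theo_rel()
                provisional.append(
                    group.observed_abundance * ta_r / ea_r
                    - float(match.theo_rel[theo_idx])
                )
            if provisional and max(provisional) < 0:
                continue
        try:
            res = partition_oip(group)
        except ValueError:
            continue
        for (match, theo_idx), share in zip(
            group.claimants, res.final_abundance
        ):
            match.assigned_abundance[theo_idx] = share
        results.append(res)
    for m in matches:
        classify(m, params, spectrum)
    return results
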