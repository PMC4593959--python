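# oiecare

Resolution of overlapping isotopic envelopes (OIEs) in top-down protein
tandem mass spectra, inside a complete fragment-matching engine.

## The problem

HCD spectra of intact proteins are dense: hundreds of b/y fragment ions at
charge states 1–15+ crowd a narrow m/z range, and their isotopic envelopes
routinely share peaks. An experimental peak whose m/z is claimed by two or
more theoretical isotopic peaks is an *overlapping isotopic peak* (OIP); its
observed abundance is the sum of every claimant ion's contribution. Unless
that abundance is partitioned, the claimant envelopes look distorted, fail
the abundance-tolerance check and are discarded as non-matching — costing
sequence coverage, identifications and PTM localizations.

`oiecare` resolves OIPs against *exact* theoretical envelopes computed from
the elemental composition of each fragment's actual residues (not an
average-residue/Averagine model), with a cost linear in the number of
overlapping ions.

## The method

For an OIP shared by *n* ions, with TA\_i the theoretical relative abundance
(%) of the shared peak in ion *i* and (EA\_r, TA\_r) the absolute
experimental and theoretical relative abundances of ion *i*'s *reference*
isotopic peak (a clean peak used for normalization):

1. ideal abundance  DEA\_i = TA\_i · EA\_r / TA\_r
2. relative deviation  RD = (EA\_OIP − Σ DEA\_i) / Σ DEA\_i
3. partitioned abundance  final\_i = DEA\_i · (1 + RD)

Step 3 is algebraically the proportional allocation
EA\_OIP · DEA\_i / Σ DEA\_i, so the observed abundance is conserved exactly
and only 2n + 1 scalar operations are needed per shared peak.

Around this core the package provides: isotope-distribution convolution for
exact envelopes; a/b/y and neutral-loss ion generation with residue-based
loss eligibility; envelope fingerprinting under IPACO/IPMD/IPAD tolerances
(abundance cutoff %, m/z deviation ppm, abundance deviation percentage
points); PrSM metrics (sequence and peptide-bond coverage, PMP, interpreted
peaks/abundance, PTM localization score); decoy-based spectrum-level FDR;
mzML/MGF/TSV readers; and a synthetic-spectrum generator with ground truth.

## Worked example

The packaged fixture holds a real three-ion overlap from a myoglobin HCD
spectrum: y10-1+, y20-2+ and y72-7+ all claim the experimental peak at m/z
1142.617676 (observed abundance 480992.312500).

```sh
oiecare resolve --out resolution.tsv
```

prints (abridged):

```
 group      exp_mz        EA_OIP    ion   TA_i          EA_r   TA_r         DEA_i         final IPAD_before IPAD_after    RD
     0 1142.617676 480992.312500 y10-1+  23.01 128926.921875  63.64  46615.469396  42330.617979         214         -2 -0.09
     0 1142.617676 480992.312500 y20-2+ 100.00 281777.062500  67.65 416521.895787 378235.583145          15         -9 -0.09
     0 1142.617676 480992.312500 y72-7+  55.06 120854.796875 100.00  66542.651159  60426.111376         343         -5 -0.09
```

Reading: the shared peak's ideal abundances (DEA) sum to 529680.016342,
9% above the observed 480992.3125 (RD = −0.09). Each ion receives its
proportional share; the abundance deviations of the shared peak collapse
from 214/15/343 percentage points to −2/−9/−5, inside the 50-point
tolerance, so y10-1+ and y72-7+ flip from non-matching to matching ions.

Other entry points: `oiecare build-db` (FASTA + PTM sidecar → theoretical
ion databases), `oiecare search` (spectra → PrSM/proteoform reports with
decoy FDR), `oiecare simulate` (synthetic overlap spectrum + ground truth),
`oiecare report` (PrSM → unique-proteoform grouping).

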