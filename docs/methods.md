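# Methods

`cffrag` analyses the size distribution of circulating cell-free DNA (cfDNA)
and simulates it mechanistically from nucleosome protection. This note
describes the statistics, the generative model, the calibration of its frozen
presets, the numerical choices, and what the synthetic data do and do not
show about real plasma.

## The measurement problem

Plasma cfDNA is nuclear chromatin degraded by blood nucleases; what survives
is what histones protect. Three assays see this population differently:

* **DSP-S** — whole-genome sequencing from a double-strand library. A
  fragment is measured only as an intact duplex: internal single-strand
  breaks (nicks) hide molecules unless one strand is still continuous.
* **SSP-S** — sequencing from a single-strand library. Each strand is
  denatured and captured on its own, so the n nicks of a strand release
  n+1 measurable pieces, down to ~25 nt.
* **Q-PCR** with nested amplicons (67/145/320 bp at one locus) — amplifies
  from a single-strand template, counting molecules that retain a nick-free
  stretch of at least the amplicon length, with no upper size limit.

The package implements the comparison statistics used to contrast these
readouts and to contrast cancer with healthy plasma, and a simulator that
generates molecule populations whose three readouts jointly match the
published healthy and colorectal-cancer (CRC) summaries.

## Profile statistics

A *size profile* is the per-base-pair frequency f(x) of fragment lengths on
a closed support, by default the 30–440 bp mono-/di-nucleosome window for
cohort statistics (WGS detection spans ~30–1000 bp). On it the package
computes:

* the cumulative curve S(x) = Σ_{y≤x} f(y);
* **ΔS**(x) = 100·(S_a − S_b) and **ΔV**(x) = 100·(f_a − f_b) between two
  profiles, both renormalized over the common support first so ΔS vanishes
  exactly at the upper end and ΔS is the running sum of ΔV;
* range fractions on closed integer ranges; the canonical partition is
  <90 / 90–240 / 241–440 bp, which sums to 100;
* the modal peak (ties to the smaller length) and the f(166)/f(145)
  frequency ratio, whose healthy values differ sharply between assays;
* sub-peak detection: a centred moving average (half-width 2, i.e. 5 bp)
  is scanned for local maxima with prominence at least 0.15 × the median
  in-window frequency; each is reported at the raw argmax within ±2 bp.
  `periodicity` is the median sub-peak spacing (half-integers round down),
  and `stagger_offset` is the modal signed difference from each sub-peak of
  one report to the nearest sub-peak of the other (ties to the smallest
  absolute value);
* per-sample feature panels against a healthy reference mean profile
  (arithmetic mean of frequencies, renormalized), and Spearman rank
  correlations of the features against the mutant allele fraction (MAF).
  Spearman is used because the claimed association is monotone, not
  linear; a feature constant across samples is reported as undefined
  (NaN), never zero.

"ΔV of the 40–160 bp range" is computed as the **sum** of per-length ΔV over
40–160 inclusive (equivalently ΔS(160) − ΔS(39)); the alternative readings
(mean or extremum) are not used anywhere.

Q-PCR statistics follow the closed forms HF = 100(C67−C145)/C67,
MF = 100(C145−C320)/C67, WF = 100·C320/C67 and DII = C320/C67 (so
DII = WF/100 identically). Concentrations are unit-free; only ratios are
meaningful. A longer amplicon measuring more template than a shorter one is
a hard nesting-violation error, never clamped.

## The generative model

### Structural classes

Each simulated molecule belongs to one class (weights per cohort preset):

| class | duplex length law | role |
|---|---|---|
| CHROMATOSOME | 166 ± 1 bp point mass (probability `chromo_peak_mass`) plus an asymmetric linker-remnant dispersion: a flat trimming continuum down to 166−`tail_left` and a truncated-exponential tail (scale `tail_right`, max +94) above | the broad 80–260 bp mono-nucleosome population with its mode at 166 |
| CORE | uniform 144–160 bp | core-particle family after H1 loss and linker trimming, with end breathing; anchors the 144–145 bp shoulder |
| SUBNUC | 166 − round(10.2·k) bp, k ≥ 1 geometric (decay per preset), ±2 triangular jitter | the ~10 bp trim ladder of deeper intra-nucleosomal cuts |
| DINUC | normal (centre 332 healthy / 300 malignant, SD 12/8), truncated 260–440 | di-nucleosomes |
| TRINUC | normal ~500 ± 20 | trace tri-nucleosomes |
| HIGH_MW | log-uniform 1000–10000 bp | chromatin above the sequencing limit, visible only to Q-PCR |

The linker-remnant dispersion of the chromatosome class is what produces the
smooth monomodal 80–260 bp profile; without it the mono population collapses
onto three bins and no weighting can reproduce the published range
percentages and frequency ratios simultaneously.

### Nicking

Nicks occur at minor-groove lattice sites every ~10.2 bp from each protected
terminus, up to 7 per side per wrapped nucleosome (14 sites per wrap; the
central linker of di-/tri-nucleosomes carries no regular lattice). Sites
get a shared ±1 bp triangular rotational jitter. Attack is one-sided: per
molecule one randomly chosen strand is solvent-exposed (per-site probability
`p_site_nick` = 0.2116) while the other is shielded
(`protected_factor` = 0.12 of that). These two constants are pinned by the
requirement that 97–98% of mono-nucleosome-family molecules carry at least
one nick while one strand frequently survives intact — with
strand-symmetric nicking those two observations are incompatible.
High-MW molecules instead receive sparse Poisson nicks (6×10⁻⁴ per nt per
strand).

### Readout rules

**DSP** — opposing nicks at the same site (within a 5 bp vicinity window)
form a double-strand break and split the duplex at the first-strand
coordinate; each resulting segment is recovered iff at least one of its
strands carries no remaining nick; duplex segments shorter than 90 bp peel
off the histone surface and are discarded with probability 0.9; lengths
outside [30, 1000] bp are dropped; high-MW molecules never enter the
library. Total segment length is conserved by the splitting.

**SSP** — every strand splits at its own nicks into n+1 pieces. Reported
piece lengths embody the 3-nt 3′ stagger of the two strand paths on the
nucleosome: every nick-bounded piece, and every intact strand of a
sub-nucleosomal trim product (whose termini are themselves staggered cuts),
reads +3 nt relative to the duplex coordinate system. Retention multiplies
three factors: the sequencer detection ramp (0 at 25 nt → 1 at 45 nt), the
peel-off survival of nick-released pieces (floor 0.05 below one full turn
at 70 nt, rising to 1 at 120 nt — pieces wrapping less of the octamer are
mostly degraded), and a single-strand library capture decay
exp(−(L−200)/95) for long templates (single-strand conversion strongly
favours short fragments; this is what makes the di-nucleosome range 12.7%
of DSP but only 4.8% of SSP despite identical molecules). Intact strands
of molecules whose sister strand is nicked additionally read with a ±2 nt
end-fraying dispersion (rounded normal, SD 1.5), which softens the SSP 166
peak relative to DSP's (2.0% vs 2.5% in data) and sets the gap between the
two 166/145 ratios (3.1 vs 1.58).

These retention effects are library efficiencies, not part of the splitting
mechanism; mechanism tests therefore run under a deterministic model variant
with all of them disabled.

The net sub-peak observable: DSP sub-peaks sit on the duplex lattice
(…95, 105, 115, 125, 135…) fed coherently by double-strand-break fragments
and the trim ladder, SSP sub-peaks sit 3 nt above (…98, 108, 118…), fed by
nick-released pieces and trim-product strands, so `stagger_offset` between
the two reports is 3.

### Cohorts, presets and MAF mixing

`simulate_cohort` derives sample i's generator from `seed + i` and jitters
the class weights per sample on the log-odds scale (SD 0.01 — small, because
the observed healthy profiles superimpose almost exactly). Three frozen
presets exist: `healthy-7` and `healthy-109` (identical chromatin mixture;
high-MW shares 16.7% and 6.4% respectively, because the two healthy
experiments they emulate report different weakly-fragmented levels — WF
≈ 23% vs mean DII 0.134), and `crc-allstage` (the malignant component at
weight 1). `crc-metastatic` mixes the frozen malignant component into the
healthy background with probability MAF/100; the MAF is used directly as
the malignant-molecule mixture weight.

MAF series simulated from one seed are coupled by common random numbers: a
leading uniform per molecule decides malignancy, components draw from
spawned child streams, and readout randomness is drawn on fixed array
shapes. Raising the MAF therefore converts a nested subset of molecules and
leaves everything else bit-identical, so monotone trends (short-fraction up,
166/145 ratio down, ΔS peak up) are measured without between-run noise.

## Calibration of the frozen presets

The structural rules above are fixed; free quantities are the class weights,
the sub-nucleosomal decay, the chromatosome tail/peak shape, the
di-nucleosome nick factor, and the four retention scalars. They were fitted
once by `scripts/calibrate_presets.py`: per structural subclass the expected
DSP segment spectrum and the SSP intact-strand and released-piece spectra
are estimated through the real readout code with retention disabled
(150,000 molecules per subclass); peel-off, detection, survival, capture and
smear are then applied analytically, so mixtures can be evaluated in
milliseconds and the weights optimized by multi-start Nelder–Mead inside a
small grid over the retention scalars. Targets were the published healthy
summaries (range percentages of both assays, both 166/145 ratios, the
30–145 bp fraction, summed ΔV(SSP−DSP) over 40–160), a matching set of
cancer-shaping targets for the malignant component, and modal-dominance
guards keeping 166 the peak of both assays. The high-MW shares then follow
in closed form from the Q-PCR integrity targets (WF 23%, DII 0.134, DII
0.004) and were refined once against a direct 400,000-molecule in-silico
Q-PCR run. The resulting constants are committed in `cffrag.simulate` and
never re-fitted by tests.

Problem sizes used by the test suite and `scripts/acceptance.py` — 7 × 200k
molecules for the WGS cohort summaries, 500k for sub-peak detection,
109/104 × 50k for the integrity cohorts, 7 × 150–200k for the MAF grid —
were chosen so that Monte-Carlo error is several times smaller than each
quantity's tolerance.

## Numerical choices and degenerate inputs

* Profiles are dense vectors over their support; frequencies must sum to 1
  within 1e-9. Narrowing a support renormalizes; a window without mass is
  an error, as are disjoint supports in ΔS/ΔV.
* Peak ties break to the smaller length; `periodicity` rounds half-integers
  down; `stagger_offset` mode ties break to the smallest absolute offset.
* `ratio_at` raises on a zero denominator frequency but returns 0.0 for a
  zero numerator.
* Sub-peak smoothing uses truncated-kernel edge normalization; a window
  shorter than the kernel is an error; two spikes merged by the kernel are
  reported once, at the higher raw bin.
* BED input is 0-based half-open; empty intervals are per-line errors. BAM
  reading takes |TLEN| of the first-in-pair, proper-pair, primary,
  non-duplicate alignment with MAPQ ≥ 20 by default (the duplicate filter
  can be disabled); all reported lengths are integer bp.
* Readouts are deterministic given a seed; cohort outputs and comparison
  reports are byte-identical across reruns.

## What the synthetic data are and are not

The generator emulates the *structure* of plasma cfDNA size data: a
homogeneous healthy population with a 166 bp mode, ~10 bp sub-peaks on the
correct lattice phases in both assays, the published range fractions,
ratios and integrity indices, and cancer profiles that shift continuously
with the malignant fraction. It does not emulate: genomic positions or
sequence (no GC effects, no tissue-of-origin signal), transcription-factor
footprints, mitochondrial cfDNA, pre-analytical contamination with
leukocyte DNA, or amplification-efficiency effects in Q-PCR (detection is
all-or-none on an intact run). The in-silico Q-PCR HF/MF balance of the
healthy presets (≈19/59 instead of the reported 38/39) was left
uncalibrated: under this nicking model the 145 bp-run capability of
mono-nucleosomes is higher than the real assay measures, and forcing it
would break the WGS-side fit — a known limitation. Likewise the simulated
peak height at 166 bp (≈5–6% of fragments for DSP) exceeds the reported
~2.5% because the calibration constrains range masses and ratios, not the
full curve shape. Passing tests therefore demonstrate that the mechanistic
rules reproduce the published summary statistics, not that the simulator is
a complete forward model of plasma sequencing data.
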