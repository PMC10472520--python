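# Methods

## Scope and model overview

The package quantifies group-specific *pmoA* copy numbers from
chip-based digital PCR and screens the assay's hydrolysis probes
against sequence panels. Everything downstream of the wet lab is
modelled: probe/primer properties, in-silico specificity, partition
statistics, unit conversion, series validation and depth-profile
statistics. Wet-lab steps (extraction, chip loading, cycling) and
real-time-PCR calibration are out of scope; an externally measured
total *pmoA* column is accepted as input for a sum/total cross-check
only.

## Oligos and melting temperature

Sequences are upper-cased, `U` maps to `T`, and every symbol must be
one of the 15 IUPAC codes; degeneracy is the product of per-position
set sizes. Probes are stored 5'→3' as synthesized and hybridize to the
sense strand, so all matching against sense-strand templates goes
through the IUPAC reverse complement.

Melting temperatures use nearest-neighbour thermodynamics (unified
parameter set, via Biopython) at 50 mM monovalent salt and 250 nM
oligo, defaults chosen as ordinary hydrolysis-probe conditions. For a
degenerate oligo the Tm is the arithmetic mean over all expansions up
to 256, else over a seeded sample of 256 — a pragmatic reduction, since
a single Tm is conventionally reported per degenerate probe. The vendor
software behind published probe Tm values does not disclose its
parameters, so only the ordering of probe Tms is asserted (the shipped
probes order correctly, each within a few °C of their nominal values;
logged, not asserted).

## Specificity screening

In-silico PCR scans both primers ungapped along the sense strand
(reverse primer as its sense-strand image) and keeps the pair
minimizing total mismatches, ties broken 5'-most with a warning; both
primers must stay within a mismatch budget (default 3) or the record is
reported "no_amplicon" and excluded from bins. Probe matching slides
the probe's sense-strand image along the amplicon; a position matches
iff the two IUPAC sets intersect, so `N` never counts as a mismatch and
degenerate positions match their whole set. No indels are allowed:
hydrolysis probes do not tolerate bulges at this length scale.

Detection calls: ≤1 mismatch "+", ≥3 "−", exactly 2 "uncertain"
(configurable); the ≥3 bin absorbs everything above 2 so the four bins
partition all counts. Multi-copy genomes (e.g. type IIa strains
carrying a divergent *pmoA2*) aggregate per-copy calls with a logical
OR on "+", since any amplifiable copy lights its well. Coverage bins
are computed over each probe's target groups only (Ia; Ib + RPC1; IIa),
on the primer-delimited region rather than full-length genes.

## Partition statistics

With k of N wells positive and p̂ = k/N, the plain Poisson estimate is
λ̂ = −ln(1 − p̂). Partition-volume variability (CV η) changes the
expected negative fraction to E[exp(−λV/V̄)]; for a normal volume law
this expectation is exactly exp(−λ + λ²η²/2), which is inverted by
bracketed root finding on λ ∈ (0, 1/η²] (the decreasing branch). The
corrected estimate always exceeds the plain one for η > 0 (Jensen) and
reduces to it continuously as η → 0. The default is η = 0 so results
never depend on an unstated instrument parameter; η is a knob.

Confidence intervals use the delta method, SE(λ̂) = √(p̂/(N(1−p̂))),
λ̂ ± 1.96·SE floored at 0, with exact binomial inversion behind a flag.
Exact coverage computed against the binomial law is 94.8–95.0% for
λ between 0.01 and 3 at N = 20,000. Empty chips (k = 0) return 0 with a
one-sided 95% Clopper–Pearson upper bound; saturated chips (k = N)
return no point estimate, only a lower bound evaluated at k = N − ½.

Well classification maximizes between-class variance exactly on the
sorted intensities (the histogram-free form of Otsu's criterion,
threshold at the midpoint of the optimal split gap — binned variants
can misplace the threshold by one well on 20k-well chips). A separation
score (gap between class means over pooled within-class SD) below a
floor of 2 rejects the automatic call, falling back to a user threshold
when given and raising otherwise.

Unit chain: copies per chip = λ̂·N; ÷ loaded volume (14.5 µL) → per µL
mix; × reaction/template volumes (15/1.5) → per µL template; ×
elution volume × dilution ÷ dry mass → copies g⁻¹ dry soil.

## Chip simulator

Per chip: the molecule count is Poisson at the requested mean (aliquot
sampling, as in real pipetting); well volumes are normal with mean 1
and CV η, truncated at zero (gamma behind a flag — no volume
distribution is published); molecules land multinomially with
volume-proportional probabilities; each molecule is detected with a
probability set by its probe mismatch count (default 1.0 at 0–1
mismatches, 0.0 at ≥2 — the behaviour at exactly 2 is untested
empirically and configurable); wells with ≥1 detected molecule, or a
false-positive event, are positive. Fluorescence is two-component
normal noise, negative (5000, 200) and positive (12000, 500) arbitrary
units — ~14 pooled SDs apart, mirroring the clear bimodal separation of
well-optimized chips. Everything is reproducible from a single seed.

The default chip has 20,000 wells, 14.5 µL loaded, volume CV 0.10 — a
typical chip-level volume dispersion, also used by the validation
studies. Dilution-series levels are interpreted as copies per µL of
loaded mix (loaded copies = conc × 14.5): the per-µL-template reading
would put only ~73 copies on the lowest chip, whose pure sampling noise
(~9–12% duplicate CV) contradicts the low-percent CVs the method is
known to achieve at its lowest levels; the template basis remains
available as an option.

What the simulator does **not** model: amplification kinetics, partial
amplification "rain" between the fluorescence components, multi-channel
chemistry, inhibition, or extraction losses. Passing tests therefore
demonstrate the statistical machinery on an idealized chip, not
robustness to those artefacts in field samples.

## Soil depth-profile fixture

The packaged fixture (`mobdpcr/data/soil_profile.toml`) encodes six
samples (bulk soil before flooding; layers 0–2, 2–4, 4–6, 6–8, 8–10 mm)
× three MOB types × three replicates. Truths are synthetic, set to the
reported orders of magnitude (Ia/Ib 10⁵–10⁶, IIa ~10⁷ copies g⁻¹, all
peaking at 0–2 mm) with the 0–2 mm layer at exactly 3.4× / 4.8× the
pre-flooding Ia / Ib abundance (increases of 240% / 380%), and the type
IIa minimum at 6–8 mm. Replicates jitter the truth by a lognormal
factor of 0.05 log₁₀ units (~12%), a typical between-microcosm spread;
extraction assumes 0.5 g dry soil eluted in 100 µL, with the abundant
IIa template pre-diluted tenfold to keep chips below λ ≈ 1. The fixture
carries its own seed (7) so the packaged dataset is a fixed object.

With triplicates at this noise level, a single fixture realization of
the percent-change statistic scatters with SD ≈ 35 (Ia) / 50 (Ib)
percentage points around the configured 240%/380%; the test suite
checks unbiasedness of the full pipeline by averaging over 60
independent fixture realizations (standard error ≈ 5 points) and checks
the packaged realization within its single-draw spread.

## Series validation and profile statistics

CV uses the n−1 sample SD over the mean (×100); for duplicates this is
|x₁−x₂|/(√2·mean). Linearity is ordinary least squares of estimated on
expected copies on the raw scale (matching how such series are
plotted), R² = 1 − SSE/SST, with a pointwise 95% band for the mean
response; a log-log option exists. The accuracy ratio is
log₁₀(estimated)/log₁₀(predicted), defined only for positive values and
predicted ≠ 1.

Depth-profile comparisons log₁₀-transform copies g⁻¹ (the base is
irrelevant to the test; base 10 matches how such profiles are plotted)
and run Tukey–Kramer: q = |mᵢ−mⱼ|/√(MSE/2·(1/nᵢ+1/nⱼ)) against the
studentized-range quantile q(α, k, df), which is exactly Tukey's HSD at
equal n and reduces to the pooled t-test (q = √2·|t|) at k = 2.
Critical values come from the studentized-range distribution function
(cached — the quantile is expensive) and are validated against
published tables and against an independent HSD implementation in the
tests. Comparisons run per MOB type across samples. The compact letter
display enumerates maximal cliques of the non-significance graph
(Bron–Kerbosch), the only construction that guarantees two groups share
a letter iff they are not significantly different; naive greedy
insertion can violate that. Percent change uses arithmetic replicate
means on the raw copy scale (log-scale means optional); relative
abundance normalizes the three type-specific means per sample.

## Problem sizes in the validation workflows

The dilution-series study uses 500 simulated duplicate series (4,000
chips of 20,000 wells); estimator bias/spread checks use 1,000 chips
per λ; CI coverage uses 4,000 chips per λ (Monte-Carlo SE ≈ 0.35%);
the familywise-error simulation uses 1,000 six-group datasets. These
sizes put Monte-Carlo noise well below every asserted margin.

## Known limitations

* Published probe Tm values cannot be reproduced bit-exactly
  (proprietary algorithm); only ordering and approximate agreement.
* The full 606-sequence design panel is not shipped; coverage bins are
  exercised on constructed panels, and reproducing the published bin
  totals requires retrieving the listed accessions externally.
* The volume-corrected estimator is a second-order moment closure; at
  extreme occupancies (negative fraction below exp(−1/(2η²))) it has no
  solution and reports an error rather than extrapolating.
* Saturated chips carry only a lower bound; near-saturated chips are
  flagged low-precision but not censored.
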