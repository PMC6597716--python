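# Methods

## Scope and models

The package analyses how a few amino-acid substitutions convert a
thermophilic enzyme's catalysis into mesophilic-like behaviour. It chains
five quantitative stages; each is an ordinary, well-characterised model, and
the package's contribution is their integration plus a fully synthetic test
surface.

### Michaelis–Menten fitting (`kinetics_fit`)

Initial velocities for one varied ligand (NAD⁺ or D-3-IPM; the other held
fixed) are fit by unweighted nonlinear least squares to
v = Vmax·S/(Km+S); kcat = Vmax/[E]. Unweighted least squares is the default
because no error model is attached to typical steady-state data; an optional
weighting hook is deliberately not exposed until a use case demands it.
Numerical choices: both axes are normalised to unit scale before the
trust-region fit (Vmax ~ 1e-10 M/s and Km ~ 1e-6 M otherwise stall the
optimizer's default tolerances); initialisation Vmax₀ = 1.2·max(v), Km₀ =
concentration nearest half-max; parameters bounded positive; a Km pinned at
the bounds is reported non-converged. Standard errors come from the
covariance of the fit.

Relative-value tables divide each enzyme's constant by the reference
enzyme's and round to **two significant figures** (half away from zero).
This convention reproduces all 24 parenthesized 25 °C fold-changes of the
packaged constants table exactly. The multi-temperature table contains a few
parenthesized values that were evidently computed from unrounded raw data
(e.g. the mesophile's 25 °C coenzyme-Km ratio appears as 57 in one table and
28 in the other, from identical printed constants); these are reported as
computed and flagged, not matched.

Specific activity uses U/mg = (slope₃₄₀/(ε·path))·V·10⁶/mass with
ε₃₄₀(NADH) = 6220 M⁻¹cm⁻¹ by default (configurable).

### Transition-state energetics (`thermo_profile`)

State energies at T_ref (default 298.15 K) relative to the initial state:
ΔG‡ from the Eyring equation, ΔG_m from Km, ΔG_T their sum; ΔH‡ from an OLS
Arrhenius slope of ln kcat on 1/T with the −RT term evaluated at T_ref; ΔH_m
from the van't Hoff slope of ln(Km/c°); entropic terms by difference. All
nine quantities satisfy the conservation identities by construction and are
validated to 1e-9 kJ/mol.

**Sign convention.** The literal textbook-table form ΔG_m = −RT ln Km gives
a positive number for micromolar Km and makes the total barrier of the
thermophile and mesophile differ by ~17 kJ/mol, contradicting both
thermodynamic meaning and the observed equality of their total barriers.
The default is therefore the *association* convention, ΔG_m = RT ln(Km/c°)
with c° = 1 M and ΔH_m = +R·slope, under which the two wild types agree to
0.55 kJ/mol at 25 °C. `as_printed` flips both binding-term signs for
comparison with literature tables, and `convention_audit` reports both.

Km is treated as a dissociation-constant proxy for coenzyme binding; this
is exact only for rapid-equilibrium binding, a stated model assumption.
Slopes use all supplied temperatures (3–4 in practice); two temperatures are
allowed with a warning. The Arrhenius estimate of ΔH‡ carries a small
curvature bias from the kB·T/h prefactor (≈0.3 kJ/mol over 25–70 °C); the
generator-inverse regression of ln(kcat·h/(kB·T)) on 1/T is exactly linear
and is what the recovery tests use when 6-digit recovery is asserted.

Profiles are compared by RMS distance over the nine state energies and
classified by nearest neighbour; on the packaged constants the combined
best mutant sits ~3.5× closer to the mesophile than to its thermophilic
parent.

Constants: R = 8.314 J K⁻¹ mol⁻¹, h = 6.626×10⁻³⁴ J s,
k_B = 1.381×10⁻²³ J K⁻¹, overridable as a frozen dataclass for
reproducibility studies.

### Mutant design (`comparative_design`)

Distances are minima over heavy atoms (hydrogens excluded), over **all
copies of a ligand in all chains** — cross-subunit proximity counts, since
active sites of homodimeric dehydrogenases are shared between subunits.
"Structurally close" substitutions are grouped by single-linkage clustering
on minimum inter-residue heavy-atom distance with a default link threshold
of 6 Å (configurable); single linkage keeps adjacent active-site pairs such
as 272/273 in one construct without merging distant shells. Alignment
position i of sequence A maps to structure residue number i + offset
(default 0, 1-based). Insertion runs in sequence B attach to a construct
when an immediately flanking aligned column is one of its substitutions; an
insertion flanked by substitutions of two constructs attaches to both, with
a logged warning.

The global aligner is Biopython's `PairwiseAligner` (BLOSUM62, gap open 11,
extend 1, global mode). Tie-breaking among co-optimal alignments uses the
aligner's deterministic first traceback path. A curated aligned FASTA can
always be supplied instead and takes precedence.

The exact grouping that produced the historical 11 + 18 constructs is not
derivable from published information, so construct *counts* are never
asserted; the properties that are asserted are shell nesting
(selected(8 Å) ⊆ selected(12 Å)), oracle equality of the distance map, and
that grouping partitions the candidate set.

### Melt fitting (`melt_stability`)

Two-state model with linear baselines and ΔCp = 0, θ(T) =
(1−f)(aN+bN·T) + f(aU+bU·T), f = 1/(1+exp(ΔH_vH(1−T/Tm)/(R·T))) (Kelvin
internally, °C at the interface). Initialisation: Tm from the extremum of a
Savitzky–Golay-smoothed derivative, baselines from the first/last decile.
A scan whose total span is below 10× a robust noise sigma (median absolute
second difference / (0.6745·√6)) is reported as a no-transition result
rather than fit; iid noise alone spans ~6σ over a typical scan. The
derivative midpoint is also exposed as a model-free fallback for
irreversible or asymmetric melts, common in thermophilic proteins. ΔTm
propagates both standard errors in quadrature.

### Trade-off regression (`tradeoff_analysis`)

OLS of log₁₀(specific activity at 25 °C) on Tm, with Pearson r (sign of the
slope). Base-10 logs: r and deviations are base-invariant, slopes are
documented as log₁₀ units per °C. The line is fit to wild-type points only;
engineered mutants are scored as vertical deviations, so "escaping the
trade-off" is a positive deviation.

## Synthetic generator (`synthetic_data`)

The generator is the package's ground-truth source. An `EnzymeTruth` fixes
activation (ΔH‡, ΔS‡) and binding (ΔH_m, ΔS_m) parameters so that kcat(T)
follows the Eyring law and Km(T) the van't Hoff law exactly, plus a melt
midpoint Tm, a van't Hoff unfolding enthalpy, and CD baselines. Velocity
and ellipticity noise is multiplicative Gaussian (velocities span orders of
magnitude across temperatures, so relative noise is the natural model;
default 1%). All randomness flows through a seed; identical seeds give
identical datasets.

Presets `thermophile-like` and `mesophile-like` (and the two combined-mutant
presets) are calibrated by exact Eyring/van't Hoff regression through the
packaged measured constants at 25/40/70 °C. Because the measured kcats are
not perfectly Eyring-consistent, the calibrated law reproduces individual
kcat rows to within ~30% (Km rows within ~5%) — the presets match the
*temperature trend*, not every printed digit. Melt midpoints are reported
only graphically for the real enzymes, so the presets adopt representative
values chosen once: 88 °C (thermophile-like), 66 °C (mesophile-like), 86 and
83 °C for the combined mutants (2 and 5 °C below the thermophile), with
ΔH_vH = 500 kJ/mol, typical of a ~70 kDa dimer. The trade-off family
generator draws wild-type points from log₁₀(activity) = 4.98 − 0.06·Tm with
0.08 log-units of scatter over Tm 58–90 °C, consistent with a ~25-fold
activity ratio across a ~22 °C stability gap.

Toy PDB structures place each residue's Cα at an exact target distance from
a single-atom HETATM ligand, with the rest of a minimal backbone (N, C, CB)
radially further out, so the minimum heavy-atom distance equals the target
to within the 0.01 Å coordinate precision of the PDB format. Ligands
co-locate by default so per-ligand and min-over-ligand distances coincide;
explicit ligand positions and residue directions are available for
controlled geometries, and placements that undercut a target distance are
reported as clashes.

**What the generator does not emulate:** two-substrate (bi-bi) kinetics,
substrate inhibition and cooperativity; ΔCp ≠ 0 and irreversible or
scan-rate-dependent unfolding; realistic side-chain geometry and packing;
correlated or heteroscedastic instrument noise. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to every behaviour of real data.

## Problem sizes and seeds

Recovery studies use 100 noise realisations at 1% relative noise
(8-concentration titrations spanning 0.2–5×Km at 25/40/55/70 °C; 81-point
melt scans at 0.5 °C over 60–100 °C), and design-rule properties use 100
random 8-residue toy structures — sizes at which the Monte-Carlo summaries
are stable to well within the asserted tolerances. The acceptance script
derives all per-dataset seeds from a single `--seed` argument.

## Known limitations

- Km-based binding energies inherit the rapid-equilibrium assumption; for
  strongly kinetically controlled Km the MS-state energies are effective,
  not equilibrium, quantities.
- The Arrhenius ΔH‡ ignores heat-capacity effects (no ΔCp‡ term).
- Construct grouping reproduces the *rules*, not the historical constructs;
  anyone with the original construct table can supply it directly.
- The trade-off regression is descriptive; no causal flexibility/stability
  model is implied.
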