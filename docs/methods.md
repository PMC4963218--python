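# Methods

This note documents the models, parameter choices and limitations behind
`ptmdelta`, in the order the pipeline runs them.

## Paired conformational ensembles

Conformations are capped tripeptides — Ace-Gly-Yyy-Gly-Nme for Lys/Arg (the
small methyl/acetyl groups leave the central residue's torsion space
unconstrained by its neighbors), Ace-Ala-Yyy-Ala-Nme for the glycosylated
residues — built from idealized internal coordinates (heavy atoms only) by
sequential natural-extension (NeRF) placement. Bond lengths and angles come
from standard residue-topology values; no geometry optimization or
force-field energy is ever computed, because the analysis consumes torsions
and pairing structure, not energies.

Backbone (φ, ψ) and side-chain χ torsions are drawn from a packaged
residue-specific library: a mixture of Ramachandran basins (β, polyproline-II,
right- and left-handed α, with residue-appropriate weights and spreads) and
gauche−/trans/gauche+ χ wells with ~10° Gaussian jitter
(`src/ptmdelta/data/torsion_library.json`). This library is a surrogate for
torsion statistics harvested from high-resolution X-ray structures; the
analysis only requires a representative, reproducible sample of
naturally-occurring torsions, and every distributional claim made by the
tests is about this library, not about any particular structure set.

Each accepted backbone yields one unmodified conformation plus modified
conformations sharing the identical `TorsionSet`:

- acetyl-Lys: 2 amide rotamers (0°, 180°); methyl-Lys (mono and di): 3
  staggered rotamers (+60°, −60°, 180°); tri-methyl-Lys: one fixed staggered
  arrangement. At 500 backbones the lysine study comprises
  500 + 1000 + 1500 + 1500 + 500 = 5,000 conformations.
- arginine: Nε-methylation has a single planar placement (500); each
  Nη site carries two planar methyl placements (2 sites × 2 × 500 = 2,000,
  so 2,500 mono-methyl in total); symmetric di-methylation enumerates two
  syn/anti combinations (1,000) and asymmetric di-methylation four
  site/orientation labels (2,000) — 3,000 di-methyl, 6,000 Arg conformations
  in total. The published conformer counts constrain the totals but not the
  exact meaning of each Nη label; the scheme here reproduces the totals and
  treats every rotamer as equally probable, and the labels for planar
  guanidinium methyls enumerate sites and in-plane placements.
- glycans (α-D-GalpNAc-(1-O)- and β-D-GlcpNAc-(1-O)-Ser/Thr,
  β-D-GlcpNAc-(1-N)-Asn) attach an idealized rigid chair template via two
  glycosidic torsions sampled from {+60°, −60°, 180°}; 500 clash-free
  glycosylated conformations are kept and their monosaccharide-removed twins
  retain the identical torsions. The pyranose ring is a fixed Z-matrix chair
  whose C5–O5 closure is recorded as an explicit bond; ring puckering is not
  sampled.

Clash screening: a conformation is rejected if any atom pair separated by
more than 3 bonds is closer than 0.5 × the sum of the van der Waals radii.
The criterion is deliberately permissive — it must only exclude genuine
atomic overlap, matching the feasibility of rejection sampling; acceptance
rates under the library are 0.5–0.9 depending on state. A configurable floor
(default 2%) turns a pathological acceptance rate into an error carrying the
rejection statistics.

Determinism: every stochastic operation takes an explicit seed; the pipeline
fans per-state seeds out of one config seed, and identical seeds reproduce
byte-identical manifests, CSVs and PDB files.

## Synthetic shielding surrogate

Running DFT shielding jobs on thousands of conformations is out of scope, so
the per-conformation shift is simulated with exactly the statistical
structure the Δ analysis relies on:

```
value = base(residue) + t(φ, ψ, χ1) + rotamer_offset + effect(state) + ε
```

- `t` is a smooth low-order periodic response
  (`A·[cos(φ−60°) + sin(ψ+45°) + ½cos(χ1)]`). Amplitude default
  A = 0.9 ppm gives the unmodified Δ distribution a standard deviation near
  1 ppm; published sources do not quantify conformational shift dispersion
  for these nuclei, so this width is a declared modeling assumption, chosen
  once. Because twins share torsions, `t` cancels exactly from every paired
  difference.
- `rotamer_offset` is a zero-sum per-rotamer shift from the calibration
  table; zero-sum means the state mean is carried entirely by `effect`.
  The lysine offsets are sized so the mean absolute per-rotamer deviation is
  1.3 ppm, the published average magnitude of the rotamer contribution.
- `effect` is the additive modification effect on the report nucleus. The
  four lysine entries (+1.5, −10.1, −19.1, −25.8 ppm) are anchored to
  published mean Δ values and marked `PUBLISHED` in
  `src/ptmdelta/data/calibration_default.json`. Arginine and glycan entries
  are `ILLUSTRATIVE`: their source distributions were published only as
  figures, so those defaults are plausible placements for exercising the
  pipeline, not reproductions. Users can override the table with their own
  JSON.
- `ε ~ Normal(0, 0.5 ppm)` i.i.d. per record — the simplest noise model
  consistent with treating the Δ distributions as approximately Gaussian.

The surrogate operates in shift space; conversions δ = σ_ref − σ (default
σ_ref = 170 ppm) provide parity with parsed shielding logs, and Δ computed
from shieldings is the negative of Δ computed from shifts. A parser for
quantum-chemistry text logs (per-atom isotropic shielding lines) and a
shielding-job input writer using the locally-dense basis scheme (default
6-311+G(2d,p) on the focus nucleus and its ≤1-bond neighbors, 3-21G
elsewhere; functional a free string defaulting to B98) let the same pipeline
consume real computations. What passing tests show, therefore, is that the
*statistical machinery* — pairing, rotamer averaging, Δ, KDE, the Bayesian
model — behaves correctly and recovers planted effects; they do not validate
any quantum-chemical prediction.

## Reference statistics

Experimental-style shift tables (CSV, or a minimal NMR-STAR v3
chemical-shift loop subset) are processed in a fixed order: restrict to
entries referenced to DSS, TMS or TSP → re-reference to DSS (+0.12 ppm TSP,
−1.7 ppm TMS) → remove Tukey-fence outliers (outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]) in a single pass → mean and sample sd (n−1).
Choices that the published procedure leaves open, fixed here for
determinism: quartiles use linear interpolation between order statistics
(type 7); fences are closed intervals (points exactly on a fence are kept);
groups smaller than 4 pass through unfiltered with a warning; fences are
applied per (residue, nucleus) group. The packaged synthetic table generator
emulates per-residue Gaussian shift distributions with a DSS/TMS/TSP/other
standards mixture (70/12/15/3%), values stored on each entry's own reference
scale, and ~2% gross outliers; it exists so tests never need a live
repository download.

## Δ statistics

Rotamer averaging happens in shift space, before Δ and before any density
estimate (shieldings are averaged over rotameric states, not densities):
the per-backbone value of an enumerated-rotamer state is the arithmetic mean
over its rotamers, and missing rotamers are an error. Δ subtracts the
unmodified-ensemble mean from every conformation of both sides, so the
unmodified Δ mean is exactly zero and a constant reference offset cancels
end to end. KDE uses a Gaussian kernel, Silverman bandwidth unless given,
512 grid points spanning the samples ± 4 bandwidths; the mode is the grid
argmax with ties broken toward smaller Δ. Pooling (e.g. condensing the Arg
mono-Nε/mono-Nη curves into one "mono-methylated" curve) concatenates
samples before re-estimating the density.

## Two-state Bayesian model

Δ samples of each state are modeled as Gaussian with unknown (μ, σ). Priors:
μ ~ Student-t(ν, loc = that state's empirical Δ mean, scale = 0.35 ppm); the
Student-t degrees of freedom ν get an Exponential hyper-prior with mean 30
(near-Gaussian unless the data argue otherwise); σ ~ Gamma moment-matched
(shape = (m/s)², rate = m/s²) to the experimental spread, with prior mean m
= the reference sd and prior sd s defaulting to m/2 (a weakly-informative
shape-4 Gamma; the published prescription fixes the center but not the
spread of this prior, and `sigma_prior_sd` overrides it). The 0.35 ppm scale
encodes that the computed Δ distributions track experiment within about
1 ppm. The source description is ambiguous about whether the Student-t is
the likelihood or the prior on the mean; this implementation uses a Gaussian
likelihood with the Student-t as the prior on μ, which matches the "two
possible Gaussian distributions" framing, and keeps the alternative
expressible by overriding the likelihood field (only "gaussian" is
implemented).

The two states are fitted independently (no shared parameters) by an
affine-invariant ensemble sampler (emcee) in (μ, log σ, log ν): 32 walkers,
1,000 warmup + 1,000 retained sweeps by default, deterministic under a
fixed seed. Because the Gaussian likelihood depends on the data only through
(n, ȳ, Σ(y−ȳ)²), the log posterior is evaluated from sufficient statistics.
Diagnostics: rank-normalized split-R̂ and effective sample size (arviz),
with walkers grouped into four pseudo-chains; R̂ > 1.05 warns, or errors in
strict mode.

Probability profiles evaluate, per retained draw k,
P_A(Δ) = π_A N(Δ|μ_A,σ_A) / (π_A N_A + π_B N_B) on a grid (state priors
default 0.5/0.5, configurable); the mean curve averages up to 500 evenly
thinned draw curves and the band is their 5th–95th percentile. Threshold
queries return the maximal grid intervals where the mean curve reaches a
level; classification of an observed shift re-references it to DSS,
subtracts the reference mean, and reads the profile at Δ_obs — refusing to
extrapolate outside the fitted grid. Profiles answer only pairwise
questions; discriminating several modifications is composed from pairwise
profiles.

## Problem sizes and numerical tolerances

The analysis scripts and the acceptance script use the study's native scale
(500 backbones per state; 5,000 Lys / 6,000 Arg conformations), which runs
in seconds per state. Unit tests use 10–40 backbones, sufficient for the
invariants they check. Stochastic recovery checks use 3–4 standard-error
bounds computed from paired per-backbone differences (the shared torsion
response cancels within a pair, so SE = sd(diff)/√n). Torsion round-trips
hold to 1e-3°, PDB coordinates to 1e-3 Å (format precision), KDE
normalization to 1e-3.

## Known limitations

- Geometry is idealized and heavy-atom only: no hydrogens, no relaxation,
  approximate chair glycans. Adequate for clash screening and torsion
  bookkeeping; not for energy or shielding computation.
- The torsion library and the surrogate's torsion response are synthetic
  stand-ins; conclusions about real spectra require replacing the surrogate
  with parsed shielding logs or measured shifts.
- Arginine/glycan calibration entries are illustrative, so the thresholds
  the pipeline prints for those states characterize the surrogate, not
  experiment.
- The asymmetric/symmetric di-methyl-arginine rotamer labels reproduce
  published conformer totals; where labels denote symmetric placements of a
  planar NMe₂ group they differ only in atom naming.
- The two-state model assumes exactly two candidate states; an observation
  from an unmodeled third state will still be assigned probabilities that
  sum to one over the two modeled states.
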