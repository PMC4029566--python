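# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Mass arithmetic and digestion (`masscalc`)

Peptide neutral masses are sums of residue masses plus one water, using
monoisotopic masses for peptide-level matching and average masses for intact
proteins (constants from pyteomics' standard amino-acid compositions; a TSV
override hook exists for non-standard tables). Two modifications are
modelled: carboxyamidomethylation of a free thiol by iodoacetamide
(+57.02146 Da monoisotopic, +57.0513 average) and the hydrogen lost by each
cysteine on disulfide formation, applied at 1.0078 Da per bonded cysteine on
*both* mass scales — one printed correction value is used for intact-mass
and fragment-mass matching alike, so sub-millidalton scale differences are
deliberately ignored.

In-silico digestion uses zero-width cleavage regexes (trypsin: after K/R not
before P; chymotrypsin: after F/Y/W/L not before P, the common
low-specificity-excluded convention; AspN: before D) via
`pyteomics.parser.icleave`. At zero missed cleavages the fragments tile the
sequence uniquely; with k missed cleavages all unions of ≤ k+1 adjacent
fragments are produced. Spans are 1-based inclusive, matching residue
numbering conventions in structural work.

Disulfide-linked species are connected components of the graph whose nodes
are peptides and edges are intact bonds; the species mass is the sum of
member peptide masses (each keeping its water) plus modification deltas over
the whole species. Species enumeration under missed cleavages considers
every tiling of the base fragments into runs of bounded length; inference
defaults to zero missed cleavages, where the tiling is unique.

## Connectivity inference (`ssbond`)

The search space is all perfect matchings over cysteine ordinals, (n−1)!!
patterns, enumerated recursively. Treatment semantics: `n_reduced` bonds
are cleaved in the partial-reduction species before alkylation; with `iaa`
their cysteines carry CAM, otherwise free thiols; with `dtt` all remaining
bonds are also cleaved and — following the stated treatment contract —
alkylation reaches every cysteine when both flags are set. Which bonds were
reduced is latent, so species are predicted for every subset of the stated
cardinality, mirroring how partial-reduction peaks are collected by count of
remaining disulfides without knowing their identity.

Matching is in parts-per-million on neutral mass (default tolerance 10 ppm,
instrument-grade and configurable; ties within tolerance are retained and
flagged ambiguous). Elimination semantics are deliberately conservative: an
observation contradicts a pattern only if no species under that pattern
explains it *and* at least one other candidate does explain it. This guards
against contaminant peaks eliminating everything; a strict mode (any
unexplained observation eliminates) is available by flag. Fragment-level
annotations ("Cys k alkylated" / "Cys k not alkylated") encode ion-series
evidence as constraints on the CAM status of one ordinal in any explaining
species — this is exactly the form of evidence that historically excluded
the 3–8/6–7 completion. The optional adjacency rule removes patterns
bonding cysteines whose sequence positions differ by ≤ 1 (configurable),
reflecting how rare disulfides between adjacent residues are.

The two-candidate endpoint in `scenario.py` is a synthetic reconstruction:
the published evidence exists only as bond-level assertions (the observed
masses are in a figure image), so a toy sequence is engineered in which
chymotrypsin isolates cysteines 1–5 in separate peptides and the 6-7-8
triplet (with the adjacent 6–7 doublet) in one peptide. The fixture is
labelled synthetic; it reproduces the logical structure of the deduction,
not its numerical masses.

The inference endpoint is deliberately MS-only: when two candidates remain,
the ambiguity is reported rather than resolved (historically the resolution
came from structure-calculation trials, which are out of scope here).

## Relaxation, spectral density and exchange (`nmr`)

Both R₁ and R₂ series are fitted with the same two-parameter
mono-exponential I(t) = I₀·e^(−Rt) by trust-region least squares with an
analytic Jacobian, initialised from a log-linear fit of the positive
intensities. The rate's standard deviation comes from the curvature
(inverse-Hessian) matrix scaled by residual variance, and the 95% interval
uses Student's t with n−2 degrees of freedom. Constant or non-decaying
series are flagged failures — never silently dropped. Empirical CI coverage
at signal-to-noise 50 on the standard 7-point delay grids (R₂: 10–210 ms,
R₁: 10–1000 ms) sits at the nominal level within binomial error.

Reduced spectral density mapping inverts

- R₁ = (d²/4)(3J(ω_N) + 7J(0.87ω_H)) + c²·J(ω_N)
- R₂ = (d²/8)(4J(0) + 3J(ω_N) + 13J(0.87ω_H)) + (c²/6)(4J(0) + 3J(ω_N)) + R_ex
- σ = (NOE−1)·R₁·γ_N/γ_H = (5d²/4)·J(0.87ω_H)

with d = μ₀ħγ_Hγ_N/(4π r³), r_NH = 1.02 Å, and c = ω_N·Δσ/√3,
Δσ = −160 ppm. All high-frequency dipolar terms are collapsed onto the
single effective frequency 0.87ω_H; the exact high-frequency convention of
the original mapping literature varies, and this standard reduced form is
adopted and used consistently in both the forward simulator and the
inversion — which is what makes the noiseless round trip exact to machine
precision. The default field is 18.8 T, parameterised as a 800.13 MHz
proton frequency (configurable). NOE = 1 forces J(0.87ω_H) = 0; a mapped J
below tolerance flags the residue rather than discarding it.

The per-residue exchange term R_ex is a labelled heuristic, not a
model-free fit: the excess of J(0) over a 10%-trimmed-mean baseline across
residues, converted to rate units via the J(0) coefficient in R₂. It
identifies µs–ms outliers; its absolute scale depends on the baseline
assumption that most residues are exchange-free.

H/D exchange uses the same decay fit (v = v₀·e^(−kt)); only peaks with at
least three time points are fitted, faster exchangers are classified
undetectable. The slow-exchanger screen uses a strict t½ > 2.5 h threshold
(boundary excluded, per "greater than"), and the hydrogen-bond candidate
search pairs each slow amide donor (amide H, or N as proxy when protons are
absent) with backbone carbonyl O atoms within 2.5 Å, excluding the donor's
own and preceding residue whose carbonyl is covalently held nearby.

## Sequence variability (`seqvar`)

Shannon entropy is computed in bits per column with gaps excluded from the
frequency vector and the gap fraction reported separately (variability
servers differ here; this choice keeps indel signal separable from
substitution signal). All-gap columns carry NaN rather than 0. The
"non-conserved" threshold for region summaries defaults to entropy > 0 (any
variation), configurable, since no canonical cutoff exists. Net charge
counts Lys/Arg (+1) against Asp/Glu (−1) with His configurable and counted
basic (+1) by default, matching the residue-class colouring convention used
in structure figures; no pH-dependent ionisation model is implied.
Inter-cysteine spacings are residues strictly between consecutive cysteines;
`spacing_stats` reports mean, SD and the fraction of sequences sharing the
modal value for a chosen gap, excluding (and counting) sequences that lack
the pair. The ProSite-subset motif scanner supports literals and x(min,max)
wildcards, compiles to a regex with per-wildcard capture groups (realized
lengths are exactly the inter-cysteine spacings), and is cross-checked in
the tests against an interval-DP oracle. The "finger 3" region is defined
as the residues strictly between the 5th and 6th cysteines of the
reference.

## Ensemble statistics (`ensemble`)

Superposition iterates: fit every model to the current mean over the atom
selection with a proper Kabsch rotation (SVD with reflection guard, via
`scipy.spatial.transform.Rotation.align_vectors`), recompute the mean,
repeat until the mean shifts < 1e-6 Å RMS; initialisation is model 1. The
backbone selection defaults to N, CA, C, O. RMSF is per residue over models
and selected atoms; RMSD-to-mean is per model with ensemble mean ± SD.
Multi-model PDB I/O goes through gemmi with altloc pruning; rosters must be
identical across models and mismatches are rejected with the first
differing atom. Disulfide Sγ–Sγ distances are checked against a
[1.8, 2.5] Å window.

## Synthetic generators (`synthetic`)

All generators draw from independent substreams of one master seed
(`SeedSequence([seed, stream_id])`) and always return ground truth.

- **Proteins**: 60 residues, 8 cysteines placed ≥ 2 apart (or with exactly
  one CC doublet on request), uniform non-cysteine background, random
  perfect matching as the hidden pattern.
- **MS observations**: predicted species masses under the true pattern for
  chymotrypsin and AspN at 0 and 1 bonds reduced (alkylated, no full
  reduction), with multiplicative Gaussian ppm noise (default 5 ppm against
  a 10 ppm match tolerance), Bernoulli peak dropout (default 20%) and
  optional contaminants uniform in log-mass. Species with CAM sites also
  emit fragment-level "Cys k alkylated" annotations, emulating ion-series
  confirmation of the alkylation site — without this, pairings internal to
  one peptide are mass-degenerate and the candidate set rarely collapses to
  one, which is precisely why the bench workflow needed MS/MS.
- **Dynamics**: observables computed from a Lipari–Szabo spectral density
  (defaults τ_m = 5 ns, τ_e = 50 ps, order parameters per residue) through
  the same reduced-form relations the mapping inverts; intensity series are
  unit-amplitude decays on the standard delay grids with additive Gaussian
  noise 1/SNR.
- **HDX**: v = e^(−kt) sampled hourly for 24 h; points below a detection
  floor (0.05) are unobserved, so fast exchangers naturally yield < 3
  points.
- **Alignments**: an invariant cysteine scaffold with the conserved
  9-residue first spacing, a hypervariable region between the 5th and 6th
  cysteines with per-row lengths drawn from {13..18} (realized directly as
  gap-padded alignment columns — alignment computation is out of scope) and
  elevated substitution probability (0.6 vs 0.05 background).
- **Ensembles**: a smooth random-walk backbone template (N, CA, C, O, Sγ on
  cysteines; bonded Sγ pairs placed at 2.02 Å), per-model chain-smoothed
  Gaussian residue displacements scaled per region, extra per-atom jitter on
  side-chain atoms, and a random rigid motion per model.

What passing tests on these fixtures show: the deduction logic, estimators
and statistics recover known ground truth under the stated noise models.
What they do not show: robustness to disulfide scrambling, non-specific
cleavage, isotope-envelope effects, peak overlap, anisotropic tumbling,
EX1/EX2 exchange regimes, phylogenetic correlation between sequences, or
physically realistic protein geometry — none of which the generators
attempt to emulate.

## Problem sizes

Default problem sizes were chosen at desk scale: 105-pattern search spaces,
100-replicate recovery sweeps, 500-fit coverage studies, 20-model
ensembles, 24-sequence alignments. The full test suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

- Elimination treats mass coincidences conservatively; with very wide
  tolerances or heavily populated spectra the candidate set degrades
  gracefully (grows) rather than mis-eliminating, but no probabilistic
  scoring of matches is attempted.
- The reduced-mapping constants (bond length, CSA, 0.87 factor) are fixed
  conventions; absolute J values shift slightly under other choices while
  orderings and round-trip behaviour do not.
- `species_mass` and the predictor assume complete, specific digestion
  within each missed-cleavage tiling; partial nonspecific cleavage is not
  modelled.
- Accession-linked records (database sequences, deposited ensembles) are
  consumed like any other FASTA/PDB input but are not fetched; all shipped
  fixtures are synthetic and labelled as such.
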