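# Methods

## Attack geometry and the NAC filter

A reactivation-competent pose is characterized in the shared docking frame
by two quantities measured against two receptor anchors — the catalytic
serine Oγ (residue 203 in human AChE, 198 in human BChE) and the phosphorus
of the organophosphate adduct:

* **attack distance d_OP** (Å). Two definitions are supported.
  `p_to_serO` (the default) is the P ↔ Oγ separation — the literal reading
  of the conventional symbol; note that with a serine-bound adduct this
  distance is a property of the receptor and identical for every pose.
  `oximeO_to_p` measures O_ox ↔ P, the distance the nucleophile must
  actually close, and is the pose-dependent quantity. The default is kept
  for fidelity to the conventional definition; analyses that need a
  per-pose distance (including every synthetic-data workflow here) should
  select `oximeO_to_p`.
* **attack angle θ_OPO** (degrees), the O_ox–P–O_Ser angle at the
  phosphorus, computed with a clamped arc-cosine so collinear arms cannot
  produce NaN; values lie in [0°, 180°].

A pose is a **near attack conformation** when all three hold:

1. it is *low-energy*: within `energy_window` kcal/mol of the ensemble
   minimum docking energy (default 5.0, a conventional docking-analysis
   window; sentinel `"all"` disables the filter — the cutoff is exposed
   precisely because no community consensus exists);
2. d_OP < `d_max` (default 10.00 Å, **strict** — the criterion is printed
   with "<");
3. θ_OPO within `theta_center ± theta_tol` (default 180° ± 60°,
   **inclusive** on both ends — a "±" tolerance reads as a closed
   interval, and a measured angle of exactly 120.0° is accepted).

For bis-oximes both oximate oxygens are measured and the pose is scored by
the oxygen maximizing θ among those passing the distance test (the
minimum-distance oxygen if none passes). A second oxime group can
therefore only add NAC opportunities, never remove them.

**%NAC** divides the NAC count by the low-energy pose count by default
(`denominator="low_energy"`); dividing by the full ensemble is selectable.
An empty denominator reports 0 with a warning rather than an error.

**Best pose** selection within the low-energy set is lexicographic:
minimal d_OP, then maximal θ_OPO, then minimal total energy — the ↓d/↑θ
ordering used in docking results tables. No weighting is attempted; the
rule is deterministic and documented rather than clever.

**Redocking validation** computes the RMSD between positionally paired
atoms with no superposition (docking output shares the receptor frame) and
no symmetry/automorphism search — a documented limitation acceptable for
redocking, where ligand topology and atom order are identical. Acceptance
is strict: RMSD < 2.0 Å.

## Reactivation arithmetic

Activities are OLS slopes of absorbance traces over a fixed, configurable
linear window (default: the full trace; no automatic curvature detection —
determinism is preferred over heuristics). Percent reactivation is

    %R = [1 − (a₀ − a_r)/(a₀ − a_i)] × 100,   a_r = a_r,raw − a_oximolysis

computed per replicate and summarized as mean ± sample SD (n−1). %R is
never clamped: noise legitimately produces values slightly below 0 or
above 100, and clamping would bias replicate means; out-of-range values
are flagged instead. The oximolysis control may be supplied per replicate
or shared across replicates. Inhibition timing uses pseudo-first-order
kinetics: k_obs is the negated slope of ln a(t)/a(0) vs t, T½ = ln 2 / k_obs,
and the incubation time for n half-lives is n·T½ with residual activity
2⁻ⁿ (n = 7 by default: a 2-hour incubation when T½ = 120/7 min, leaving
0.8 % residual activity). Units are minutes and mol/L throughout.

## Correlation

%NAC is paired with %R per oxime (by default the 100 µM column — the
higher-signal measurement) and fitted by OLS; association strength is
Pearson's r. Because n is typically 6, significance comes from a
permutation test on |r|: all n! pairings are enumerated exactly when
n! ≤ 5040 (deterministic, input-order independent), otherwise a seeded
Monte-Carlo sample of 10 000 permutations with the add-one correction.
Degenerate variance yields r = NaN (flagged) and p = 1.

## Synthetic data: what it emulates, and what it does not

The generators replace the docking engine and the bench assay, not the
analysis:

* **Pose ensembles** place the adduct P at the origin and serine Oγ 4 Å
  along +z, then embed each pose's oximate oxygen at a sampled
  (d, θ, azimuth) and complete a rigid 5-heavy-atom dummy ligand in a
  random orientation. Defaults emulate a typical docking run: 100 poses,
  d ~ U(3, 15) Å spanning the cutoff, θ ~ U(90°, 180°) spanning the angle
  bound, energies ~ N(−110, 5) kcal/mol. With `nac_fraction_target` set,
  draws are stratified so the realized NAC fraction equals
  round(target·n)/n exactly and energies are compressed inside the
  low-energy window (the energy filter then keeps every pose, so the
  target survives the full analysis chain). Because the per-pose distance
  distribution can only be carried by the nucleophile–phosphorus
  separation, generator ground truth is recorded under the
  `oximeO_to_p` definition and the generator returns those criteria
  alongside the ensemble.
* **Assay scenarios** encode a chosen true %R: a_i = 0.05·a₀ (inhibition
  to 5 % of original activity), a_r,raw chosen so the corrected formula
  evaluates to the target exactly, then independent multiplicative
  Gaussian noise (CV 2 % by default, consistent with the small replicate
  SDs of the bundled reference table) per condition and replicate, three
  replicates by default. Per-replicate child RNG streams mean extending
  the replicate count never perturbs earlier draws. The bundled 24-row
  reference table (six oximes × two enzymes × two concentrations) supplies
  the true %R values used across the tests. The first-order
  delta-method helper `replicate_pct_R_sd` propagates the noise model
  through the formula, giving the true replicate SD used for recovery
  tolerances (a 3-sample SD estimate is far too noisy to set a band).
* **Inhibition courses** are exponential decays with multiplicative noise;
  **redocking fixtures** are rigid translations (true RMSD = |shift|
  exactly) or coordinate jitter (realized RMSD recorded).

None of this is physically realistic chemistry: no conformer strain, no
force-field energies, no receptor flexibility, no correlated assay drift.
Passing tests therefore demonstrate that the *analysis* is correct and
unbiased under its stated noise model — not that any docking protocol or
bench assay is accurate.

## Numerical and design choices

* Boundary semantics are exact (no epsilon): strict distance, inclusive
  angle. Boundary unit tests feed numbers to the classifier directly,
  since reconstructing an angle of exactly 120° from Cartesian coordinates
  is not representable.
* Energy sidecar CSVs are read with the round-trip float parser so
  energies survive write/read bit-exactly.
* PDB parsing keeps altloc blank/"A", skips waters, and skips
  insertion-coded residues with a warning (determinism over coverage).
  Anchor selectors must resolve to exactly one atom; ambiguity is an
  error, not a guess.
* The exact permutation test is vectorized (permuting y preserves its mean
  and norm, so r reduces to one matrix product), keeping 720-permutation
  enumeration trivially cheap even inside simulation studies.
* Problem sizes in the test-suite simulation studies (200-pose ensembles,
  300-seed unbiasedness runs, 200-seed correlation recovery, 1000-rep
  permutation-uniformity check) were chosen as the smallest designs whose
  Monte-Carlo error is comfortably below the effects being verified.

## Known limitations

* No symmetry-aware RMSD; atom correspondence is positional.
* Interaction fingerprints (H-bond/π–π residue lists) are pass-through
  metadata, never computed.
* No reactivation rate-constant (k₂/IC₅₀) estimation — only fixed-time %R.
* The `p_to_serO` distance default is faithful to the conventional symbol
  but pose-invariant for covalent adducts; users wanting a discriminating
  distance must opt into `oximeO_to_p`.
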