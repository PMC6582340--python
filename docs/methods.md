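# Methods

## Scope and model structure

`searchkin` implements a mean-field kinetic theory of site-specific
DNA binding in three coupled layers:

1. **Facilitated diffusion.** A single protein searches M base pairs by
   rounds of 1D sliding (mean dwell τ_1D, scan length ⟨n⟩ = 2√(D_1D τ_1D))
   separated by 3D excursions of mean duration τ_3D, giving the mean
   search time τ_S = (M/⟨n⟩)(τ_1D + τ_3D).  Rounds are assumed
   uncorrelated (uniform re-landing), the target is a single site, and
   only means are computed — no first-passage distributions.
2. **Two-state recognition.** At the target the protein must switch from
   the search (S) to the recognition (R) conformation across a barrier
   ΔG‡.  Per visit this succeeds with P_f = k_SR/(k_SR + k_res); per
   round, with P_loc = min(1, ⟨n⟩·P_f), using the random-walk estimate
   that each covered site is revisited ~⟨n⟩ times during the ~⟨n⟩² steps
   of a round.  The total mean recognition time is τ_R = τ_S/P_loc.
3. **Frustration coupling.** Sliding roughness and the transition
   barrier are both controlled by the similarity index χ — the overlap
   between the positively charged sliding patch and the specific-contact
   patch: σ = χ·σ_max and ΔG‡ = ΔG_max(1 − χ).  Fast sliding and easy
   recognition therefore exclude each other, and τ_R(χ) generically has
   an interior minimum.

All energies (σ, E_ns, ΔG) are dimensionless multiples of k_BT;
temperature enters only through the hop time τ₀.  D_1D is carried in
bp²/s (the base pair is the lattice unit), with explicit converters to
m²/s via BP = 0.34 nm, so the residence law k_res = 4·D_1D and the
diffusion law never mix unit systems silently.  ⟨n⟩ is kept real-valued;
it enters only as a mean.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| T | temperature | 298 K | enters τ₀ only |
| η | viscosity | 1.0·10⁻³ Pa·s | water |
| R | protein radius | 3 nm | typical globular DBP |
| R_OC | protein–DNA axis offset | R | rotational drag arm |
| BP | rise per base pair | 0.34 nm | B-DNA |
| M | genome length | 5·10⁶ bp | bacterial scale |
| τ_3D | 3D excursion time | 0 s | see below |
| σ_max | roughness at full similarity | 5 k_BT | stability of the specific complex requires ≈5 k_BT |
| ΔG_max | barrier at zero similarity | required | system-specific; no defensible default |
| E_ns | non-specific binding energy | required | salt-dependent |
| a, r_c | χ decay constant, neighbor cutoff | 5, 8 Å | the χ landscape is smooth in both |

τ_3D has no canonical value in this theory; the default 0 gives the
pure-sliding bound and is used by the χ-scan presets.  The E_ns-scan
presets (`fig4a`, `fig4b`) instead use τ_3D = 4.7·10⁻⁵ s (≈ τ₀·e⁶),
chosen once so that the 1D/3D balance point τ_1D ≈ τ_3D falls mid-range
of the scanned E_ns: with τ_3D = 0 the round count costs nothing and the
low-E_ns rise of τ_R — the hallmark of an optimal 1D/3D mix — cannot
appear.  Every preset records the value it uses.

χ handling: the kinetic map is defined on χ ∈ [0, 1].  Structure-derived
χ may be negative (net-negative neighborhoods) and is reported as such by
the frustration module, but the kinetic model rejects negative values
with an explicit error; values above 1 are clamped to 1.  Exponents
beyond |700| raise a range error rather than returning inf.

`optimal_chi` does a grid search plus bounded golden-section refinement.
Exact ties are broken toward **larger** χ: ties arise only on plateaus
where P_loc has clamped at 1, and such a plateau always extends to
χ = 1, the low-frustration regime the plateau represents.  The result is
deterministic either way; this choice names the plateau by its
high-similarity end.

## Monte-Carlo oracle

The closed-form chain rests on order-of-magnitude arguments (rounds
~M/⟨n⟩, ~⟨n⟩ revisits per covered site).  The simulator replaces them
with an explicit process: an unbiased ±1 walk on a **ring** of M sites
(periodic, so no edge effects foreign to the theory), one step per
τ_res = 1/k_res; after each step the walker dissociates with probability
τ_res/τ_1D (geometric dwell with mean τ_1D) and re-lands uniformly after
τ_3D; every arrival at the target — by step or by landing — attempts the
S→R switch with probability P_f, matching the rate competition behind
Eq. P_f.  A trial ends at the first success; a zero switching
probability is rejected up front (no absorbing state).

The RNG is numba's Mersenne-Twister, seeded per run; draws occur in a
fixed order (direction, attempt-on-target, dissociation), so a fixed
seed reproduces the event sequence bit-for-bit across runs and
platforms.  The kernel also reports the step count of the final,
success-truncated round, so the dwell per *completed* round can be
estimated without truncation bias.

Agreement with the analytic τ_R is within a factor of 2 across the
tested (E_ns, χ) grid at M = 2000 — the expected accuracy of the scaling
estimates, and the tolerance the acceptance checks use.  Two systematic
effects partly cancel: the theory's ⟨n⟩ underestimates the true span of
a round (≈1.4√steps vs 2√(Dτ) with D = 1/4), while the ~⟨n⟩-revisits
argument overestimates per-round success.  Note that where P_loc < 1 and
τ_1D dominates, τ_R = M/(4 D_1D P_f) is *independent of E_ns*, so some
grid settings are exact theoretical ties; rank-order comparisons against
the simulator only carry information for strictly ordered pairs, and
simulated means of tied settings differ by their (real, E_ns-dependent)
finite-size corrections.

Problem sizes used by tests and the acceptance script — M = 2000,
10⁴ trials per setting, nine settings — keep the full grid at a few
minutes of one-CPU time while holding the standard error of each
simulated mean near 1 %.

## Structure pipeline

Reading (gemmi): residues classified by name (standard amino acids plus
a small modified-residue table mapped to parents, e.g. MSE→MET; DA/DC/
DG/DT/DU/DI and ribo variants as DNA); waters and other hetero residues
dropped (a warning for non-trivial ones); alternate locations resolved
to highest occupancy, ties to the first listed; first model by default.
NMR ensembles are not averaged.  Protonation is ignored.

Charges: integer point charges per residue — LYS/ARG +1, ASP/GLU −1,
everything else (including HIS) 0; an alternative `his+1` scheme
protonates histidine.  The scheme name travels with every result.

Specific contacts: the R-mode patch is taken from geometry, defaulting
to the hydrogen-bond-like criterion "any protein N/O atom within 3.5 Å
of an N/O atom of a DNA *base*" (backbone phosphates and sugars are the
non-specific interface).  No angle term — most crystal structures lack
hydrogens.  A looser `base-heavy` rule (any heavy-atom pair ≤ 4.5 Å to a
base atom) is selectable; by construction the polar rule's contact set
nests inside the heavy rule's.

χ evaluation: neighbors j are *protein* residues strictly within
r_c = 8 Å; r_ij is the minimum heavy-atom distance between residues
(selectable Cβ–Cβ alternative with CA fallback for glycine); the
residue's own charge is included at weight 1 by default (`include_self`)
— a charged specific-contact residue is itself part of the patch.  All
protein chains in the selection are pooled into one χ; for oligomers
this is a convention, not a law of nature, and per-chain runs are one
chain selection away.

Mutations are charge edits: the residue is renamed and its charge
reassigned under the active scheme, coordinates untouched — χ consumes
only charges and distances, so no side-chain rebuilding is needed, and
the wild-type geometry stays the common frame for Δχ.  By default the
wild-type contact set is pinned for the mutant so Δχ isolates the
electrostatic effect; re-detection on the mutant is a flag away
(relevant for mutations that create or destroy contacts themselves).

## Synthetic complexes

The toy complexes are idealized geometries, not stereochemically valid
structures; every consumer of them is distance-based.  They pin down the
calculator's behavior exactly: `arg-on-guanine` (one guanidinium–O6
contact inside an all-positive neighborhood, χ = 1 by normalization),
`symmetric-dipole` (a neutral contact flanked by a mirror-symmetric
+1/−1 pair, χ = 0 by antisymmetry), and `patch-overlap` (20 residues:
three contacts inside a five-lysine patch with an acidic rim, χ checked
against an independent brute-force all-pairs evaluation to 10⁻¹²).
Generation is deterministic (fixed seed for the filler-shell jitter) and
byte-stable, in both PDB and mmCIF with identical coordinates.

What the toys do *not* emulate: realistic DNA duplex geometry, side-chain
packing, solvent, partial charges, or conformational change.  Passing
tests on them validates the arithmetic and the conventions, not the
biological accuracy of χ for any real complex.  Reproduction of
published similarity indices requires the real PDB entries (3Q05, 4MZR,
1ECR, 1LMB); the corresponding test documents the expected values and
tolerances and runs whenever those files are present under `data/pdb/`,
scanning the convention grid (contact rule × distance convention ×
self-inclusion) and reporting the best match, since the printed values'
exact conventions are underdetermined.  Similarly, the published
χ–roughness correlation across nine measured proteins needs their
experimental D_1D values; the package covers the statistic itself with
synthetic perfect- and noisy-linkage records instead.

## Known limitations

- No roadblocks, crowding, protein concentration, DNA-sequence or
  DNA-geometry effects; σ is a Gaussian-disorder summary, not a
  sequence-resolved landscape.
- The S→R transition is modeled at the target only (the simulator
  attempts it only there); the theory's P_f is a per-visit probability,
  not a spatially resolved rate field.
- Mean-time theory only; the simulator produces empirical distributions
  but no distribution theory is implemented.
- Association-rate *predictions* from Δχ are out of scope; the package
  reports directions and correlations.
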