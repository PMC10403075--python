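# Methods

This note records the models implemented in staplekit, the assumptions
behind them, the parameters that matter, and the design choices made
where the design was genuinely open.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Peptide model and sequence dialect

A peptide is an ordered list of residues drawn from a registry covering
the 20 proteinogenic amino acids plus seven non-naturals used in stapled
apolipoprotein mimetics: the olefin-arm residues R8, S5, S8 (one arm
each) and B5 (two arms, the stitch hub), norleucine (Nle), sarcosine
(Sar, N-methyl-glycine) and α-aminoisobutyric acid (Aib).  Staples are
(i, j) records with j−i ∈ {4, 7} (one or two helical turns); a stitched
peptide is two staples sharing a B5 hub, and its mass bookkeeping counts
two ethene losses, one per ring-closing metathesis.  Masses are computed
from residue elemental formulas: Σ residues + H₂O + cap deltas
(acetyl +C₂H₂O, octanoyl +C₈H₁₄O, amide −OH+NH₂) − C₂H₄ per closed
staple, with +CH₂ for a post-hoc N-methylation of a residue whose
registered formula is not already N-methylated.

No community standard encodes stapled peptides, so the package defines a
one-line dialect (uppercase = L, lowercase = D, `{Token}` for
non-naturals, `Ac-`/`Oct-` prefixes, `-NH2` suffix, `|i-j` staples).
Parsing and writing are exact inverses; this is property-tested.
Positions are 1-based everywhere.

Stereochemistry bookkeeping: Gly, Aib, Sar and B5 are achiral; the
R/S configuration of the α,α-disubstituted arm residues is carried by the
residue code itself (R8 vs S5/S8) rather than the per-position L/D flag,
which is reserved for proteinogenic-style chirality.  Consequently
`stereo_flip` is rejected on all of them.

### Packaged study peptides

The activation-helix scaffold is ApoC2 mature-chain 59–79,
`AMSTYTGIFTDQVLSVLKGEE`.  The stapled mimetics are derived from it by
explicit modification lists (Met2→Nle, staple 3–10, Gly19→Sar, terminal
D-Glu pair, N-acetyl for the single-staple 21-mer; B5 hub at 10 with a
second span 10–17 for the stitched form; octanoyl cap plus Ala1→Aib for
its acylated analogue).

The bi-helical 41-mer predecessor (D6PV) was never published as a full
sequence.  The packaged fixture is a **synthetic reconstruction**
(flagged as such in `catalog.py`) constrained by every described
property: 41 residues; a first helix (positions 1–20) containing the
potentially immunogenic stretch KEVFEKLRDLY at positions 4–14 with Glu at
position 8 (the residue deleted to produce the "damaged" first helix) and
a junction Pro at position 20; a second helix (21–41) identical to ApoC2
59–79.  Dropping the 7 N-terminal residues and the junction Pro yields
the 33-mer design scaffold on which all reported staple placements —
(3,10), (11,18), (14,18), (15,22) — land consistently, with (15,22)
mapping onto (3,10) of the 21-mer.  Conclusions drawn from this fixture
are about the reconstruction, not the original molecule.

## Helical-wheel geometry

The wheel uses the ideal α-helix twist of 100°/residue (no 3₁₀/π
options): θₙ = ((n−1)·100°) mod 360°.  The hydrophobic moment is the
complex sum μ = Σ hₙ·e^{iθₙ} over a residue window; hydrophobicities hₙ
come from the Eisenberg consensus scale.  The olefin-arm residues are
assigned the Leu value (aliphatic chains sitting on the hydrophobic
face), Nle likewise, Sar the Gly value, Aib the Ala value.  The
hydrophobic face is the set of positions within ±90° (configurable) of
the moment direction; a face is undefined (error) when |μ| falls below a
configurable floor (default 1e-6, i.e. only genuinely zero moments are
rejected).

Staple-site proposal enumerates (i, i+4) or (i, i+7) pairs with both
arms inside the face and ranks them by the summed hydrophobicity of the
displaced residues, least hydrophobic first — displacing polar residues
costs the amphipathic design least.  One known limitation: a
helix-stabilizing staple deliberately placed across a Gly near the polar
face (the (15,22) placement above) is *not* produced by this face-based
heuristic; such placements answer a different design question (helicity
rescue) than face-packing and must be specified manually.

Variant arrays: the Ala scan substitutes every non-Ala, non-arm position
in the window one at a time; the quadruple-Ala design replaces the four
LPL-activation residues Y5, I8, D11, Q12 (window-relative); the damaged
first helix deletes the window's E8, re-indexing all downstream residues
on the wheel — the mechanism by which a single deletion roughly halves a
designed amphipathic moment.

## Antigenic-segment scan

The Kolaskar–Tongaonkar (1990) propensity table is embedded verbatim and
version-tagged.  The scan averages propensities over each 7-mer window,
assigns the mean to the centre residue (scores exist for positions
4…L−3) and reports maximal runs of scores strictly above the threshold
(default 1.0) at least 8 residues long.  The original method's
renormalization — thresholding at the whole-sequence mean when that mean
is below 1 — is available behind `renormalize=True` but off by default;
with the default plain >1 threshold the packaged 41-mer fixture yields a
segment spanning positions 4–18 (overlapping KEVFEKLRDLY) while the
native counterpart of its first helix yields none, so the default mode
is the one that reproduces that qualitative call.  Non-natural residues
are mapped to natural surrogates before scanning (Nle→L, Sar→G, Aib→A,
arms→A, D→L-equivalent) and every mapping is recorded in the scan
provenance, because the propensity table only covers the 20 naturals.

## Proteolysis rule engine

Deterministic, kinetics-free.  Endoprotease rules name P1 sets and an
active pH interval: trypsin {K, R} (pH 6–10; the scaffold peptides
contain no free Arg, but the canonical P1 set is kept), pepsin
{F, L, W, Y} as a minimal broad-specificity aromatic/aliphatic set
(pH 1–4), proteinase K {A, V, L, I, F, W, Y} (pH 4–12).  A candidate
bond b (P1 = residue b, P1′ = residue b+1) is *protected* when any
blocker fires:

* staple span: bonds with P1 ∈ [i, j−1] for a staple (i, j) — the amides
  inside the macrocycle;
* N-methylated P1′ (sarcosine rule);
* α,α-disubstituted P1′ (Aib or an olefin-arm residue): a steric block
  of the scissile amide.  Besides being chemically standard, this makes
  protection monotone: when a staple arm displaces a residue that was
  itself a blocker for the preceding bond (a Pro or a D-residue), the
  arm re-blocks that bond, so adding any protection can never increase
  the susceptible-site count (property-tested over 1000 random triples);
* D-residue at P1 or P1′ (stereospecificity);
* Pro at P1′.

Exopeptidase rules report terminal vulnerability only: an aminopeptidase
needs a free, non-D N-terminus; a carboxypeptidase needs a free-acid
C-terminus whose last two residues are not both D.  Whether helix
propagation beyond the staple should widen the protected window is left
out: the lone Lys outside the stapled region is protected in the model
only via the explicit N-methyl rule.

## Trilayer trajectory statistics

Frames hold typed atoms (classes PL, TO, peptide, ion, water; roles
phosphorus, Cα, donor H with its heavy parent, acceptor) in an
orthorhombic box; all pair geometry uses the minimum image in all three
axes.  Frame weighting is uniform; no equilibration discard by default
(`--skip-frames` on the CLI).

**Leaflets.**  Phosphorus atoms are split about the midpoint of their z
range; each leaflet plane is the mean phosphorus z of its side, and a
peptide joins the leaflet whose plane is nearest its mean Cα z.
Coincident planes raise a degenerate-geometry error.

**Insertion depth.**  Per residue, the frame-average of the signed
Cα-to-plane z displacement, with negative pointing toward the TO core
(so the sign flips between leaflets).  Reported per (leaflet, residue)
with SD.

**Hydrogen bonds.**  A donor–acceptor pair is bonded iff
r(D, A) ≤ r_max0 − curvature·θ², with θ the angular deviation of the
donor H from the D→A axis; defaults r_max0 = 0.33 nm,
curvature = 0.00044 nm/deg² (the Wernet–Nilsson cone).  Donors are the
peptide amide/side-chain hydrogens with their heavy parents; acceptors
are the six TO ester oxygens (TO has no donors).  Counts are reported
per (leaflet, frame); `percent_bonded` — the percentage of frames with
at least one bond — is pooled across leaflets, since per-leaflet
pooling conventions in published occupancy figures are rarely stated.

**Coordination.**  The switching term (1−(r/r₀)⁶)/(1−(r/r₀)¹²) with
r₀ = 0.4 nm is evaluated in the equivalent form 1/(1+(r/r₀)⁶), which is
continuous through r = r₀ with value 0.5, strictly decreasing, and in
(0, 1].  The statistic is residue-wise: for each peptide residue the sum
over (residue atom, TO atom) pairs, maximized over TO molecules and
averaged over frames.  A stated ambiguity — "all peptide atoms" vs a
residue-wise output — is resolved residue-wise because the output is
per-residue; a whole-peptide mode (sum over all residues) backs the TO
contact count, which thresholds the whole-peptide coordination per TO
molecule (default threshold 0.5) and averages the count over frames.

**I/O.**  Trajectories read and write as multi-model PDB through
biotite (coordinates nm↔Å), with molecule classes inferred from residue
names via a configurable map and roles from atom names.  PDB's 0.001 Å
coordinate quantization bounds file round-trip error at 1e-4 nm.

## Synthetic trilayer generator

The generator emulates only the geometric relations the analyses read;
it has no energies, no dynamics, and is not a substitute for simulation.
Defaults: 40 PL per leaflet and 32 TO — a quarter of the reference
trilayer composition (160 POPC / 128 TO) — in a 6×6×14 nm box with
leaflet planes at ±2 nm, chosen to keep test trajectories fast while
preserving realistic areal density; phosphorus z jitter SD 0.02 nm; a
21-residue stapled peptide at planted depth −0.5 nm in the upper
leaflet; 2 planted TO contacts; hydrogen-bond fraction 0.105 per frame.

Placement rules and their guarantees:

* PL heads on a per-leaflet grid with small xy jitter and Gaussian z
  jitter about the plane, so the estimated plane deviates from nominal
  with SE = jitter_sd/√(n_PL·n_frames); the depth-recovery tolerance in
  the noisy tests derives from exactly this.
* The peptide backbone comes from `ideal_helix_coords` (0.15 nm rise,
  100° twist, 0.23 nm radius, ≈0.38 nm Cα spacing, optional kink at a
  named residue).  By default the frame placement flattens the helix z
  to the planted depth so every residue's planted depth is exact;
  `flatten_depth=False` keeps true helical z at the cost of a ±radius
  spread.  Noise-free recovery is therefore exact by construction, and
  the tests require <0.005 nm.
* Contact TO molecules hang below anchor residues with tail carbons
  ~0.30 nm from a Cα (whole-peptide coordination well above the 0.5
  contact threshold) while their ester oxygens stay ≥0.55 nm below the
  Cα, hence ≥0.7 nm from the amide donors — they can never register as
  hydrogen bonds.  Background TO molecules are rejection-sampled in the
  core slab at ≥1.5 nm from every peptide atom, keeping their
  whole-peptide coordination far below threshold; placement failure
  raises an overfilled-box error.  Planted contact counts are therefore
  recovered *exactly*.
* Per frame, a Bernoulli(hbond_fraction) draw — the first draw of the
  frame's RNG stream, so the sidecar can replay it — decides whether one
  ester oxygen of the first contact TO is moved into ideal bond geometry
  (collinear N–H…O at 0.29 nm, θ = 0).  On non-bonded frames every
  acceptor is ≥0.45 nm from every donor, so the analysis indicator
  equals the planted outcome frame by frame and `percent_bonded` equals
  the realized Bernoulli fraction exactly; the realized fraction differs
  from the planted probability by binomial sampling error only.
  Planting requires at least one contact TO (validated), since the
  bonded acceptor belongs to it.
* All randomness is seeded per (seed, frame index); identical configs
  give byte-identical PDB output (hash-tested).

Because the generator plants geometry directly, passing recovery tests
demonstrates the correctness of the measurement operators — not that
real trajectories resemble the synthetic ones.  Real systems add
correlated frames, conformational flexibility, wrapped coordinates and
donor/acceptor chemistry the reduced atom set does not carry.

## Assay post-processing

AUC is the trapezoid rule over the observed interval (strictly
increasing times enforced).  Dose–response uses the 2-parameter
saturation hyperbola V = Vmax·d/(EC50+d), least-squares via
`scipy.optimize.curve_fit` with EC50 bounded positive; an optional fixed
baseline adds a third parameter, and a 4-parameter logistic is
deliberately not the default since saturation behaviour is the modelled
regime.  Flat or monotone-decreasing responses return a degenerate,
non-converged fit rather than forced parameters.  EC50 is exactly
scale-equivariant in dose (tested).  Percent-baseline divides each
subject's series by its t=0 value (×100) and reports group mean ± SD
(ddof=1) across subjects; group-comparison statistics (ANOVA etc.) are
intentionally out of scope — the module emits tidy arrays/CSV for any
stats package.

## Problem sizes

Test and acceptance runs use deliberately small systems: 100–110
randomized frames for oracle-equivalence checks, 2000 frames of a
4-PL/1-TO system for the binomial hydrogen-bond recovery, 20 noise-free
and 200 noisy frames for depth recovery, and 1000 random triples for the
monotone-protection law.  These sizes make every check exact or
statistically sharp (3σ) while keeping the whole suite in seconds.
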