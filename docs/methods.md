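# Methods

This note records the models, conventions and numerical choices behind
`p450fx`, and what its synthetic validation does and does not establish
about real data.

## The electron-transfer ruler

Nonadiabatic electron tunneling through protein falls off approximately
exponentially with donor–acceptor distance. The package implements the
empirical Moser–Dutton form

    log10 k_et = C − β₁₀ (R − R₀) − γ (ΔG + λ)² / λ

with defaults C = 13 (log₁₀ of the rate at van der Waals contact),
R₀ = 3.6 Å (contact distance), β₁₀ = 0.6 Å⁻¹ (tunneling decay through the
insulating medium), γ = 3.1 (room-temperature Franck–Condon coefficient),
ΔG = 0 eV and λ = 1.0 eV. All six constants live in `RulerParameters` and
are overridable; λ ≤ 0 is rejected. The ruler is an interpolation for
R ≥ R₀: sub-contact distances return the contact rate with a
`clamped_to_contact` flag rather than extrapolating upward, because the
linear-in-R form has no physical meaning below van der Waals contact.
Verified properties: strict monotone decrease in R, and a maximum over ΔG
at the activationless point ΔG = −λ.

**Which distance feeds the ruler.** For a heme/[2Fe-2S] pair the donor
distance is taken to the *nearer* cluster iron (conventionally Fe1, the
iron closest to the protein surface on the acceptor side). Reports also
carry the mean over both irons because decoy filtering (below) is
conventionally expressed as a cluster-average distance.

## Affinity conversion

Binding free energies and dissociation constants interconvert as
K_d = exp(ΔG / RT) with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ and K_d in
mol/L, i.e. ΔG = RT ln K_d on this sign convention: a favourable
(negative) ΔG of binding gives K_d < 1 M. Temperature defaults to
298.15 K and is exposed, since published ΔG→K_d pairings rarely state it;
converting printed (2-decimal) ΔG values back to K_d reproduces published
nanomolar values to within ~10%, which is the rounding noise of the
printed free energies. The two directions are exact algebraic inverses.

## Geometry layer

* **Superposition** is Kabsch via SVD with the determinant correction, so
  the returned rotation is always proper (det = +1). Inputs with fewer
  than 3 pairs, or effectively collinear inputs (second singular value
  < 1e−8), are rejected. Rotation angles are extracted as
  arccos((trace R − 1)/2).
* **Residue pairing** for RMSD is either `same_numbering` (optionally
  offset) or `sequence_alignment` — global alignment with match +1,
  mismatch 0, gap −1 (Biopython `PairwiseAligner`), keeping non-gap
  columns. This is a deliberate, documented substitute for
  secondary-structure-matching pairings used by crystallographic software:
  cross-ortholog RMSDs computed here can differ from published values by a
  few tenths of an Å purely through pairing differences, so same-protein
  comparisons are the testable ones.
* **Heme plane**: total-least-squares plane through the four pyrrole
  nitrogens plus the four meso carbons when present (fallback: the four
  nitrogens). Robust to porphyrin naming variants; real porphyrin cores
  fit with residuals well under 0.3 Å.
* **Elevation angle** of a point above a plane is signed,
  arcsin(v̂ · n̂) ∈ [−90°, +90°], with the normal oriented toward a caller
  -supplied reference (for hemes, the proximal side); a point coincident
  with the plane centroid has no defined angle and raises. Published
  figures usually print unsigned angles; the CLI reports |angle| alongside
  the sign.
* **Minimum heavy-atom distance** uses an exact KD-tree nearest-neighbour
  query and returns the achieving atom pair; hydrogens are excluded unless
  requested.
* **Segment displacement** superposes structure B onto A using a core
  pairing that excludes the segment of interest (the function strips it if
  supplied), then reports per-residue Cα shifts over the segment and the
  angle of the segment's own best-fit rotation. This mirrors how
  domain/arm movements are quoted in the literature ("x Å movement, ~y°
  rotation").

## Ensemble analyses

**Decoy post-processing.** `rank_top_fraction` keeps the best
ceil(f·n) poses by ascending interface score with stable tie-breaking;
`filter_by_mean_fe_distance` applies a *strict* `< cutoff` test on the
heme-Fe→cluster mean distance (the boundary pose at exactly the cutoff is
dropped). Both return sub-ensembles preserving order, so a brute-force
recount is a direct oracle. The composed workflow reports the tunneling
rate range as the ruler evaluated at the retained minimum and maximum Fe1
distances.

**Occupancy.** An interaction criterion holds in a frame when the minimum
donor–acceptor heavy-atom distance is ≤ cutoff (defaults: 3.5 Å H-bond,
4.0 Å salt bridge, 4.5 Å contact — field-standard values, all exposed);
for H-bonds a D–H…A angle ≥ 120° is additionally required when hydrogens
exist in the model. Boundary distances count as satisfied. "Open" salt
bridges are the negation of the closed criterion, and reports carry both
fractions so an x%-open statement is unambiguous. The standard error
comes from block averaging over contiguous blocks (library default 5); in
validation gates that compare single runs against programmed truth at
±3 SE we estimate the SE with 20 blocks instead, because a 5-block SE has
only 4 degrees of freedom and its own sampling noise would dominate such
a gate — block length (100 frames) still exceeds the synthetic chain's
~9-frame correlation time by an order of magnitude.

**Geometry series.** Per-frame Fe1 distance/elevation (Fe1 identity fixed
from the first frame) plus the same measures for an optional reference
atom. A series is flagged "converged" when the last-quartile standard
deviation of the Fe1 distance is below 0.5 Å (default) — a deliberately
blunt single-number summary, not a substitute for autocorrelation
analysis, which is out of scope.

**Path contiguity.** An ordered relay of selections (cluster iron →
ligating/bridging residues → axial cysteine → heme iron) is "contiguous"
in a frame when every consecutive pair is within a hop cutoff, default
4.5 Å (van der Waals contact range between heavy atoms). The statistic is
the contiguous-frame fraction.

## Active-site characterization

**Lining residues**: protein residues with any heavy atom within a cutoff
(default 4.5 Å, a typical operationalization of "van der Waals distance")
of the probe selection; waters, heme and bound sterols are never listed.
Published residue counts are cutoff-dependent, so they should be treated
as ±few-residue references, not exact targets.

**Cavity volume** is a probe-excluded flood fill: grid nodes (default
spacing 0.5 Å) farther than the probe radius (default 1.4 Å) from every
wall heavy atom are open; the cavity is the 6-connected open component
containing the seed, and its volume is n·spacing³. Heme, bound ligands
and waters are removed from the walls so the space they occupy counts as
cavity. A fill that reaches the bounding-box edge flags the cavity as
open and still reports the enclosed component. This estimator is simpler
than probe-rolled-surface volumes computed by dedicated crystallographic
cavity software and will not match them exactly; it converges under grid
refinement (< 5% change on halving the default spacing) and recovers an
analytic sphere to a few percent. It is monotone non-increasing in probe
radius.

## Structure model and I/O

Parsing goes through gemmi (PDB and mmCIF; format auto-detected or
forced). Alternate locations collapse to the highest-occupancy conformer
per atom name — all geometric measurements assume a single conformer.
Coordinates are used in the file's orthogonal Å frame; no symmetry
expansion is performed, since all supported measurements are
intra-asymmetric-unit. Multi-model PDB is the only ensemble interchange
format (no binary trajectory formats); the writer enforces a shared atom
roster across models and round-trips coordinates at the format's
3-decimal precision. Cofactor detection is name-driven
(HEM/HEB/HEC → heme with atom FE; FES/FS2 → [2Fe-2S] with FE1/FE2;
common sterol codes → substrate) and configurable. When a model holds
several hemes (multiple copies in an asymmetric unit), the caller must
name a chain; the cluster and substrate associated with that heme are the
nearest ones by distance. Absent cofactors yield empty fields; only a
missing heme is an error. The sterol 14α-methyl carbon can be named
explicitly in the naming config; otherwise it falls back to the substrate
carbon nearest the heme iron, which in a catalytically posed sterol is
the 14α-methyl.

## Synthetic data: what it emulates, and what it does not

The generators provide the three data classes the pipeline consumes but
which original studies rarely deposit: docking decoys, MD snapshot
trajectories and a reference complex.

* The **toy complex** is built for exactness: an exactly planar porphyrin
  core with the iron at its centroid (plane residual 0, and an exercised
  undefined-elevation path), a [2Fe-2S] pair 2.7 Å apart with Fe1 exactly
  15.0 Å from the heme iron, a 2.8 Å Glu178–His259 donor/acceptor pair,
  a sterol stand-in whose nearest carbon is 4.1 Å above the iron, and a
  contiguous five-station electron relay.
* **Pose ensembles** place the ligand chain rigidly at
  N(μ, σ) Fe1 distances (defaults μ = 16 Å, σ = 1.5 Å, truncated above
  van der Waals contact; n = 3000 poses — the scale of a docking decoy
  analysis) along uniformly random directions with uniformly random
  orientations (normalized 4-normal quaternions). Orientations that would
  put the second iron nearer the heme than Fe1 are rejected, so the
  logged Fe1 distance is exactly the measured minimum distance. Scores are
  offset + 5·distance + N(0, 4) — distance-correlated with noise, in a
  negative interface-energy-like range.
* **Two-state trajectories** drive the Glu178–His259 pair with a hidden
  two-state Markov chain. Transition probabilities are derived from the
  open fraction p and a persistence knob ρ (the stationary frame-weighted
  stay probability): with c = (1−ρ)/(2p(1−p)), P(open→closed) = c(1−p)
  and P(closed→open) = c·p, which leaves the stationary open fraction
  exactly p. Defaults: 2000 frames, ρ = 0.9, emission means 2.8 Å
  (closed, σ 0.2) and 6.0 Å (open, σ 0.5) — chosen so the default 4.0 Å
  salt-bridge cutoff separates the states with negligible overlap and the
  logged state sequence predicts per-frame criterion outcomes exactly.

Every generator is bit-deterministic for one integer seed (numpy PCG64)
and logs its ground truth; stochastic estimators are always validated as
estimate-versus-log. What passing these tests shows is that the
estimators are correct on data whose generating process is known. What
they cannot show: real docking decoys have correlated, physics-shaped
score/geometry distributions rather than Gaussians; real MD frames carry
slow collective motions, many interacting contacts and hydrogen-atom
geometry; real structures have naming quirks, partial occupancy and
missing atoms beyond the altloc handling implemented here. Measurements
against deposited crystal structures are therefore kept as separate
tests that run whenever the coordinate files are present under
`data/structures/` (see `scripts/fetch_structures.py`).

## Problem sizes and reproducibility

Validation runs use 3000-pose ensembles, 2000-frame trajectories
(20 seeds per recovery check), 50–400-frame fixtures for unit tests, and
a 0.5 Å grid for cavity work — sizes at which every check completes on a
single CPU in seconds to a couple of minutes. `scripts/acceptance.py`
regenerates everything from one `--seed` and writes all headline numbers
as JSON; re-running any workflow with the same config, inputs and seed
reproduces byte-identical reports (sorted-key JSON, fixed float
formatting).

## Known limitations

* No quantum pathway/superexchange calculations; the ruler's constants
  are temperature-fixed.
* No secondary-structure-based pairing or iterative superposition
  trimming; published RMSDs computed with SSM pairings are approximate
  references here.
* No symmetry-mate generation, assembly building, or hydrogen placement;
  H-bond angle tests apply only when the input already has hydrogens.
* The cavity estimator is not a replacement for probe-rolled-surface
  volumes; absolute volumes carry estimator-definition differences of
  order 10–20%.
* Block averaging is the only correlation handling for occupancy errors;
  no autocorrelation-time estimation.
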