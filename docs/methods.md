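# Methods

This note documents the models, numerical choices and limitations behind
each stage of the design funnel. Units are Å, degrees, kcal/mol, mM and
seconds unless stated.

## Active-site model

The catalytic motif is the acylation machinery of serine hydrolases applied
to MHET: the Ser nucleophile attacks the ester carbon, His deprotonates the
Ser hydroxyl (with Asp/Glu orienting and polarising His), and the resulting
tetrahedral oxyanion is stabilised by two backbone N–H donors; an auxiliary
Ser/Thr hydroxyl binds the substrate's terminal carboxylate. The shipped
model (`data/mhet_active_site.yaml`) declares six roles and eight distance
constraints. The windows encode canonical serine-hydrolase geometry:
hydrogen-bonding heavy-atom separations 2.6–3.5 Å (2.5–3.5 for the
carboxylate contact, 2.6–4.0 for the His–leaving-group contact), and a
nucleophile-oxygen-to-sp³-carbon distance of 2.0–3.0 Å. Every number is
config-overridable; the machinery is independent of the specific table.

The transition state is a heavy-atom model of the first tetrahedral
intermediate (TI1) of MHET: an sp³ carbon C1 bonded to the oxyanion O1, the
glycol ester oxygen O2, the aromatic ring, and a marker atom ON standing at
the position the serine Oγ occupies in the intermediate. ON gives the
matcher an attack *direction* without needing an angle constraint; it is
excluded from clash tests. Three rotatable torsions (ring twist, carboxylate
rotation, glycol tail) define the conformer space. Atom "charges" are
charge-like weights for the screened-Coulomb term, not force-field charges.

**Penalty.** For each constraint with measured value g and window
[lo, hi], the excess is the distance of g outside the window (0 inside) and
the penalty is Σ w·excess². A quadratic out-of-window form is smooth,
standard in geometric matching, and makes "penalty = 0 iff all constraints
satisfied" exact rather than approximate. Angle/dihedral constraints use
squared degrees, so their weights should be ~10⁻²–10⁻³ relative to distance
weights; the shipped default uses distances only.

## Matching

Triad candidates follow type-matched anchoring: the nucleophile only at
native Ser, the base only at native His, the acid at native Asp or Glu.
Oxyanion donors may be any non-proline residue (backbone N is the donor);
the carboxylate binder any Ser/Thr. For each enumerated triad triple the TS
is placed by a coarse scan — 40 Fibonacci-sphere attack directions × 12
spins about the attack axis, with C1 at the target attack distance from the
Ser Oγ and ON aligned to it — followed by Powell rigid-body minimisation of
the penalty from the best 5 starts (two rounds, with one re-selection of the
completion roles between them). Completion roles (donors, binder) are chosen
deterministically per pose: the candidate minimising its constraint excess,
ties by |value − target| then by position. The pose search is skipped when
the pose-independent part of the penalty (the triad-internal distances,
fixed once the triple is chosen) already exceeds the reporting cutoff
(default 5.0) — a sound pruning, since that part lower-bounds any pose.

Torsional freedom of the TS is deliberately not explored during matching:
the matcher uses the reference conformer for feasibility, and conformational
freedom is handled by the conformer-library stage. Likewise the catalytic
side chains use their native (crystal) conformations; matching asks whether
the scaffold can host the site as built, which is also what the
triad-RMSD-vs-native diagnostic measures.

By default the whole chain is searched. Pocket restriction
(`MatchConfig.restrict_to_pockets`) is intended for large scaffolds; small
fixtures must be searched exhaustively or the matcher could not be compared
against full enumeration.

**Pocket detection** is a grid method (1.0 Å spacing): cells within 2.2 Å of
a heavy atom are protein; an empty near-surface cell is a pocket cell when
at least 68% of 14 rays (axes + body diagonals, 12 Å range) hit protein.
Pocket cells are clustered by 6-connectivity, ranked by cell count ×
spacing³, and report up to 100 lining residues (any atom within 4.5 Å of a
pocket cell). The parameters are tuned for the synthetic shell fixtures and
exposed as arguments; the contract that matters downstream is "the three
largest pockets, ≤ 100 positions each".

## TS conformer library

Rotatable torsions are enumerated on uniform grids (steps per torsion are
parameters; the default is 6), optionally combined with seeded rigid-body
jitter (σ = 0.25 Å translation, 5° rotation). Candidates must pass every
placing rule — the shipped rule rejects any TS heavy atom within 0.8 × the
vdW-radius sum of a scaffold heavy atom, with the nucleophile side chain
(the covalent partner) and ON exempt — and have penalty ≤ 5.0 against the
matched site. Deduplication keeps, per 0.3 Å heavy-atom-RMSD cluster, the
lowest-penalty pose (ties by torsion vector, then jitter index); because
candidates are sorted canonically before the greedy pass, the result is
independent of enumeration order. An empty library carries a per-rule
rejection histogram for diagnosis.

## Design energy model

The energy is a deliberately simple, fully documented surrogate with the
pairwise decomposition the search machinery needs:

* Lennard-Jones 12-6, E = 4ε[(σ/r)¹² − (σ/r)⁶] with ε = 0.15 and
  σ = (rᵢ+rⱼ)·2^(−1/6) from vdW radii (C 1.70, N 1.55, O 1.52, S 1.80),
  heavy atoms only;
* screened Coulomb 332·qᵢqⱼ/(4r·r) (distance-dependent dielectric ε(r)=4r)
  over charge-like weights on polar atoms;
* a geometric hydrogen-bond bonus of −2.0 per bond passing the strict
  distance/angle test (hydroxyl hydrogens are explicit; N–H donors without
  explicit H use an idealized hydrogen constructed in the
  antecedent–donor–acceptor plane);
* per-amino-acid reference energies (default 0, configurable);
* every group–group interaction capped at +50 to keep tables finite.

Absolute kcal/mol values are not meaningful; only the pipeline logic
(tables → DEE → exact search → ΔΔG accounting → filter) is claimed and
tested. Rotamers are built from a shipped coarse backbone-independent χ
table (3–6 rotamers per residue type) by ideal-geometry internal-coordinate
construction; the crystal conformation is appended for each position's
native type, and Ser/Thr/Tyr are expanded over the hydroxyl dihedral grid
(60/180/−60°). The bound state appends the TS conformer as an extra
"position" whose states are the library conformers; the unbound state drops
all TS terms and re-optimises rotamers (this realises
ΔG_fold = ΔG_unbound). The wild-type amino acid is always kept in a mutable
position's choice set so the ΔΔG reference is representable.

**Search.** Goldstein singles DEE to a fixed point, then exact depth-first
branch-and-bound with additive lower bounds (assigned interactions exact,
unassigned positions bounded by per-candidate minima). The search refuses to
run (explicit error) if the post-DEE space exceeds a ceiling (default 2×10⁶)
rather than fall back to heuristics. Sequence enumeration solves every
amino-acid sequence exactly (bound and unbound), ranks by bound energy, and
greedily accepts subject to the pairwise diversity restriction (≥ d
positions differing in amino-acid type); at toy scale this is equivalent to
successive exact solves with exclusion constraints.

## Trajectory screening

Indicators are computed per replicate and pooled by frame-weighted means
(identical to mean-of-fractions at equal frame counts, which is the usual
acquisition of 10 × 1 ns and 5 × 5 ns at 10 ps saving intervals → 100 and
500 frames). RMSD_TS superposes the protein backbone (N, CA, C, O) of each
frame onto the first frame before measuring TS heavy-atom RMSD; the first
frame is its own reference and always counts below the cutoff.
"Improvement" over the wild type is strict (>) on all four indicators;
higher attack-distance *fraction* is the operative criterion, the mean
distance being diagnostic only. The funnel report lists round-1 survivors,
round-2 survivors, designs pending round-2 data (excluded from ranking), and
a shortlist ranked by (attack fraction, RMSD frequency, H-bond occupancies)
descending with the design id as final tie-break; the whole computation is
order-independent.

## Kinetics and product accounting

The Michaelis–Menten fit is unweighted nonlinear least squares (trust-region
reflective with positivity bounds) started from a Lineweaver–Burk
regression; standard errors come from the fit covariance, and a warning is
raised when K_m is weakly identified (outside the sampled range or
se > 0.5·K_m). Conversion arithmetic counts BHET, MHET and TPA as one
aromatic unit each against pet_mass/192.17 mol of repeat units; composition
percentages are reported as absent (NaN), not zero, where no product has
been released. Crystallinity is the DSC formula with the 140.1 J/g reference
for fully crystalline PET; negative values (ΔH_cc > ΔH_m) are reported with
a warning rather than clamped.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions and return planted truth:

* **Toy scaffolds** place the six catalytic anchors exactly at their
  constraint targets (or at stated offsets beyond the upper bound, giving a
  known quadratic penalty), build full ideal-geometry residues outward from
  the anchors with clash-avoiding spins, and add apolar decoys at 9–14 Å.
  They exercise anchoring, enumeration, placement and scoring, but have no
  real tertiary structure, no backbone connectivity between residues, and no
  solvent.
* **Frame ensembles** make each indicator's geometric event hold in exactly
  round(p·n) frames (seeded positions; a Bernoulli mode exists for
  statistical tests). Events are decoupled — each indicator has a dedicated
  "off" modification touching atoms no other indicator reads — so recovered
  fractions are sharp. They do not emulate MD physics, correlated motions,
  or solvent; passing tests show the *estimator* is exact, not that any
  design would survive real dynamics.
* **Kinetic tables** draw v₀/[E] from the MM curve with mean-corrected
  log-normal multiplicative noise on a geometric 6-level grid spanning the
  2–20 mM assay range, in triplicate (n = 18). The funnel cohort lays
  indicator fractions on a 0.01 grid so strict comparisons are exact at 100-
  and 500-frame replicates.

## Known limitations

* The K_m recovery precision achievable at n = 18 with 5% multiplicative
  noise is bounded by the Fisher information of the design: within a
  2–20 mM substrate range (K_m ≈ 4.6 mM, incomplete saturation), the
  asymptotic σ(K_m)/K_m is ≈ 5.8% even for the D-optimal two-point design,
  so single-assay K_m estimates should be quoted with their standard errors
  rather than trusted to a few percent. k_cat is ~2× better determined.
* The energy function is a surrogate: it ranks packing alternatives sanely
  but its ΔΔG values are not comparable to force-field results.
* Fused aromatic rings in the side-chain builder are chains of ideal
  internal-coordinate placements; ring-closure residuals of a few
  hundredths of an Å are accepted.
* Pocket detection is resolution-limited by the 1 Å grid and tuned on
  idealized shells; on real scaffolds the parameters (probe radius,
  buriedness threshold) may need adjustment.
* Trajectory input is multi-model PDB only; binary MD formats are out of
  scope, as is running MD itself.
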