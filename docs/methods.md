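# Methods

This package reimplements, as a tested pipeline, a structure–sequence–
phylogeny analysis of the π-turn signature in nuclear-receptor (NR)
ligand-binding domains (LBDs): classifying helix conformations from
atomic coordinates, scanning alignments for the RxxxE motif and the
class I/II dimerization markers, mapping dimer-interface contact
networks, and tracing the motif's gains and losses over a phylogeny.
This note records the models, the defaults and why they were chosen,
what the synthetic data does and does not emulate, and the numerical
choices a maintainer would want to know.

## Helix classification from backbone hydrogen bonds

A π-turn (also called an α/π-bulge) is a local widening of an α-helix in
which the i→i+4 backbone hydrogen bonds are replaced by i→i+5 bonds,
pushing one residue out of the helix axis. The classifier makes this
pattern observable in three steps.

**Hydrogen placement.** Crystal structures lack amide hydrogens; each H
is rebuilt at N + 1.0 Å along the unit vector (C_prev − O_prev).
Chain-start residues and prolines receive no hydrogen.

**Bond energy.** Hydrogen bonds are scored with the Kabsch–Sander
electrostatic model,

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

recorded when E < −0.5 kcal/mol, for donor–acceptor pairs separated by at
least two residues; at most the two best acceptors per donor are kept.
This is the community-standard operationalization of "N+3/N+4/N+5
hydrogen bonds"; the cutoff is configurable because the underlying
analysis never states an explicit criterion.

**n-turn logic.** An n-turn starts at residue i when the bond
(i+n)→i exists; two consecutive n-turn starts make residues i..i+n−1
helical of the corresponding class (3₁₀ for n=3, α for n=4, π for n=5).
Two deliberate deviations from classic DSSP:

1. *Priority π > α > 3₁₀ on overlaps.* Classic DSSP's α-first priority
   systematically absorbs short π-bulges into α-helices — precisely the
   objects this package exists to find. The priority is configurable in
   effect by consuming the raw turn flags exposed on `HelixAssignment`.
2. *Donor-best turn detection.* Only each donor's lowest-energy hydrogen
   bond contributes a turn start (all bonds are still recorded). One
   amide hydrogen donates one primary bond; counting a donor's marginal
   secondary acceptor as an independent turn smeared planted-π
   boundaries by up to two residues. With the rule, planted π segments
   are recovered within ±1 residue per junction on randomized composite
   helices, and pure ideal helices match an independent DSSP
   implementation (mdtraj) exactly over their interiors.

A maximal contiguous π stretch flanked by α on both sides is reported as
a π-turn; the bulge residue is the one with maximal perpendicular CA
distance from the helix axis fitted over the flanking α residues.
Stretches at chain termini are flagged `unflanked`; an isolated single
offset-5 bond inside α context is reported as a candidate with a `weak`
flag rather than a span, because the biological π-turn is a short local
bulge, not a long π-helix.

**Motif/conformation verdicts.** `verify_motif_conformation` combines
(i) canonical R…E spacing (E at R+4), (ii) an intra-chain salt bridge
between the pair (basic N atoms to acidic O atoms within 4.0 Å), (iii) a
π-turn overlapping the pair, and (iv) optionally a 3₁₀ stretch inside a
caller-supplied junction window (the helix H10–H11 junction check). The
three verdict labels — `pi-turn-motif`, `motif-without-pi-turn`,
`no-motif` — encode the central dichotomy: some receptors (the COUP-TF
and PNR groups) carry the sequence motif with no structural π-turn.

## Motif scanning and coordinate systems

Alignment rows are scanned gap-aware: pattern spacing is counted over
non-gap residues, so a motif split by gap columns is still one hit. The
recognized variants are RxxxE (canonical), KxxxE, QxxxE, and RxxxxxxE,
with precedence in that order at a shared anchor — the variants are
degradation states of the canonical motif. Hits are non-overlapping per
row; columns are 1-based everywhere and output files say so.

Three numbering systems are mapped explicitly: generic alignment
positions, native author numbering per receptor, and Brelivet marker
numbering. The packaged anchor table records, for six receptors
(hRXRα, hHNF4α, hCOUP-TFII, hPNR, hRARα, hTRα), the native residue at
each of fifteen anchored alignment positions grouped into
secondary-structure blocks (H4-H5, H5, H7, H8, loop H8-H9, H10, H11);
within a block, native numbering is contiguous with alignment numbering,
which is what lets a single anchor (e.g. 202 ↔ R348) place every other
H7 position. All shipped anchors were audited for internal contiguity at
load time and in tests.

The default class-marker definition is: class I (monomeric/homodimeric
receptors) E5, W40, K/R55, R/K93, R105; class II (RXR-heterodimer
partners) E/D42, R62, H/R/K90; universally conserved E50 and R105. Two
documented judgment calls: positions 5, 55 and 90 have no anchored
alignment column in the packaged table and are skipped with a note
unless the caller maps them; and R105, listed both as class I and as
universal, is treated as universal but still counted in class I audits
(this matches the published SpNR2 audit, where its absence counts
against class I). Verdicts: `class I`/`class II` when exactly that class
is complete, `outlier` when the closest class misses ≤ 2 markers,
`undetermined` otherwise.

## Interface contacts and buried surface

Contacts between two chains are typed by distance only — hydrogen bond
(N/O–N/O ≤ 3.5 Å), salt bridge (Arg/Lys N to Asp/Glu O ≤ 4.0 Å, which
outranks the hydrogen-bond label for the same residue pair), van der
Waals (any heavy-atom pair ≤ 4.5 Å not otherwise typed) — with one
record per residue pair at the minimal distance. Water-mediated contacts
require exactly one bridging water whose oxygen lies within 3.5 Å of a
polar atom in each chain; two-water chains are out of scope. Cutoffs are
configuration, not science: the source analysis reports bonds at residue
level without stating criteria, and crystal structures lack the
hydrogens an angular term would need (an angle filter exists but is off
by default).

Contacts are binned by named element pairs (H7, H8, loop H8-H9, H9, H10,
H11 per chain, from a per-structure range map; no automatic helix naming
is attempted). The asymmetry score is

    count(H7_A ↔ loopH8-H9_B) − count(H7_B ↔ loopH8-H9_A),

positive when chain A behaves like RXR in a heterodimer — its π-turn-
bearing H7 packs against the partner's loop H8-H9 far more than the
reverse — and zero for a symmetric homodimer.

SASA uses Shrake–Rupley sampling with a fixed golden-spiral point set
(960 points/atom by default, deterministic, no RNG), standard van der
Waals radii, a 1.4 Å probe, and hydrogens excluded. Buried surface area
is SASA(A) + SASA(B) − SASA(AB); tests pin the isolated-sphere closed
form (within 2%), chain-order symmetry, and rigid-motion invariance.

## Character evolution

The engine is k-state generic. The rate model is SYM — a continuous-time
Markov chain with symmetric rates q_ij = q_ji, zero row sums — with ER
(all rates equal) as the one-parameter special case. Transition
probabilities are P(t) = exp(Qt) via `scipy.linalg.expm`, rows clipped
and renormalized against roundoff.

**Likelihood** is Felsenstein pruning with per-node log-scaling; missing
tips enter as all-ones partials (the conservative "coded as unknown"
policy), and multifurcations are handled natively as products over all
children. Pruning is verified to 1e-10 against exhaustive enumeration
over all internal labelings on every rooted shape with ≤ 5 tips and
≤ 4 states, and against two-state closed forms.

**Rate fitting** maximizes the pruning likelihood with non-negative
bounds (tolerance 1e-8). Loss-dominated binary data has a likelihood
surface with a high-rate saturation plateau (all tips effectively i.i.d.
stationary) that can trap a bounded scalar search, so the optimizer
first scans a log-spaced grid (1e-4 to 1e3) and then refines locally;
the SYM fit starts all pairs at the best shared-rate grid point.
Invariant data returns the rate-zero boundary with a warning. The fitter
accepts several independent characters sharing a state space and sums
their log-likelihoods; the parameter-recovery acceptance experiment fits
four independent binary characters per 128-tip replicate because a
single binary character does not carry enough Fisher information for
±30% precision at any rate (≈ 24 expected changes ⇒ CV ≈ 20%).

**Ancestral states** are marginal posteriors from up/down message
passing, root prior equal by default (matching the common default of the
reference stochastic-mapping implementation; a stationary prior is
equivalent under SYM, and any prior vector can be supplied).

**Stochastic mapping** samples joint node states root-to-tip from the
conditional distribution implied by the upward partials, then fills each
branch with an endpoint-conditioned path: rejection sampling first
(exact and fast in this analysis's low-rate regime), with an exact
uniformization sampler after 1,000 failed attempts (number of virtual
jumps drawn from its conditional series, bridge states by matrix-power
weighting, self-jumps collapsed). Samples are summarized as per-node
state frequencies and per-type transition-count means and quantiles.
Tests check endpoint consistency of every sampled path, agreement of
10,000-sample node frequencies with marginal posteriors within 0.02,
agreement of conditioned-branch mean counts with an independent
sojourn-integral oracle within 3 Monte-Carlo standard errors, and that
no sampled history ever beats the parsimony lower bound.

**Parsimony.** Minimum changes use Hartigan voting (exact on
multifurcating rooted trees, reduces to Fitch on binary trees), verified
against exhaustive labeling on small trees. Dollo loss counting assumes
a single origin with irreversible loss: each loss is placed on the
highest node all of whose non-missing tip descendants lack the
character; missing tips neither anchor nor veto a loss. Declaring the
root absent while present tips exist is an error.

## Synthetic data: what it emulates, what it does not

`synthetic` generates every input the pipeline needs. Ideal backbones
are built by internal-coordinate chain extension with standard bond
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°) and default
dihedrals α(−57°, −47°), 3₁₀(−49°, −26°), π(−57°, −70°) — the π pair
from standard tabulations, since tests assert the hydrogen-bond pattern,
not dihedral values. Toy dimers are two parallel ideal α-helices (the
helix axis is aligned with the inter-chain offset so designed geometry
holds everywhere) with one pseudo side-chain atom per bridged residue —
an Arg-like NH1 and a Glu-like OE1 placed on the CA–CA line at the exact
target distance; construction verifies that every non-designed
inter-chain atom pair stays beyond the van der Waals cutoff + 1 Å and
rejects infeasible layouts (bridges closer than ~4 residues interact).
Planted alignments draw background residues uniformly outside
{R, K, Q, E} so no spurious motif can arise. Trees are Yule processes
scaled to unit depth; characters evolve forward by Gillespie simulation,
with the per-branch event lists retained as ground truth.

None of this emulates real data's hard parts: side-chain rotamers,
crystallographic noise, alternate conformations, alignment errors, or
rate heterogeneity across lineages. Passing tests demonstrate that the
algorithms are correct on their stated models, not that the biological
calls on real structures are settled; the structure-facing operations
accept real PDB/mmCIF files for that purpose.

## The packaged NR dataset

`piturn/data/` ships a 50-tip NR phylogeny and a reconciled π-turn
character table transcribed from published qualitative statements about
motif occurrence — not from the original inference files. Coding rules,
stated in the file header: structural evidence overrides the sequence
motif (COUP-TF and PNR carry RxxxE without the π-turn); lineages whose
only motif is a degraded variant are coded absent for the canonical
character; motif-bearing lineages without structures are coded present;
lineages without usable evidence are coded unknown. Clade sizes are kept
representative of the real superfamily (the derived subfamilies and the
conserved HNF4/RXR/SpNR1 groups each contain many receptors, so each is
several tips here), and relative branch lengths 0.5/1/2 encode the
reported pattern that motif losses sit on the longest, fastest-evolving
branches while conserved motif-bearers sit on the shortest. At desk
scale this dataset reproduces the analysis's two phylogenetic
conclusions: Dollo counting yields 10 independent losses (≥ 5), and
ML-ER marginal reconstruction places `present` at the root
(posterior ≈ 0.69, simmap root frequency ≈ 0.70).

## Problem sizes and determinism

Default experiment sizes are chosen for desk-scale runs: 100 random
composite helices for classifier validation; 10,000 stochastic maps on a
5-tip tree for the frequency/posterior consistency check; 20 replicates
of 128-tip trees (4 characters each) for rate recovery; 960 sphere
points per atom for SASA. Every stochastic operation takes an explicit
seed and is bit-reproducible given it; the SASA point set and all
optimizers are deterministic. `scripts/acceptance.py` recomputes the
pipeline's headline numbers from the packaged data and writes them as
JSON; the only seed-dependent entries are the stochastic-mapping
summaries.

## Known limitations

- No β-sheet/bridge assignment; non-helical structure is `turn`/`coil`.
- Distance-only contact typing can over-count hydrogen bonds in tightly
  packed apolar interfaces; the angular filter is available but off.
- The Dollo counter is binary-character only; multi-state irreversible
  models are out of scope.
- SYM fitting with k > 2 optimizes k(k−1)/2 rates by L-BFGS-B from a
  single grid-selected start; strongly multimodal surfaces may need a
  user-supplied start.
- The packaged NR dataset is a curated transcription at desk scale;
  swapping in the original tree/character files (they load through the
  same readers) is the intended path for real re-analysis.
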