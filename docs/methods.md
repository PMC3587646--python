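# Methods

## Scope and model

`trapmap` treats primary-structure characterization of a homodimeric
receptor–Fc fusion protein as four deterministic matching problems over a
shared mass model, plus a charge model for isoelectric focusing:

1. **Peptide mapping.** Trypsin is modeled as cleavage after K or R unless
   the next residue is P. A digest with `max_missed` m produces every
   concatenation of up to m+1 adjacent fully cleaved peptides; the zero-missed
   peptides tile the chain exactly, which gives two checked conservation
   laws (length tiling and water-corrected mass additivity). Peptide masses
   are sums of residue (monomer-minus-water) masses derived from elemental
   compositions, plus one water and any modification deltas. Monoisotopic
   and average scales are kept strictly separate by the `MassValue` type;
   both are always computed, because ion-trap peak tables do not state
   which scale their values approximate.

2. **PNGase F occupancy.** An occupied N-X-(S/T) sequon (X ≠ P) releases
   its glycan and converts Asn to Asp, +0.98402 Da. In the PNGase F-treated
   workflow this is applied as a fixed consequence at every occupied sequon;
   in the untreated workflow deamidation (N/Q) and oxidation (M) are
   variable modifications expanded combinatorially up to a configurable
   count. Occupancy is read back from matches: a site is called occupied
   when a peptide carrying the deamidation signature at that Asn is
   assigned.

3. **Disulfide mapping.** From a non-reduced digest, the expected linked
   species are the connected components of the peptide–bond graph; a
   component with b bonds has mass ΣM_i − 2.01565·b. In a symmetric
   homodimer the two chains' intra-chain species are indistinguishable and
   collapse to one reported species, and the hinge peptides joined by two
   inter-chain bonds form a single two-bond homo-di-peptide — hence a
   trap-type topology yields exactly five di-peptide species. The
   scrambling check enumerates every unordered pair of Cys-bearing peptide
   species (self-pairs included; two-bond variants where both members carry
   two cysteines) and flags any peak explained only by a non-native pair.

4. **Glycoform assignment.** Compositions are antenna counts
   (Hex, HexNAc, Deoxyhexose, NeuAc) over a boolean Man3GlcNAc2 core,
   mirroring how glycopeptide reports print them. A free reducing glycan is
   the residue sum plus one water; 2-AA labeling adds a fixed
   reductive-amination delta (anthranilic acid − H2O + H2 = +121.05276 Da
   mono); an attached glycan contributes its residue mass only, and the
   attachment Asn stays unmodified. De novo assignment is an exhaustive
   bounded-lattice search (defaults Hex ≤ 10, HexNAc ≤ 8, Deoxyhexose ≤ 3,
   NeuAc ≤ 4), sorted by |error| with a deterministic count-order
   tie-break; library matching replaces the lattice when a library is given.
   Per-site ranking uses intensity when present, |error| otherwise.

5. **pI model.** Net charge is the Henderson–Hasselbalch sum over the
   termini, D, E, C, Y, K, R, H and one carboxylate (pKa 2.6) per sialic
   acid on attached glycans. The pKa set is Bjellqvist's, exposed in the
   configuration and overridable — isoelectric focusing pI values are
   empirical and no single set is canonical. The charge curve is strictly
   decreasing in pH, so the pI is the unique root on [0, 14]; it is found
   with Brent's method (xtol 1e-10) and verified to |charge| < 1e-4.
   Compositions lacking a sign change (no acidic or no basic group) are
   rejected rather than clamped.

## Matching

Observed peaks are given as MH+ or (m/z, z) and canonicalized to neutral
monoisotopic mass. Each peak gets its best candidate within tolerance:
smallest |error| in Da, ties broken by fewer modifications, then
lexicographic sequence — so matching is deterministic and order-invariant,
and is implemented as (and tested against) the exhaustive all-pairs search.
The default tolerance is ±0.5 Da, the working accuracy of an ion-trap full
scan. Ion traps also mis-pick +1 isotope peaks for larger peptides; the
matcher can retry an unmatched peak at −1.00335 Da and flags such
assignments as isotope-offset matches instead of silently absorbing them.

## The synthetic fixture

The generator emulates the architecture of a VEGF-trap-type fusion protein
without copying any real sequence. Each 400-residue chain interleaves
designed tryptic peptides — seven sequon-bearing peptides at fixed
coordinates (Asn 33, 65, 120, 193, 249, 270, 376), two receptor-domain
cysteine peptide pairs, a hinge peptide with two cysteines, and two Fc
(CH2/CH3) cysteine pairs — with seed-generated filler peptides. Fillers
contain no C, N, K or R in their bodies, so cleavage sites, sequons and the
cysteine inventory are exactly the designed ones; an assertion-with-retry
loop enforces this. Filler residue frequencies include D/E at 5% each and
H at 6%, keeping the chain pI near neutral, the regime isoelectric
focusing of such fusion proteins reports. The topology (four intra-chain
bonds per chain, two inter-chain hinge bonds) yields five linked di-peptide
species, one with two bonds.

Per-site glycoforms are complex biantennary compositions on the core —
sialylated/fucosylated at the receptor-domain sites, a truncated asialo
series at the Fc-like site — with rank abundances 0.4/0.35/0.25. The noise
model emits one peak per surviving species at MH+ + N(0, σ) with σ = 0.2 Da
by default, a 0.1 probability of a +1.00335 Da isotope mis-pick, optional
dropout, and Poisson-count contaminants uniform over m/z 500–2000. All
generators are deterministic under their seeds.

What the fixture does *not* emulate: isotope envelopes, charge-state
distributions, retention behavior, ionization-efficiency differences
between glycoforms, and real receptor/IgG1 sequences. Passing tests
therefore demonstrate correctness of the mass arithmetic, enumeration and
matching logic under realistic mass error — not performance on real
instrument data.

## PNGase F time course

Site release is modeled as independent first-order kinetics
(fraction released = 1 − e^(−rt), default r 0.05 h⁻¹ — the snapshots the
model reproduces do not constrain the rate tightly, so it is exposed in the
API). The exact distribution over (converted sites, total sialic count) is
computed by convolution across sites, and each state's pI comes from the
charge model (converted sites add Asp; occupied sites add their mixture's
sialic carboxylates). At t = 0 the profile is a heterogeneous multi-state
distribution; as t → ∞ it collapses to the single fully deamidated species.
Mean pI strictly decreases with time because, at the preset mixture, the
mean sialic charge per site (≈0.89) is below the one full Asp charge each
conversion adds; the net shift is accordingly modest. The larger
"acidic shift" reported by the pipeline compares the fully glycosylated
ensemble against the fully deglycosylated chain.

## Numerical and design choices

- Mass constants: water 18.010565, proton 1.007276, disulfide −2.015650,
  carbamidomethyl +57.02146, deamidation +0.98402, C13 spacing 1.00335
  (all mono, Da), derived from the atomic tables rather than hard-coded
  observations.
- Cys blocking in the reduced workflow is carbamidomethylation, fixed on
  every Cys: it is the adduct consistent with the reference observations.
- Coordinates are 1-based with inclusive intervals throughout.
- When a peptide pool contains missed-cleavage variants, canonical linked
  species are built from the zero-missed peptides (each cysteine then maps
  to exactly one peptide); missed-cleavage linked variants remain visible
  to the hypothetical enumeration.
- Intra-peptide ("looped") disulfides are supported as size-1 species.
- Degenerate composition-search hits inside the tolerance are all reported
  in a deterministic order; on the default lattice no two compositions lie
  within 0.01 Da, which the suite verifies by round-trip.
- Reports contain no timestamps, so identical configurations produce
  byte-identical output.

## Problem sizes

The test suite and the acceptance script run the preset fixture
(400 residues/chain, ~40 tryptic peptides, 10 bonds, 21 glycoforms), 20
replicates for the parameter-recovery property and 20 random instances for
the matcher-oracle equivalence; the whole suite completes in a few seconds
on one CPU.

## Limitations

No MS/MS scoring (the MGF reader supports qualitative b/y confirmation
only), no quantification beyond intensity pass-through, no semi-tryptic
search space, no linkage/isomer resolution for glycans, and no modeling of
partially reduced disulfide intermediates. The pI model treats pKa values
as context-free; real CE pI values shift with local sequence environment
and temperature.
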