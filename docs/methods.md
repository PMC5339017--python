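# Methods

## The design model

An assembled guide reads 5′→3′: `back-fold — loop/cleaving unit — spacer
[— scaffold]`. The back-fold reverse-complements the loop-proximal 5′
segment of the spacer; the superscript x of SBH(x) counts spacer
nucleotides left unpaired at the scaffold-proximal 3′ end. This placement
is forced by topology: the loop joins the back-fold's 3′ end to the
spacer's 5′ end, so only the 3′ spacer tail can remain free. Coordinates
are 0-based half-open; position 0 is the guide's 5′ nucleotide. Inputs may
be DNA or RNA and are normalized to uppercase RNA at ingestion.

Bulges are expressed in *paired-stem depth*: a bulge at depth d sits after
d base pairs counting from the loop. Spacer-strand bulges are realized as
skipped complements (the spacer itself stays intact for DNA targeting);
back-fold-strand bulges insert filler nucleotides. Defaults:

| parameter | default | rationale |
|---|---|---|
| spacer length | 20 nt (10–20 accepted) | canonical SpCas9 guide |
| SBH(0B) bulges | 2 nt on the spacer strand at depths 5 and 12 | two interior bulges that destabilize without opening either stem end; positions are configurable |
| SBH(0B\*) basal bulge | additional 2 nt at depth 13 | one pair above the stem base — the closest interior position to "basal" available after the 0B bulges |
| basic loop | GAAA tetraloop | stable, structurally inert stand-in for the prototype loop |
| scaffold | 80-nt tracrRNA constant; SAM 2×MS2 variant selectable | excluded from folding by default (see below) |

Every construct carries its *expected pairing* (the design's target
structure) explicitly: stem pairs, cleaving-unit internal pairs, and
sensing-loop flank pairs. The target dot-bracket and constrained-position
mask are derived from this pair set; scaffold positions are unconstrained.

## Graft geometries and residual nucleotides

Apex grafts swap the loop for the unit. Bulge grafts (medium = distal,
loop-proximal bulge; nano = proximal, scaffold-proximal bulge) delete the
stem between the apex and the chosen bulge on both strands and bridge the
cut points with the unit. Where the unit has a cut site, its post-cut 3′
tail (8 nt for the Csy4 repeat) is fused into the rebuilt stem: the
deleted back-fold apex segment is replaced by the reverse complement of as
much tail as the deleted depth accommodates. Consequences, both monotone
across full → medium → nano: the back-fold:spacer pair count shrinks
(16 → 11 → 4 with the default bulges), and `residual_5p_nt` — retained
nucleotides 3′ of the cut and 5′ of the spacer region that are unpaired in
the expected fold — drops 8 → 3 → 0. The geometry of a bulge graft is not
uniquely determined by its name alone; both-strand deletion with tail
absorption was chosen because it is the only variant we found that yields
both intended trends simultaneously (decreasing stem stability and
decreasing unstructured 5′ residue).

The Csy4 unit is the canonical 28-nt *P. aeruginosa* repeat with its 5-bp
stem-loop and cleavage 3′ of nt 20. The Cas6A and HHRz units shipped as
defaults are synthetic stand-in hairpins with the same layout; real
designs should override them with the experimentally validated motifs via
the unit catalog.

## Folding engine and scoring

Folding goes through a pluggable engine object (`fold(seq) → FoldResult`);
the default backend is ViennaRNA at 37 °C with default parameters, which
is deterministic for a pinned version. `stem_free_energy` folds the
hairpin region only (back-fold + loop + spacer): the scaffold's own
structure would dominate the value, and the quantity of interest is stem
stability; a flag folds the full guide, and a duplex-only variant ignores
the loop sequence.

The folding score FSᵢ defaults to the fraction of constrained positions
whose pairing state in the MFE structure matches the target, where
brackets require the identical partner and dots require the unpaired
state. This is deterministic and cheap; an alternative probability mode
averages equilibrium pair probabilities of target pairs (and unpaired
probabilities at target dots) for users who prefer ensemble-weighted
similarity. Exact match ⇔ FSᵢ = 1. Pseudoknots are not modelled; all
target structures are nested by construction.

A caveat found while validating: MFE is not monotone under stem edits.
Adding the basal SBH(0B\*) bulge *usually* raises the hairpin's MFE
relative to SBH(0B) (46/50 random GC-balanced spacers), but the edited
sequence occasionally folds into an alternative register that is up to
~2 kcal/mol more stable. The destabilization ordering is therefore a
statistical property over random spacers, not a per-sequence theorem.

## Sensing-loop evolution

The ASL is 20 nt: a 14-nt single-stranded core (the ASO footprint) with
3-nt flanks. The flanks are interpreted as a stem *extension* that pairs
flank-to-flank and closes the loop at a fixed register: a loop shared
across spacers cannot have spacer-dependent flanks, and any flank-to-spacer
pairing would be pseudoknotted. Flank values are fixed by the design
context (default 5′-GGC/GCC-3′, a strong closing stack) and re-imposed
after every crossover and mutation; evolution therefore explores the core.

The GA per generation: every pool member is recombined (single-point
crossover at a uniform position) with a uniformly chosen partner and both
offspring join the candidate set; mutated copies (per-base substitution to
a different base, default rate 0.05) and fresh random loops are added
(default pool/2 each); every candidate is scored by ∏ᵢ FSᵢ over the
loop–spacer SBH(0B) hairpins, and the best `pool_size` unique sequences
survive (elitist, score-then-truncate on the merged pool; duplicates are
collapsed to preserve search diversity). Ranking is total: product score
descending, then |GC − 0.5|, then longest homopolymer run, then sequence —
which also makes ranked TSV output byte-reproducible under a fixed seed.
Stopping: the generation count must exceed `max_generations` (default 20)
*and* the best score must have been unchanged for `stall_generations`
(default 2) consecutive generations; a hard cap of 5 × `max_generations`
guarantees termination. Defaults (pool 150, 20 generations, 2-generation
stall) are the method's standard operating point; the mutation rate and
per-generation injection counts are free parameters chosen here. Folding
results are memoized per loop sequence within a run, which changes nothing
observable (the engine is deterministic) and keeps a default run at ~15 s
for two spacers on one CPU.

`exhaustive_evolve` enumerates all 4ᵏ fills of a variable region (guarded
at k ≤ 8) and is the independent optimum against which GA runs are
validated; with 4-nt cores the GA matched the exhaustive optimum in 20/20
seeded instances.

## Synthetic data

`synth_spacers` draws i.i.d. bases (G/C with probability `gc_target`,
default 0.5) — it emulates sequence composition only, not genomic
context, PAM availability or off-target structure, so passing tests say
nothing about on-genome guide activity. `plant_shared_loop_instance`
rejection-samples spacers until a fixed probe loop folds perfectly on each
(GC 0.6 proposals; a planted instance whose global optimum is known),
which is how loop-recovery claims are made falsifiable. The fixed
`synthetic_cts_spacers` pair is a frozen synthetic stand-in for a pair of
reporter-target spacers; the sequences are generated, not genomic.

## Numerical choices and limitations

- Energies are reported to 0.01 kcal/mol as returned by the engine;
  orderings are compared with a 10⁻⁹ tie tolerance.
- Bulge-slide placements use depth range [0, paired-stem length], so a
  bulge may abut the loop or the stem base; placements = paired length −
  depth span + 1.
- The +G1 rule is idempotent and applied at oligo generation, not to the
  stored RNA design.
- The bottom cloning oligo is AAAC + reverse complement of the insert,
  the annealed-duplex convention for BbsI-linearized guide backbones.
- Cross-engine free energies differ by up to ~1.5 kcal/mol from
  NUPACK-family values; orderings are robust, absolute values are
  engine-family-specific.
- Off-target scanning, PAM validation, cleavage kinetics and ribozyme
  catalysis are out of scope; the HHRz is handled purely as a graftable
  sequence unit.
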