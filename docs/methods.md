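# Methods

## Scope and pipeline

`glycorank` ranks every modification isomer of a GAG precursor against an
annotated MS² fragment list. The pipeline is deterministic end to end:

1. **Neutral mass.** Precursor ions are unadducted deprotonated species;
   `M = |z|·(m/z) + |z|·1.007276` Da. Metal-cationized precursors are out
   of scope.
2. **Composition inference.** Candidate compositions (dp 2–12 by default,
   every legal sulfate/acetyl count, saturated and 4,5-unsaturated
   nonreducing ends for HS/CS) are enumerated with exact monoisotopic
   masses and the arithmetically closest one wins. Exact ties are broken
   by fewest modifications, then lowest dp, then saturated first — the
   closest-mass rule alone does not define a unique winner and a
   deterministic tool needs one.
3. **Backbones.** Unequal residue counts force the majority kind onto both
   termini (one backbone); equal counts leave two alternating backbones
   unless the unsaturated flag pins ΔHexA at the nonreducing end.
4. **Enumeration.** For HS, `C(a, nAc)` acetyl placements times
   `C(open, nS)` sulfate placements over the open positions (2-O per
   HexA/ΔHexA; N, 3-O, 6-O per GlcN, the N position closed by acetylation);
   CS offers 2-O per HexA and 4-O/6-O per GalNAc, KS 6-O per residue.
   At most one sulfate per position. Uronic-acid epimers (GlcA/IdoA) are
   isobaric and not enumerated; candidate counts reflect modification
   placement only.
5. **Fragments.** Terminal glycosidic B/C/Y/Z at every bond (C = B + H₂O,
   Z = Y − H₂O, reducing-end tag on the Y/Z side), terminal cross-ring A/X
   ions, and internal double-glycosidic spans (span residues + H₂O).
   Internal glycosidic–cross-ring and cross-ring–cross-ring ions are not
   generated. Each fragment may shed 0..k SO₃ losses bounded by its
   retained sulfates.
6. **Matching.** Observed peaks are converted to neutral masses, merged
   across charge states (within the ppm tolerance; intensities summed,
   best G-score kept) and matched to theoretical masses at 5 ppm relative
   to the theoretical value. A peak isobaric with both a terminal and an
   internal fragment of the same sequence counts as terminal.
7. **BiRank.** Symmetric degree normalization, query-vector blending, L1
   convergence. Output is the descending score list with tie-aware rank
   spans and percent-of-incorrect-outscored.

## Cross-ring fragment catalog

The upstream fragment database is replaced by on-the-fly mass arithmetic.
Cross-ring cleavages are generated from a per-residue ring-arc partition:
atoms C2..C6 and the ring oxygen are each assigned an elemental group
(summing exactly to the residue formula), a cleavage label names the arc
retained on the nonreducing side (defaults `0,2`, `1,5`, `2,4`, `3,5`),
and the A ion is the nonreducing prefix plus that arc with the
modifications sitting on retained carbons. The X ion is defined as the
exact complement (precursor minus A), which enforces A + X = M by
construction. Arcs that do not contain the residue's chain-in linkage
carbon (C4, or C3 for 1→3-linked residues) are skipped for non-terminal
residues because the retained piece would be disconnected. For the
4,5-unsaturated ΔHexA the partition is a bookkeeping split of C₆H₆O₅
rather than an atom-exact treatment of the ene — ΔHexA cross-ring masses
are therefore approximate at the level of the lost water's formal
position, while all its glycosidic fragments are exact. The whole table
is a configurable argument of `theoretical_fragments`, since published
ExD studies differ in which cross-ring ions they observe.

## Parameters

| parameter | meaning | default | bounds |
|---|---|---|---|
| `r1` | internal-edge downweight exponent, weight `0.2^r1` | 5.4 | [0, 10] |
| `r2` | G-score exponent in the fragment prior `I/G^r2` | 5.1 | [0, 10] |
| `r3` | rare-modification penalty exponent in the sequence prior | 0.4 | [0, 10] |
| `alpha` | graph weight vs fragment prior per iteration | 0.98 | [0, 1] |
| `beta` | graph weight vs sequence prior per iteration | 0.94 | [0, 1] |
| `N` | leading peak-list rows used | 68 | 5–100 or all |
| ppm | fragment match tolerance | 5 ppm | > 0 |

Defaults for the six tunables are the medians of the optimal combinations
found by the simulated-annealing search on the training standards. The
top-N selection takes the first N rows of the peak list as provided (the
simulator writes rows sorted by ascending G-score, so "first" means
"best fit" there).

## Simulated annealing

Fitness of a parameter vector is the mean over training compounds of the
fraction of incorrect sequences scoring strictly below the known
sequence (1.0 truth-first, 0.0 truth-last; a single-candidate compound
contributes 1.0 by convention to avoid 0/0). The schedule starts at
T = 1, multiplies by 0.9 after 100 iterations per level, and stops below
T = 1e−3 (about 67 levels / 6700 evaluations). A proposal redraws exactly
one uniformly chosen parameter from its bounds with the stated rounding;
worsening moves are accepted with probability `exp((f_new − f_current)/T)`
and the best-ever solution is retained. The initial state is a uniform
draw under the run seed. Refitting reuses all cached candidate chemistry,
so one evaluation on a dp4 compound costs ~1–2 ms and a full default
schedule a few tens of seconds.

## Numerical choices

* Monoisotopic atomic masses are embedded constants (IUPAC values, ≥ 6
  decimals); formula arithmetic is integer-exact.
* BiRank: tol 1e−9 on the L1 change of (p, u), max 1000 iterations
  (warn and return the last iterate on failure). Zero-degree rows/columns
  get a zero normalization factor and relax to their query components.
* G-scores are floored at 1e−6 before exponentiation so a perfect fit
  does not divide by zero.
* Score ties use a 1e−12 relative tolerance; tie groups share a
  contiguous rank span and percent-outscored counts only strictly lower
  scores.

## The synthetic-spectrum generator

`glycorank.simulate` emulates the upstream peak picker's output for a
known sequence or isomeric mixture: each theoretical fragment is detected
with a per-family probability (terminal 0.9, internal 0.5 by default),
true-peak intensities are log-normal with terminal ions brighter than
internal ones (medians 1000 vs 100, σ = 0.5 in log space) scaled by the
component's abundance ratio, G-scores are uniform(0.1, 2) for true peaks
and uniform(1, 5) for decoys, and decoy masses are rejection-sampled at
least 3× the match tolerance away from every theoretical fragment of
every candidate isomer. Detection is additionally scaled by
`ratio^0.5`: a minority component's fragments fall below the picking
threshold more often, which is the physical mechanism that makes mixture
ranking informative at all — with abundance-independent detection the two
components of a mixture would be statistically symmetric. Pure samples
(ratio 1) are unaffected by this term.

What the generator does **not** emulate: isotope envelopes and their fit
statistics (G-scores are only ordinally realistic), charge-state physics
(fragment charges are drawn uniformly from {−1, −2}), fragmentation
efficiency differences along the chain, chemical noise with structure
near real fragment masses, and co-eluting non-isomeric contaminants.
Passing recovery tests on these fixtures therefore demonstrates that the
graph model identifies the generating isomer when the fragment evidence
is present and honestly weighted — not that any given real spectrum
contains that evidence.

Test problem sizes are chosen for desk-scale determinism: recovery runs
use dp 4–6 compositions capped at ~1500 candidates, the mixture check
uses a dp4 pair over ten seeds, and the annealing check trains on two
dp4 compounds with full fragment complements.

## Known limitations

* Mixture *detection* is out of scope: the ranker has no way to tell a
  user the sample is a mixture, it only orders candidates.
* Epimers (GlcA vs IdoA) and anomeric configuration are invisible to
  mass-based matching and are not reported.
* The exact cross-ring catalog of any particular instrument/method is
  not knowable from masses alone; the default table is a documented,
  configurable reconstruction.
* Sequences whose only distinguishing feature is a rare modification are
  penalized by the prior and can rank below rare-modification-free
  rivals with identical edge sets — the deliberate trade-off behind the
  Eq.-4 penalties.
* Sulfate losses are applied to fragments only, not to charge-reduced
  precursor species.
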