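# Methods

## The design model

A PCR clamp is useful when two conditions hold simultaneously: it binds
every host template at its site (so host amplification is reliably
blocked), and it fails to bind every microbial template (so microbial
amplification is untouched). clampforge operationalizes this on a
pre-computed multiple alignment of host and microbial references for the
target locus:

- **Host bindability** is modelled as strict column conservation. A column
  is usable when no host row has a gap there and the majority host residue
  reaches `min_conservation` (default 1.0 — "strictly conserved"). The
  default is strict because a clamp that misses even one host haplotype
  leaks host reads; it is relaxable for degraded reference sets, in which
  case every reported block should be read together with the host sample
  size `n_host` that the profile carries — conservation over three
  sequences is weak evidence, over thirty it is strong.
- **Microbial sparing** is modelled as per-site divergence: the number of
  clamp positions whose host-consensus base fails to IUPAC-intersect the
  microbial residue. A microbial gap under the clamp counts as a mismatch —
  a clamp spanning a host-specific insertion cannot bind the microbe at
  all, which is the strongest possible mismatch and the reason
  insertion-anchored clamps are the best designs where an insertion exists.
  Degenerate microbial bases count as matches whenever the base sets
  intersect: this deliberately understates divergence and never overstates
  clamp safety. The aggregate score is the *minimum* over microbial rows
  (config-selectable to mean), matching the "at least five mismatches to
  every microbial sequence" design rule; a mean would let one vulnerable
  taxon hide behind many divergent ones.

Ranking is a total deterministic order: minimum mismatches descending,
then |Tm − 80 °C| ascending, then fewer guideline violations, then
leftmost start with the host-strand orientation before the reverse. The
tie-breaks matter because conserved blocks produce many overlapping
co-optimal windows; determinism makes designs reproducible across runs.

## Guideline screen and soft constraints

Candidates are annotated against the compositional guidelines: length
12–21 nt, purine content strictly below 50%, no purine run longer than 4,
no self-complementary stretch of `self_comp_k` (default 4) or more, Tm
above the PCR primers' Tm and above the 72 °C extension temperature. The
default `constraint_mode` is **soft**: violations are listed per candidate
rather than fatal. This is a deliberate choice — several field-proven
published clamps bend these guidelines (a 24-nt ITS1 clamp, a V5V7 clamp
with a 5-purine run, a mitochondrial clamp sitting exactly at 50%
purines), so hard enforcement would reject working designs. Hard mode is
available for strict workflows. The purine threshold is applied strictly
("lower than 50%"): a candidate at exactly 0.50 is flagged.

The guideline pair "annealing temperature higher than the primers" and
"melting temperature above extension" involves two temperature notions
whose offset is instrument- and chemistry-dependent; both are evaluated as
Tm-based predicates with reported margins rather than collapsed into one
number.

## Thermodynamics

DNA/DNA Tm uses the unified nearest-neighbor parameters (Allawi &
SantaLucia 1997) with the entropic salt correction
`ΔS += 0.368·(N−1)·ln[Na⁺]` and a two-state Tm at 250 nM oligo, 50 mM
monovalent salt (both configurable). Degenerate primers are resolved by
enumerating concrete expansions and taking the most stable one by default:
for blocking purposes, feasibility is governed by the strongest variant
("min" and "mean" modes exist). Sequences below 8 nt are rejected — the
nearest-neighbor model is unreliable there — which also sets the effective
minimum for the PNA correlation.

PNA/DNA Tm uses the published sequence-based correlation
`Tm_PNA = 20.79 + 0.83·Tm_NN − 26.13·f_pyr + 0.44·L` (coefficients
configurable). It is an empirical regression, not a duplex model: absolute
parity with vendor web tools is not claimed, and for the pyrimidine-rich
oligomers clamp design favours it correctly predicts PNA/DNA duplexes
melting above their DNA/DNA counterparts. A practical consequence of using
a conservative DNA-anchored correlation is that short clamps rarely reach
the nominal 80 °C target on the predicted scale; the target acts as a
ranking attractor and a reported margin, and the soft default keeps
Tm-shortfall candidates visible rather than silently dropped.

## Blocking primers

Blocking primers (3' C3 spacer, not extendable) are designed by geometry
plus Tm targeting only — the compositional PNA criteria are not applied to
them. Competitive designs seed at the intersection of a conserved block
with a PCR primer's binding site and record which primer they out-compete;
elongation-arrest designs seed at the centre of the widest conserved block
strictly between the primer sites. The seed grows one base at a time,
alternating ends within the block, until the target Tm (primer Tm + 5 °C
short class, + 15 °C long class) is met or the block is exhausted; the
achieved Tm is reported either way. Growing short and long designs along
the same path guarantees the long oligo is an extension of the short one
at the same locus. When the geometry is impossible the result carries an
explicit reason instead of a design.

## In-silico PCR

Primer scanning is an exhaustive IUPAC-aware comparison of both strands
with default stringency max 2 total mismatches and zero mismatches in the
3'-terminal 5 bases. Amplicons pair every plus-strand forward hit with
every downstream minus-strand reverse hit (all pairings reported — no
"shortest product wins" heuristic); product length runs from forward 5'
end to reverse 5' end inclusive. Clamp outcome is binary with
`block_max_mismatch = 0` by default, reflecting the evidence that a single
mismatch destabilizes PNA/DNA hybrids; users studying partial blocking can
raise it. Pool composition is deterministic weight bookkeeping over
amplifiable templates — no PCR-efficiency, cycle, chimera or read-merging
simulation. In particular the real-world artifact where over-long host
amplicons fail Illumina read merging (and so vanish bioinformatically
while still consuming reagents) is out of scope; the amplicon-length
asymmetry itself is modelled and tested.

## Mock-community math

Marker copies per µL are computed as
`conc / (genome_bp × m_bp) × copies_per_genome` with
`m_bp = 650 g·mol⁻¹ / N_A = 1.0794×10⁻¹² ng` per bp (configurable).
Balanced recipes put `target_copies` from each member into the mix;
unbalanced recipes scale volumes to arbitrary target fractions. The
observed-vs-expected comparison harmonizes taxa (unexpected observed taxa
pool into "other"), reports per-taxon log2 ratios with a pseudo-fraction
(default 10⁻⁶) for zeros, an L1 distance in [0, 2], and the list of
expected-but-undetected taxa. Ploidy corrections and fungal ITS
copy-number databases are out of scope; final qPCR-based trimming of a
real mix is wet-lab work with nothing to compute.

## Synthetic panels

The fixture generator emulates the structure the method exploits: a host
locus with an optional host-specific insertion (default 320 bp, the scale
seen in real organellar loci — microbial rows carry gaps there, and host
amplicons come out exactly that much longer), a planted 17-nt clamp site
that is 100% host-conserved, guideline-compliant (sampled
pyrimidine-leaning and rejection-checked), and divergent from every
microbial row by a forced minimum of 5 substitutions; primer sites
embedded exactly once per template (verified, regenerated on collision);
host background divergence 2% per site and microbial 10% per site outside
the protected features. These defaults are chosen to resemble a realistic
design scenario: near-identical host references, congeneric-to-confamilial
microbial divergence, one clearly best clamp site. All randomness flows
from one integer seed through a single numpy Generator; identical seeds
give byte-identical panels.

What the fixtures do **not** emulate: sequencing error, chimeras, indel
polymorphism outside the single insertion, phylogenetic correlation among
microbes (rows are i.i.d. draws around one ancestor), or compositional
bias in real reference databases. Passing the recovery tests therefore
shows the algorithm finds the right site when one exists by construction;
it does not certify performance on taxonomically skewed reference panels.

Recovery test panels set `insertion_length = 0` on purpose: with an
insertion present, windows inside it score mismatch = clamp length against
every microbe and legitimately outrank any planted site — the correct
behaviour for the method, but useless as a recovery check of a planted
optimum. Insertion panels are exercised separately for the
amplicon-length-asymmetry property.

## Problem sizes and determinism

The shipped verification runs at desk scale: 20 recovery panels of 60–800
alignment columns with 4 host and 10 microbial rows, 100-case randomized
brute-force equivalence suites (self-complementarity, primer scanning,
candidate enumeration, summary extremes), 17-member mock panels with 10
unbalanced round-trips. `scripts/acceptance.py` recomputes everything from
scratch from a single `--seed`; the bundled wheat-leaf read counts and the
published oligomer panel are fixed reference inputs, not recomputed
quantities.

## Known limitations

- No duplex-with-mismatch ΔG or secondary-structure folding energies; the
  mismatch count is a proxy for destabilization, not a free-energy model.
- No thermodynamic competition between clamp and primer at shared sites;
  competitive designs are validated geometrically.
- No clamp-concentration/efficiency relationship (real optimizations — e.g.
  template dilution improving blocking — are wet-lab territory).
- The tool never aligns; garbage alignments give garbage profiles.
- Reproducing any specific published clamp sequence is a non-goal: choices
  among co-optimal candidates in real studies involve manual judgment the
  ranking deliberately does not imitate.
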