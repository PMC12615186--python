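# clampforge

Design and in-silico validation of PCR clamps — PNAs and C3-spacer blocking
primers — that block host DNA co-amplification in 16S/ITS amplicon
sequencing while sparing the microbial templates the assay is after.

## The problem

Endophyte and other host-associated microbiome surveys amplify a marker
locus (16S rRNA hypervariable regions for bacteria, ITS1/ITS2 for fungi)
from total DNA that is overwhelmingly host-derived. Host organellar loci
(chloroplast 16S, mitochondrial 18S) and the nuclear ITS are homologous
enough to be co-amplified, so sequencing output can be almost entirely host
reads. A PCR clamp fixes this at the chemistry level: an oligomer that
hybridizes inside the host amplicon — either a peptide nucleic acid (PNA),
which polymerases cannot extend, or a conventional blocking primer carrying
a 3' C3 spacer — and stalls host amplification, while carrying enough
mismatches to every microbial homolog to leave microbial amplification
untouched. PNA/DNA duplexes melt higher than the corresponding DNA/DNA
duplexes and are destabilized by a single mismatch, which is exactly what
makes a well-placed clamp both strong and specific.

## The design algorithm

Given a pre-computed multiple alignment of host references and microbial
homologs for the target locus, clampforge:

1. builds a per-column conservation profile (host consensus, host
   conservation fraction, microbial base/gap frequencies);
2. finds maximal host-conserved blocks (default: strict 100% conservation,
   no host gaps) — a clamp must bind every host haplotype;
3. enumerates every candidate window of 12–21 nt on both strands and
   annotates each with the guideline attributes: PNA/DNA Tm (affine
   correlation `Tm_PNA = c0 + c1·Tm_NN + c2·f_pyr + c3·L` over the
   nearest-neighbor DNA/DNA Tm), purine fraction (< 50%), longest purine
   run (≤ 4), self-complementary stretch, and Tm margins over the PCR
   primers and the 72 °C extension step;
4. scores each candidate by its mismatch count against every microbial row
   (a microbial gap under the clamp — e.g. a host-specific insertion — is
   the strongest possible mismatch), keeping the minimum over microbes;
5. ranks by minimum mismatches (descending, ≥ 5 recommended), breaking ties
   toward the 80 °C Tm target.

Blocking primers are designed on the same conserved blocks, either
overlapping a PCR primer's binding site (competitive) or strictly between
the two primer sites (elongation arrest), grown base by base to a Tm offset
(+5 °C short class, +15 °C long class) above the PCR primers.

The companion modules provide IUPAC-aware in-silico PCR (degenerate primer
scanning, amplicon prediction, per-template blocked/amplifiable calls, pool
composition), mock-community copy-number normalization
(`copies/µL = conc / (genome_bp × 1.0794·10⁻¹² ng) × copies_per_genome`,
with balanced/unbalanced pipetting recipes and observed-vs-expected
comparison), host-vs-microbial read-fraction reporting, and a seeded
synthetic panel generator with planted ground truth.

## Worked example

```python
from clampforge import (FixtureSpec, simulate_panel, MultipleAlignment,
                        build_profile, DesignConstraints, PrimerPair, design_pna)
from clampforge import wheat_panel

records, truth = simulate_panel(FixtureSpec(seed=1, insertion_length=0,
                                            locus_length=300))
profile = build_profile(MultipleAlignment(tuple(records)))
pair = PrimerPair(wheat_panel.PRIMERS["799F"], wheat_panel.PRIMERS["1193R"])
ranked = design_pna(profile, DesignConstraints(), primer_pair=pair)
top = ranked[0]
print(top.sequence, top.alignment_interval, top.min_microbe_mismatches,
      round(top.tm_pna, 1))
print(truth.planted_columns)
```

prints

```
GGAGGCACAGAGGGATAGGGA (22, 43) 5 76.6
(24, 41)
```

i.e. the top-ranked candidate is a 21-mer (reverse-complement strand,
alignment columns 22–43) covering the clamp site planted at columns 24–41
in the synthetic panel, divergent from every microbial row by at least 5
mismatches, with a predicted PNA/DNA Tm of 76.6 °C — among the co-optimal
windows over the planted site, ranking favours the one nearest the 80 °C
target. The same flow works on a real aligned FASTA via
`clampforge design-pna --alignment aln.fasta --roles roles.tsv ...`.

On the bundled wheat-leaf read counts:

```python
from clampforge import read_fraction_report
from clampforge.wheat_panel import BACTERIAL_READ_COUNTS
rep = read_fraction_report(BACTERIAL_READ_COUNTS)
print(rep["V5V7/PNA_V5V7"].microbial_percent_1dp)   # 99.8
```

— with the V5V7 PNA in the reaction, 99.8% of reads are bacterial (231
host vs 104,078 bacterial reads).

## Layout

- `seq_core` — IUPAC algebra, composition metrics, FASTA/role I/O
- `alignment_profile` — conservation profiles, conserved blocks, coordinates
- `thermo` — nearest-neighbor DNA/DNA Tm and the PNA/DNA Tm correlation
- `clamp_design` — candidate enumeration, scoring, ranking, blocking primers
- `insilico_pcr` — primer scanning, amplicon prediction, clamp outcomes
- `mock_community` — copy-number normalization and recipe math
- `fixtures` — seeded synthetic panels with planted ground truth
- `reporting` / `cli` — read-fraction reports and the `clampforge` CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
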