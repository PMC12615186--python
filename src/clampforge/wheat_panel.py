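"""Published wheat (Triticum aestivum) clamping panel: oligos and read counts.

The toolkit was developed around a published set of PCR clamps that block
wheat organellar 16S/18S and nuclear ITS co-amplification in endophyte
metabarcoding.  The oligomer sequences and the per-condition read counts of
that study's wheat-leaf assay are bundled here as reference inputs: they
drive the guideline-compliance screen (the printed designs themselves bend
a couple of the stated guidelines) and the host-vs-microbial read-fraction
arithmetic.
"""

from __future__ import annotations

from .seq_core import Oligo, OligoKind

__all__ = [
    "PRIMERS",
    "PRIMER_PAIRS",
    "BLOCKING_PRIMERS",
    "PNAS",
    "BACTERIAL_READ_COUNTS",
    "FUNGAL_READ_COUNTS",
]

#: Traditional PCR primers, 5'->3', IUPAC-degenerate.
PRIMERS: dict[str, Oligo] = {
    name: Oligo(name=name, sequence=seq, kind=OligoKind.PCR_PRIMER)
    for name, seq in {
        "799F": "AACMGGATTAGATACCCKG",
        "1193R": "ACGTCATCCCCACCTTCC",
        "515F": "GTGCCAGCMGCCGCGGTAA",
        "806R": "GGACTACHVGGGTWTCTAAT",
        "ITS1": "TCCGTAGGTGAACCTGCGG",
        "58A2R": "CTGCGTTCTTCATCGAT",
        "18SF": "GTAAAAGTCGTAACAAGGTTTC",
        "ITS2_KYO2": "TTYRCTRCGTTCTTCATC",
        "gITS7ngs": "GTGARTCATCRARTYTTTG",
        "ITS4ngsUni": "CCTSCSCTTANTDATATGC",
        "fITS9": "GAACACAGCGAAATGTGA",
        "ITS4-Fun": "AGCCTCCGCTTATTGATATGCTTAART",
    }.items()
}

#: (forward, reverse) primer names per assayed marker region.
PRIMER_PAIRS: dict[str, tuple[str, str]] = {
    "16S_V5V7": ("799F", "1193R"),
    "16S_V4": ("515F", "806R"),
    "ITS1_a": ("ITS1", "58A2R"),
    "ITS1_b": ("18SF", "ITS2_KYO2"),
    "ITS2_a": ("gITS7ngs", "ITS4ngsUni"),
    "ITS2_b": ("fITS9", "ITS4-Fun"),
}

#: C3-spacer blocking primers for the 16S V5V7 assay.  *_1* compete with the
#: reverse primer for its binding site; *_2* arrest elongation mid-amplicon.
#: S/L = short/long design (larger Tm offset from the PCR primers).
BLOCKING_PRIMERS: dict[str, Oligo] = {
    name: Oligo(name=name, sequence=seq, kind=OligoKind.BLOCKING_PRIMER,
                three_prime_block=True)
    for name, seq in {
        "BL_V5V7_1S": "GGACTGCCAGTGAGATACTGGAG",
        "BL_V5V7_2S": "AAAGGTGCGTGCCGCA",
        "BL_V5V7_1L": "CTCACGAGGGACTGCCAGTGAGATACTGGAGGAAGG",
        "BL_V5V7_2L": "CGCTCCGAAACAAAGAAAAAGGTGCGTGCCGCA",
    }.items()
}

#: PNA clamps (no C3 spacer: a PNA is inherently non-extendable).
PNAS: dict[str, Oligo] = {
    name: Oligo(name=name, sequence=seq, kind=OligoKind.PNA)
    for name, seq in {
        "PNA_V5V7": "CCCACGGAGACCTACCT",
        "PNA_V4chloro": "GCGTCTGTAGGTGGCTTTTC",
        "PNA_V4mito": "CGGAATGCTCTCGAAACC",
        "PNA_ITS1": "CTATTTAATCCACACGACTCTCGG",
        "PNA_ITS2": "CGGCATCTGGTCCCTCGTCTC",
    }.items()
}

#: Wheat-leaf bacterial assay read counts per blocking condition:
#: host chloroplast (c) and mitochondrial (m) reads vs microbial reads.
BACTERIAL_READ_COUNTS: dict[str, dict[str, int]] = {
    # 16S V5V7, 799F/1193R
    "V5V7/no_blocking": {"host_chloroplast": 5, "host_mitochondrial": 32754, "microbial": 12163},
    "V5V7/BL_V5V7_1S": {"host_chloroplast": 7, "host_mitochondrial": 16830, "microbial": 51824},
    "V5V7/BL_V5V7_1L": {"host_chloroplast": 5, "host_mitochondrial": 29075, "microbial": 58373},
    "V5V7/BL_V5V7_2S": {"host_chloroplast": 9, "host_mitochondrial": 1956, "microbial": 107240},
    "V5V7/BL_V5V7_2L": {"host_chloroplast": 5, "host_mitochondrial": 1988, "microbial": 96726},
    "V5V7/PNA_V5V7": {"host_chloroplast": 2, "host_mitochondrial": 229, "microbial": 104078},
    # 16S V4, 515F/806R
    "V4/no_blocking": {"host_chloroplast": 58505, "host_mitochondrial": 8749, "microbial": 48},
    "V4/PNA_V4chloro": {"host_chloroplast": 28572, "host_mitochondrial": 22378, "microbial": 24567},
    "V4/PNA_V4mito": {"host_chloroplast": 68645, "host_mitochondrial": 941, "microbial": 9652},
    "V4/PNA_V4chloro+PNA_V4mito": {"host_chloroplast": 7141, "host_mitochondrial": 4450, "microbial": 47404},
}

#: Wheat-leaf fungal assay read counts (host nuclear ITS vs fungal reads).
FUNGAL_READ_COUNTS: dict[str, dict[str, int]] = {
    "ITS1:18SF/ITS2_KYO2/no_blocking": {"host_nuclear": 34684, "microbial": 5},
    "ITS1:18SF/ITS2_KYO2/PNA_ITS1": {"host_nuclear": 13796, "microbial": 26269},
    "ITS1:ITS1/58A2R/no_blocking": {"host_nuclear": 66877, "microbial": 3623},
    "ITS1:ITS1/58A2R/PNA_ITS1": {"host_nuclear": 1738, "microbial": 32752},
    "ITS2:gITS7ngs/ITS4ngsUni/no_blocking": {"host_nuclear": 53355, "microbial": 16},
    "ITS2:gITS7ngs/ITS4ngsUni/PNA_ITS2": {"host_nuclear": 6631, "microbial": 21297},
    "ITS2:fITS9/ITS4-Fun/no_blocking": {"host_nuclear": 51278, "microbial": 1769},
    "ITS2:fITS9/ITS4-Fun/PNA_ITS2": {"host_nuclear": 4966, "microbial": 14308},
}
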