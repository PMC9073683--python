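"""Published worked-example sequences, packaged as string fixtures.

These are the reference sequences used in the experimental characterization
of spaced AAAG/ACGT element pairs:

* ``MPS`` — the 139-nt minimal promoter sequence that provides basal
  transcription in transient-expression assays; spacer candidates are
  evaluated for transcription-factor binding sites against this baseline.
* ``SPACER_24_EXAMPLE`` — an AAAG-first pair whose 24-nt spacer carries the
  largest number of predicted binding sites.
* ``SPACER_14_EXAMPLE`` — the reciprocal ACGT-first pair with a 14-nt spacer.
* ``CLONING_INSERT`` — the 50-nt random insert, flanked by BamHI sites
  (GGATCC) on both ends, used when assembling promoter-reporter cassettes.
"""

MPS = (
    "TCACTATATATAGGAAGTTCATTTCATTTGGAATGGACACGTGTTGTCATTTCTCAACAATTACCAACAAC"
    "AACAAACAACAAACAACATTATACAATTACTATTTACAATTACATCTAGATAAACAATGGCTTCCTCC"
)
assert len(MPS) == 139

SPACER_24 = "TTGGGCTTTCAAAATTGTTAACTC"
SPACER_24_EXAMPLE = "AAAG" + SPACER_24 + "ACGT"

SPACER_14 = "GGATGCTATTATTA"
SPACER_14_EXAMPLE = "ACGT" + SPACER_14 + "AAAG"
assert SPACER_14_EXAMPLE == "ACGTGGATGCTATTATTAAAAG"

# printed with its BamHI flanks; the random core is the inner 50 nt
CLONING_INSERT = "GGATCCGGCTATGGCGGAGCAAGATTCACTCTGCGAGGCCAAAGCTTACCCCGGAAGGATCC"
CLONING_INSERT_CORE = CLONING_INSERT[6:-6]
assert len(CLONING_INSERT_CORE) == 50

ALL_FIXTURES = {
    "MPS": MPS,
    "SPACER_24_EXAMPLE": SPACER_24_EXAMPLE,
    "SPACER_14_EXAMPLE": SPACER_14_EXAMPLE,
    "CLONING_INSERT": CLONING_INSERT,
}
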