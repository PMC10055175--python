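"""Synthetic worked-example fixtures.

The transcript built here is a synthetic stand-in shaped like the mouse
Tmem249 (Catsperq) mRNA: the annotated ATG-initiated ORF is 171 codons
(matching the annotated CATSPERtheta protein of NCBI record NP_001365176),
and an in-frame CTG sits 213 nt upstream in the 5'-UTR with no intervening
in-frame stop and a preferred Kozak context (A at -3, G at +4).  Initiating
at the CTG therefore extends the N terminus by 71 residues, for a 242-aa
protein.  Only these documented coordinates are biological; the filler
sequence itself is synthetic, not the GenBank sequence.
"""

from __future__ import annotations

from .orf import AnnotatedTranscript

__all__ = ["catsperq_like_transcript"]

#: annotated protein length (aa) of the short, ATG-initiated form
ANNOTATED_ORF_CODONS = 171
#: codons gained by initiating at the upstream in-frame CTG
EXTENSION_CODONS = 71


def catsperq_like_transcript() -> AnnotatedTranscript:
    """Build the synthetic CATSPERtheta-like transcript fixture.

    Layout (0-based offsets):

    * 8 nt of 5'-UTR, with an A placed 3 nt before the CTG;
    * CTG at offset 8, followed by 70 GCC codons (no stop, +4 base = G);
    * ATG at offset 221 (= 8 + 3*71), followed by 170 GAA codons;
    * TAA stop, then a short 3' trailer.
    """
    utr = "CCCCC" + "A" + "CC"  # A at position 5 = CTG offset - 3
    ctg_block = "CTG" + "GCC" * (EXTENSION_CODONS - 1)  # first GCC puts G at +4
    orf = "ATG" + "GAA" * (ANNOTATED_ORF_CODONS - 1)
    sequence = utr + ctg_block + orf + "TAA" + "CCCCCC"
    return AnnotatedTranscript(
        transcript_id="Catsperq_like_synthetic",
        sequence=sequence,
        cds_start=len(utr) + len(ctg_block),
        orf_len_codons=ANNOTATED_ORF_CODONS,
    )
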