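"""The published 16-gene 8-pair breast cancer prognosis signature.

The published 8-TSP classifier (vote threshold 2) was trained on the
78-patient discovery cohort of the 70-gene MammaPrint signature and
uses 16 of its 70 genes.  Four pairs each combine one gene whose
expression was originally associated with good prognosis with one
associated with recurrence; the other four pairs consist of
recurrence-associated genes only.

Only the member gene lists were published in machine-readable form;
the exact partner assignments within each group of pairs appear only
in a figure, so the pairings are deliberately left unknown here rather
than guessed.  Use :func:`signature_genes` for the flat gene set.
"""

from __future__ import annotations

PUBLISHED_K = 8
PUBLISHED_THRESHOLD = 2

#: Four pairs combine one good-prognosis-associated gene ...
GOOD_PROGNOSIS_PARTNERS = ("RTN4RL1", "LGP2", "MS4A7", "GSTM3")
#: ... with one recurrence-associated gene:
POOR_PROGNOSIS_PARTNERS = ("OXCT1", "HRASLS", "Contig40831_RC", "MELK")
#: The remaining four pairs draw both genes from this recurrence-associated set:
POOR_ONLY_PAIR_GENES = (
    "GPR180",
    "DTL",
    "IGFBP5",
    "SERF1A",
    "GNAZ",
    "RFC4",
    "CDCA7",
    "UCHL5",
)

#: Within-pair partner assignments were not published in text form.
PAIRINGS_KNOWN = False


def signature_genes() -> list[str]:
    """All distinct genes of the published 8-pair signature, sorted."""
    genes = set(GOOD_PROGNOSIS_PARTNERS) | set(POOR_PROGNOSIS_PARTNERS) | set(
        POOR_ONLY_PAIR_GENES
    )
    return sorted(genes)
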