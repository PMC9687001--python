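"""Experimental design constants for sucrose-gradient polysome profiling.

The gradient is collected as ten equal-volume fractions F1 (lightest, free
RNA) to F10 (heaviest polysomes).  The analysis partition is fixed by the
biology of the gradient and is never inferred from data:

* F1-F2   free RNA (excluded from translatome statistics)
* F3-F5   monosome-bound mRNA
* F6-F7   intermediate
* F8-F10  polysome-bound mRNA

rRNA-based QC calls (see :mod:`polymodes.qc`) are evidence that the gradient
worked; they warn on mismatch but never move this partition.
"""

STAGES = ("GV", "MII", "2C", "8C", "MOR", "BL")
"""Developmental stages in order: germinal-vesicle and metaphase-II oocytes,
two-cell, eight-cell, morula and blastocyst embryos."""

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

FRACTIONS = tuple(range(1, 11))
FREE_FRACTIONS = (1, 2)
MONOSOME_FRACTIONS = (3, 4, 5)
INTERMEDIATE_FRACTIONS = (6, 7)
POLYSOME_FRACTIONS = (8, 9, 10)
GRADIENT_FRACTIONS = tuple(range(3, 11))  # F3-F10, used for gradient stats

SAMPLE_TYPES = ("fraction", "transcriptome")


def fraction_role(fraction: int) -> str:
    """Analysis-partition role of a fraction index (1-10)."""
    if fraction in FREE_FRACTIONS:
        return "free"
    if fraction in MONOSOME_FRACTIONS:
        return "monosome"
    if fraction in INTERMEDIATE_FRACTIONS:
        return "intermediate"
    if fraction in POLYSOME_FRACTIONS:
        return "polysome"
    raise ValueError(f"fraction index out of range 1-10: {fraction}")
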