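"""The 96 trinucleotide substitution categories.

Single-base substitutions are reported on the pyrimidine strand: a mutation
whose reference base is a purine is reverse-complemented (alleles and flanking
bases) before classification. This yields 6 substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) x 16 flanking-base combinations = 96
categories, labelled ``"X[R>A]Y"`` where X/Y are the 5'/3' neighbours.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")

#: the six pyrimidine-strand substitution classes, in conventional order
SUBSTITUTIONS = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

#: canonical ordering of the 96 category labels (class-major, then 5' then 3')
CONTEXT_LABELS = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def context_label(ref: str, alt: str, context3: str) -> str | None:
    """Map an SNV (ref, alt, trinucleotide context) to its 96-category label.

    Returns ``None`` when the inputs do not describe a classifiable SNV:
    non-single-base alleles, alleles outside ACGT, a context that is not a
    3-mer over ACGT, or a context whose middle base disagrees with ``ref``.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        return None
    if ref == alt:
        return None
    if not isinstance(context3, str) or len(context3) != 3:
        return None
    context3 = context3.upper()
    if any(b not in BASES for b in context3):
        return None
    if context3[1] != ref:
        return None
    if ref in ("A", "G"):  # purine strand: flip to the pyrimidine convention
        ref = revcomp(ref)
        alt = revcomp(alt)
        context3 = revcomp(context3)
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"
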