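"""Trinucleotide-context conventions for single-base substitutions.

Somatic SNVs are classified into the 96 pyrimidine-centred channels used by
the COSMIC SBS catalogs: 6 substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
times 16 flanking-base combinations.  Substitutions reported on the purine
strand are reverse-complemented onto the pyrimidine strand.
"""
from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = frozenset("CT")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical channel order: substitution-major, flanks lexicographic.
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


class ReferenceMismatchError(ValueError):
    """The reference FASTA base does not match the variant's REF allele."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_from_triplet(triplet: str, alt: str) -> str:
    """Map a plus-strand reference trinucleotide plus ALT base to a channel.

    ``triplet`` is the three reference bases centred on the mutated
    position; the centre base is the REF allele.  Purine-centred triplets
    are reverse-complemented.
    """
    triplet = triplet.upper()
    alt = alt.upper()
    if len(triplet) != 3:
        raise ValueError(f"need a trinucleotide, got {triplet!r}")
    ref = triplet[1]
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref not in PYRIMIDINES:
        triplet = revcomp(triplet)
        ref = triplet[1]
        alt = COMPLEMENT[alt]
    label = f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"
    if label not in CONTEXT_INDEX:
        raise ValueError(f"invalid channel {label!r}")
    return label


def _contig_length(fasta, contig) -> int:
    seq = fasta[contig]
    return len(seq)


def _fetch_triplet(fasta, contig: str, pos: int) -> str:
    """Return the reference trinucleotide around 1-based position ``pos``."""
    seq = fasta[contig]
    piece = seq[pos - 2 : pos + 1]
    return str(piece).upper()


def trinucleotide_context(fasta, contig: str, pos: int, ref: str, alt: str) -> str:
    """Classify the SNV ``contig:pos ref>alt`` into one of the 96 channels.

    ``fasta`` may be any mapping from contig name to a sliceable sequence
    (``dict`` of strings, :class:`pyfaidx.Fasta`, ...).  ``pos`` is 1-based.
    Raises :class:`ReferenceMismatchError` when the FASTA base differs from
    ``ref`` and from its complement, and :class:`ValueError` for non-SNVs or
    positions lacking a flanking base.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("trinucleotide context is defined for SNVs only")
    if pos < 2:
        raise ValueError(f"position {pos} has no 5' flanking base")
    if pos >= _contig_length(fasta, contig):
        raise ValueError(f"position {pos} has no 3' flanking base on {contig}")
    triplet = _fetch_triplet(fasta, contig, pos)
    centre = triplet[1]
    if centre != ref.upper():
        if centre == COMPLEMENT[ref.upper()]:
            # Variant reported on the opposite strand of the FASTA.
            triplet = revcomp(triplet)
            return channel_from_triplet(triplet, alt)
        raise ReferenceMismatchError(
            f"{contig}:{pos} FASTA base {centre!r} != ref {ref!r}"
        )
    return channel_from_triplet(triplet, alt)
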