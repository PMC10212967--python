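"""Canonical variant representation, normalization, and cross-caller match keys.

Coordinates are 1-based and inclusive throughout, exactly as in VCF; they are
never converted internally.  Alleles are upper-cased on ingest and compared
case-insensitively.  Normalization is: parsimony-trim shared suffix/prefix,
decompose multi-nucleotide substitutions into per-base SNVs, and (when a
reference sequence is available) left-align indels to their leftmost
equivalent representation, anchored on one preceding reference base in
standard VCF style.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Protocol

from .errors import ContextError, InvalidVariantError, ReferenceMismatchError

__all__ = [
    "SNV",
    "INDEL",
    "MNV",
    "GenomicVariant",
    "VariantKey",
    "ReferenceSource",
    "DictReference",
    "classify_alleles",
    "trim_alleles",
    "left_align",
    "normalize_alleles",
    "make_key",
]

SNV = "SNV"
INDEL = "INDEL"
MNV = "MNV"

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class ReferenceSource(Protocol):
    """Anything that can serve reference bases (pysam.FastaFile satisfies this)."""

    def fetch(self, reference: str, start: int, end: int) -> str:
        """Return bases for 0-based half-open [start, end) on contig *reference*."""
        ...


class DictReference:
    """In-memory reference backed by a ``{contig: sequence}`` mapping.

    Useful for tests and for small reference windows; mirrors the
    ``pysam.FastaFile.fetch`` signature.
    """

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    def fetch(self, reference: str, start: int, end: int) -> str:
        try:
            seq = self._contigs[reference]
        except KeyError:
            raise ContextError(f"contig {reference!r} not in reference") from None
        if start < 0 or end > len(seq):
            raise ContextError(
                f"window [{start}, {end}) outside contig {reference!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


def classify_alleles(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV, INDEL, or MNV."""
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(ref) != len(alt):
        return INDEL
    return MNV


class VariantKey(NamedTuple):
    """Normalized identity used to match the same event across callers.

    Equality of keys is equality of the normalized
    (chrom, pos, ref, alt) tuple.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenomicVariant:
    """One allele change as parsed from a caller VCF.

    ``alt_depth``, ``total_depth`` and ``vaf`` are ``None`` when unknown;
    they are never guessed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    caller_id: str = ""
    filter_status: str = "."
    alt_depth: int | None = None
    total_depth: int | None = None
    vaf: float | None = None
    variant_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        _validate_alleles(self.ref, self.alt)
        if self.pos < 1:
            raise InvalidVariantError(f"pos must be >= 1, got {self.pos}")
        if self.alt_depth is not None and self.alt_depth < 0:
            raise InvalidVariantError("alt_depth must be non-negative")
        if self.total_depth is not None and self.total_depth < 0:
            raise InvalidVariantError("total_depth must be non-negative")
        if (
            self.alt_depth is not None
            and self.total_depth is not None
            and self.alt_depth > self.total_depth
        ):
            raise InvalidVariantError("alt_depth exceeds total_depth")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise InvalidVariantError(f"vaf must be in [0, 1], got {self.vaf}")
        if not self.variant_class:
            object.__setattr__(
                self, "variant_class", classify_alleles(self.ref, self.alt)
            )

    @property
    def key(self) -> VariantKey:
        return make_key(self)


def _validate_alleles(ref: str, alt: str, line: int | None = None) -> None:
    if not ref or not alt:
        raise InvalidVariantError("empty allele", line=line)
    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
        raise InvalidVariantError(f"non-ACGTN allele {ref!r}>{alt!r}", line=line)
    if ref == alt:
        raise InvalidVariantError(f"ref equals alt ({ref!r})", line=line)


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove the shared suffix, then the shared prefix, of an allele pair.

    Position advances one base per removed prefix base.  Both output alleles
    keep at least one base.  Idempotent.
    """
    _validate_alleles(ref, alt)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: ReferenceSource,
) -> tuple[int, str, str]:
    """Shift a trimmed indel to its leftmost equivalent VCF representation.

    SNVs and MNVs are returned unchanged.  The returned indel is anchored on
    one preceding reference base whenever the alleles share an end base, i.e.
    the standard parsimonious left-aligned form.  Raises
    :class:`ReferenceMismatchError` if *ref* disagrees with the reference and
    :class:`ContextError` if the contig start is reached while context is
    still needed.
    """
    pos, ref, alt = trim_alleles(pos, ref, alt)
    if classify_alleles(ref, alt) != INDEL:
        return pos, ref, alt

    window = reference.fetch(chrom, pos - 1, pos - 1 + len(ref))
    if window.upper() != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF {ref!r} != reference {window.upper()!r}"
        )

    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos <= 1:
                # indel abuts the contig start: anchor on the following
                # reference base instead (standard VCF telomere form)
                base = reference.fetch(chrom, len(ref), len(ref) + 1).upper()
                ref, alt = ref + base, alt + base
                break
            base = reference.fetch(chrom, pos - 2, pos - 1).upper()
            ref, alt = base + ref, base + alt
            pos -= 1
            continue
        if ref[-1] != alt[-1]:
            break
        if len(ref) == 1 and len(alt) == 1:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_alleles(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: ReferenceSource | None = None,
) -> list[tuple[int, str, str]]:
    """Normalize one (pos, ref, alt) into its atomic components.

    Alleles are upper-cased and trimmed.  Multi-nucleotide substitutions are
    decomposed into per-base SNVs at each mismatching position (the SNV/indel
    dichotomy has no MNV category, so they are kept in the SNV stream).
    Indels are left-aligned when a reference is supplied.  Returns a list of
    (pos, ref, alt) tuples, each of which is SNV or INDEL, never MNV.
    """
    ref = ref.upper()
    alt = alt.upper()
    pos, ref, alt = trim_alleles(pos, ref, alt)
    cls = classify_alleles(ref, alt)
    if cls == MNV:
        return [
            (pos + i, r, a)
            for i, (r, a) in enumerate(zip(ref, alt))
            if r != a
        ]
    if cls == INDEL and reference is not None:
        return [left_align(chrom, pos, ref, alt, reference)]
    return [(pos, ref, alt)]


def make_key(variant: GenomicVariant) -> VariantKey:
    """Build the match key of an already-normalized variant.

    Raises :class:`InvalidVariantError` if the variant is not in normalized
    form (untrimmed alleles or a surviving MNV): keys of un-normalized
    variants would silently fail to match across callers.
    """
    trimmed = trim_alleles(variant.pos, variant.ref, variant.alt)
    if trimmed != (variant.pos, variant.ref, variant.alt):
        raise InvalidVariantError(
            f"variant {variant.chrom}:{variant.pos}:{variant.ref}>{variant.alt} "
            "is not trimmed; normalize before keying"
        )
    if variant.variant_class == MNV:
        raise InvalidVariantError(
            "MNVs must be decomposed into SNVs before keying"
        )
    return VariantKey(variant.chrom, variant.pos, variant.ref, variant.alt)


def normalize_variant(
    variant: GenomicVariant, reference: ReferenceSource | None = None
) -> list[GenomicVariant]:
    """Return the normalized atomic variants derived from *variant*.

    Support fields and provenance are carried over to every component.
    """
    parts = normalize_alleles(
        variant.chrom, variant.pos, variant.ref, variant.alt, reference
    )
    return [
        GenomicVariant(
            chrom=variant.chrom,
            pos=p,
            ref=r,
            alt=a,
            caller_id=variant.caller_id,
            filter_status=variant.filter_status,
            alt_depth=variant.alt_depth,
            total_depth=variant.total_depth,
            vaf=variant.vaf,
        )
        for p, r, a in parts
    ]
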