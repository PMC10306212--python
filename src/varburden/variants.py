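"""Variant representation and normalization.

All variant keys are biallelic: multiallelic VCF records are split into one
key per alternate allele before anything downstream sees them.  Keys use
1-based positions (VCF convention) and are normalized by a reference-free
trim so that the same underlying edit always maps to the same key whether it
came from the case VCF or a control summary row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

ALLELE_ALPHABET = frozenset("ACGTN")

#: Predicted loss-of-function consequence classes counted as "high impact".
HIGH_IMPACT_CONSEQUENCES = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
    }
)

#: Controlled vocabulary of consequence terms the pipeline understands.
CONSEQUENCE_VOCABULARY = HIGH_IMPACT_CONSEQUENCES | frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "splice_region_variant",
        "inframe_insertion",
        "inframe_deletion",
        "stop_retained_variant",
        "intron_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intergenic_variant",
    }
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single biallelic variant: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        for allele in (self.ref, self.alt):
            if not set(allele) <= ALLELE_ALPHABET:
                raise ValueError(f"allele {allele!r} outside alphabet ACGTN")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")

    def __str__(self) -> str:  # chrom:pos:ref:alt, used in all file outputs
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


def normalize_variant(key: VariantKey) -> VariantKey:
    """Trim shared allele bases to a minimal, unique representation.

    Shared trailing bases are removed while both alleles keep length > 1,
    then shared leading bases are removed under the same constraint, with the
    position advancing one base per trimmed leading base.  The operation is
    idempotent and never needs the reference genome: indel keys stay anchored
    on their final shared leading base.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (key.ref, key.alt, key.pos):
        return key
    return VariantKey(key.chrom, pos, ref, alt)


def split_multiallelic(
    chrom: str, pos: int, ref: str, alts: tuple[str, ...]
) -> list[tuple[int, VariantKey]]:
    """Split a (possibly multiallelic) record into normalized biallelic keys.

    Returns ``(alt_index, key)`` pairs where ``alt_index`` is the 1-based GT
    allele index of the alternate allele in the original record.  Symbolic
    alleles (``<DEL>`` etc.) and spanning-deletion placeholders (``*``) are
    skipped: they carry no sequence to normalize or count.
    """
    out: list[tuple[int, VariantKey]] = []
    for i, alt in enumerate(alts, start=1):
        if alt == "*" or alt.startswith("<") or alt == ref:
            continue
        out.append((i, normalize_variant(VariantKey(chrom, pos, ref, alt))))
    return out


@dataclass(frozen=True)
class AnnotatedVariant:
    """A normalized biallelic variant with the annotations the filters need.

    ``af_by_source`` maps an allele-frequency source name (for example
    ``af_gnomad_nfe`` or ``af_alfa_eur``) to a frequency in [0, 1].  A variant
    absent from every frequency database has an empty map and is treated
    downstream as frequency 0 (novel).
    """

    key: VariantKey
    gene: str
    consequence: str
    cadd_phred: float
    af_by_source: Mapping[str, float] = field(default_factory=dict)
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.cadd_phred < 0:
            raise ValueError("CADD Phred score must be non-negative")
        for source, af in self.af_by_source.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} from {source} outside [0, 1]")
        if self.consequence not in CONSEQUENCE_VOCABULARY:
            warnings.warn(
                f"unknown consequence term {self.consequence!r}; treated as non-impact",
                stacklevel=2,
            )
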