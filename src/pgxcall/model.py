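"""Core domain types shared across the package.

Coordinates are 1-based GRCh38 throughout, matching VCF conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The nine biogeographic groups used to stratify allele frequencies
#: (African American/Afro-Caribbean, American, Central/South Asian,
#: East Asian, European, Latino, Near Eastern, Oceanian, Sub-Saharan
#: African).
BIOGEOGRAPHIC_GROUPS: tuple[str, ...] = (
    "AAC", "AME", "SAS", "EAS", "EUR", "LAT", "NEA", "OCE", "SSA",
)


class PgxError(Exception):
    """Base class for all package errors."""


class UsageError(PgxError):
    """A caller violated a documented precondition."""


class SchemaError(PgxError):
    """A knowledgebase file does not conform to its schema."""


class InputError(PgxError):
    """A user-supplied input file is unreadable or malformed."""


class StateError(PgxError):
    """An internal contract was violated (e.g. unfilled frequency null)."""


class TemplateError(PgxError):
    """A report template is missing a required block."""


def validate_group(code: str) -> str:
    """Return ``code`` if it is one of the nine biogeographic groups.

    Raises
    ------
    UsageError
        If the code is not admissible; the message lists the nine codes.
    """
    if code not in BIOGEOGRAPHIC_GROUPS:
        raise UsageError(
            f"unknown biogeographic group {code!r}; expected one of "
            + ", ".join(BIOGEOGRAPHIC_GROUPS)
        )
    return code


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalized genomic variant (left-aligned, parsimonious).

    ``ref`` and ``alt`` are uppercase allele strings; ``position`` is the
    1-based coordinate of the first ref base after normalization.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    rsid: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise UsageError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise UsageError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise UsageError(f"non-variant record: ref == alt ({self.ref})")

    @property
    def locus(self) -> tuple[str, int]:
        """(chromosome, position) pair identifying the site."""
        return (self.chromosome, self.position)


def normalize_variant(
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    rsid: Optional[str] = None,
) -> VariantKey:
    """Left-align and trim a variant to its parsimonious representation.

    The shared suffix is trimmed first, then the shared prefix with the
    position advanced accordingly; at least one base is kept on each
    side.  SNVs are returned unchanged.  Idempotent.

    Raises
    ------
    UsageError
        If ref equals alt (before or after trimming), or either is empty.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise UsageError("ref and alt must be non-empty")
    if ref == alt:
        raise UsageError(f"non-variant record at {chromosome}:{position}")
    # trim shared suffix, keeping >= 1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    # trim shared prefix, advancing position
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        position += 1
    if ref == alt:  # cannot happen after the guards above, but be safe
        raise UsageError(f"non-variant record at {chromosome}:{position}")
    return VariantKey(chromosome, position, ref, alt, rsid)
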