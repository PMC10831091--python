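"""Domain types for MuTect2-dialect somatic variant calls.

A :class:`VariantCall` is one (record, alt allele) pair together with the
per-allele annotations MuTect2 emits.  Missing annotations are represented
by ``None`` -- never by 0 -- so that downstream imputation can distinguish
"absent" from "observed zero".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

_ACGT = frozenset("ACGT")


class Label(str, Enum):
    """Truth label of an FFPE call: present in the matched FF call set or not."""

    TRUE_VARIANT = "TRUE_VARIANT"
    FFPE_ARTIFACT = "FFPE_ARTIFACT"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a called allele: (chrom, 1-based pos, ref, alt).

    Equality is component-wise and instances are hashable, so keys can be
    used directly in the set operations that drive FF/FFPE matching.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ACGT:
                raise ValueError(f"{name} must be a nonempty uppercase ACGT string, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos} ({self.ref})")


@dataclass
class VariantCall:
    """One alt allele of a MuTect2 record with its per-allele annotations.

    ``filter_status`` is the set of FILTER labels on the source record; an
    empty set (or the literal PASS) means the caller passed the site.
    ``ad_inconsistent`` flags records whose AD sum exceeds DP; the values
    are recorded verbatim, never clamped.
    """

    key: VariantKey
    depth: Optional[int] = None
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    f1r2_ref: Optional[int] = None
    f1r2_alt: Optional[int] = None
    f2r1_ref: Optional[int] = None
    f2r1_alt: Optional[int] = None
    mbq_ref: Optional[float] = None
    mbq_alt: Optional[float] = None
    mmq_ref: Optional[float] = None
    mmq_alt: Optional[float] = None
    mfrl_ref: Optional[float] = None
    mfrl_alt: Optional[float] = None
    mpos: Optional[float] = None
    tlod: Optional[float] = None
    ecnt: Optional[int] = None
    popaf: Optional[float] = None
    germq: Optional[float] = None
    seqq: Optional[float] = None
    strandq: Optional[float] = None
    roq: Optional[float] = None
    filter_status: frozenset = field(default_factory=frozenset)
    ad_inconsistent: bool = False

    def __post_init__(self) -> None:
        for name in ("depth", "ad_ref", "ad_alt", "f1r2_ref", "f1r2_alt", "f2r1_ref", "f2r1_alt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        self.filter_status = frozenset(self.filter_status)
        if (
            self.depth is not None
            and self.ad_ref is not None
            and self.ad_alt is not None
            and self.ad_ref + self.ad_alt > self.depth
        ):
            self.ad_inconsistent = True

    @property
    def is_pass(self) -> bool:
        """PASS literal, '.' or an empty FILTER field all count as pass."""
        return self.filter_status <= {"PASS", "."}

    def with_filter(self, labels) -> "VariantCall":
        return replace(self, filter_status=frozenset(labels))


@dataclass(frozen=True)
class LabeledVariant:
    """A VariantCall plus the truth label derived from FF/FFPE matching."""

    call: VariantCall
    label: Label
    sample_id: str = ""
    cancer_type: Optional[str] = None

    @property
    def key(self) -> VariantKey:
        return self.call.key
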