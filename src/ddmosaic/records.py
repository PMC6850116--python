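"""Shared record types: count triples, variants, families, cohorts.

Units convention: every allele/mutant fraction is stored internally as a
fraction in [0, 1].  All I/O (fixtures, TSV reports) uses percent, matching
how clinical mosaicism tables are printed; :func:`pct_to_frac` /
:func:`frac_to_pct` are the only conversion points.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .errors import ParameterError

__all__ = [
    "DropletCounts",
    "AlleleCounts",
    "VariantDescriptor",
    "MemberRecord",
    "SampleResult",
    "FamilyRecord",
    "CohortTable",
    "pct_to_frac",
    "frac_to_pct",
    "round_half_up",
]

#: tissues counted as somatic when deciding parental somatic vs germline-only
SOMATIC_TISSUES = frozenset({"blood", "buccal", "saliva", "hair", "urine", "skin"})
GERMLINE_TISSUES = frozenset({"sperm"})

SANGER_STATUSES = ("het_detected", "weak_signal", "not_detected", "not_tested")


def pct_to_frac(x: float) -> float:
    return x / 100.0


def frac_to_pct(x: float) -> float:
    return x * 100.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how report percentages are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DropletCounts:
    """Mutant / wild-type / non-informative droplet tallies for one assay."""

    mu: int
    wt: int
    na: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "wt", "na"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def informative(self) -> int:
        return self.mu + self.wt

    @property
    def total(self) -> int:
        return self.mu + self.wt + self.na


@dataclass(frozen=True)
class AlleleCounts:
    """Read-level allele tallies from deep amplicon sequencing (~10,000x)."""

    alt_reads: int
    ref_reads: int
    platform_tag: str = "PASM"

    def __post_init__(self) -> None:
        for name in ("alt_reads", "ref_reads"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def depth(self) -> int:
        return self.alt_reads + self.ref_reads


@dataclass(frozen=True)
class VariantDescriptor:
    """hg19-anchored variant with transcript and protein-level names."""

    chrom: str
    pos: str  # 1-based hg19; ranges kept verbatim for multi-base deletions
    ref: str
    alt: str  # empty string for a pure deletion
    cdna: str
    protein: str

    def __post_init__(self) -> None:
        if not self.cdna or not self.protein:
            raise ParameterError("cdna and protein names must be non-empty")


@dataclass
class MemberRecord:
    role: str  # proband / father / mother / sibling / control
    affected: bool = False
    sanger_status: str = "not_tested"

    def __post_init__(self) -> None:
        if self.sanger_status not in SANGER_STATUSES:
            raise ParameterError(f"sanger_status {self.sanger_status!r} invalid")


@dataclass
class SampleResult:
    """One tissue sample of one family member on one platform.

    Carries either raw counts (simulated / gated assays) or a pre-computed
    estimate (transcribed published tables), plus the latent truth when
    simulated.
    """

    member_role: str
    tissue: str
    platform: str  # mDDPCR or PASM
    counts: object = None  # DropletCounts | AlleleCounts | None
    estimate: object = None  # MAFEstimate | None
    call: Optional[str] = None
    true_maf: Optional[float] = None


@dataclass
class FamilyRecord:
    family_id: str
    variant: Optional[VariantDescriptor] = None
    members: dict = field(default_factory=dict)  # role -> MemberRecord
    samples: list = field(default_factory=list)  # list[SampleResult]
    aspcr_origin: str = "uninformative"  # paternal / maternal / uninformative
    scenario_kind: Optional[str] = None  # generating truth for simulations

    def member_samples(self, role: str) -> list:
        return [s for s in self.samples if s.member_role == role]


@dataclass
class CohortTable:
    """A set of families plus (optionally) the printed screening tallies.

    ``tallies`` carries cohort-level counts that are not reconstructible from
    per-family rows (e.g. the 74+ screened families with no published
    per-sample data); when absent, summaries fall back to counting families.
    """

    families: list = field(default_factory=list)
    tallies: Optional[Mapping[str, int]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(ids) != len(set(ids)):
            raise ParameterError("family_id values must be unique")

    def __len__(self) -> int:
        return len(self.families)


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


def check_fraction(name: str, value: float, *, upper_open: bool = False) -> float:
    """Validate a [0,1] fraction (or [0,1) when ``upper_open``)."""
    _require_finite(name, float(value))
    if value < 0 or value > 1 or (upper_open and value == 1):
        hi = "1)" if upper_open else "1]"
        raise ParameterError(f"{name} must lie in [0, {hi}, got {value!r}")
    return float(value)
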