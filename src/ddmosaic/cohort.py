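"""Family-level inheritance classification and cohort summaries.

A family whose proband carries the variant is assigned one inheritance
category by a fixed decision order that mirrors the screening cascade
(trio Sanger first, then the parental blood/tissue screen, then the sperm
screen, then the proband's own MAF):

1. a parent is an affected Sanger heterozygote  -> inherited_affected_parent
2. any parental somatic-tissue sample is mosaic -> parental_somatic_mosaic
3. otherwise a parental sperm sample is mosaic  -> parental_germline_only_mosaic
4. otherwise the proband's blood is mosaic      -> proband_postzygotic_mosaic
5. otherwise                                    -> de_novo_unresolved
                                                   (origin from ASPCR, if informative)

Sperm positivity proves paternal origin; maternal germline-only mosaicism is
unobservable in this design (no female germ cells are collected), an
asymmetry the summary reports explicitly.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Tuple

from .errors import AmbiguousInheritanceError, ParameterError
from .records import (
    CohortTable,
    FamilyRecord,
    GERMLINE_TISSUES,
    SOMATIC_TISSUES,
    frac_to_pct,
    round_half_up,
)
from .stats import LOWER_CUT, UPPER_CUT, classify_sample, estimate_maf

__all__ = ["InheritanceCall", "CohortSummary", "classify_family", "summarize_cohort"]

CATEGORIES = (
    "de_novo_unresolved",
    "inherited_affected_parent",
    "parental_somatic_mosaic",
    "parental_germline_only_mosaic",
    "proband_postzygotic_mosaic",
)

PARENT_ROLES = ("father", "mother")


@dataclass(frozen=True)
class InheritanceCall:
    category: str
    origin: str  # paternal / maternal / unknown


def _ensure_call(sample, alpha: float, lower_cut: float, upper_cut: float) -> str:
    """Sample call, computing the estimate from counts when needed."""
    if sample.call is not None:
        return sample.call
    est = sample.estimate
    if est is None:
        if sample.counts is None:
            raise ParameterError(
                f"sample {sample.member_role}/{sample.tissue} has neither counts nor estimate"
            )
        est = estimate_maf(sample.counts, alpha=alpha)
        sample.estimate = est
    sample.call = classify_sample(est, lower_cut, upper_cut).call
    return sample.call


def _origin_of(role: str) -> str:
    return {"father": "paternal", "mother": "maternal"}.get(role, "unknown")


def classify_family(
    f: FamilyRecord,
    alpha: float = 0.05,
    lower_cut: float = LOWER_CUT,
    upper_cut: float = UPPER_CUT,
) -> InheritanceCall:
    """Assign one inheritance category to a family (pure in the family data).

    Raises :class:`AmbiguousInheritanceError` when both parents show somatic
    mosaicism for the same variant — contradictory for a single transmitted
    allele, so flagged for manual review instead of silently classified.
    """
    probands = [r for r, m in f.members.items() if m.role == "proband" or r == "proband"]
    if not probands:
        raise ParameterError(f"family {f.family_id} has no proband")
    proband_samples = [
        s for s in f.samples if s.member_role in probands and s.tissue == "blood"
    ]
    proband_ok = any(
        _ensure_call(s, alpha, lower_cut, upper_cut) in ("mosaic", "het_consistent")
        for s in proband_samples
    ) or any(f.members[r].sanger_status == "het_detected" for r in probands)
    if not proband_ok:
        raise ParameterError(
            f"family {f.family_id}: proband is not variant-positive; nothing to classify"
        )

    # 1. inherited from an affected heterozygous parent
    for role in PARENT_ROLES:
        m = f.members.get(role)
        if m is not None and m.affected and m.sanger_status == "het_detected":
            return InheritanceCall("inherited_affected_parent", _origin_of(role))

    # 2. parental somatic mosaicism (blood or any peripheral tissue)
    somatic_mosaic_parents = []
    for role in PARENT_ROLES:
        for s in f.samples:
            if s.member_role != role or s.tissue not in SOMATIC_TISSUES:
                continue
            if _ensure_call(s, alpha, lower_cut, upper_cut) == "mosaic":
                somatic_mosaic_parents.append(role)
                break
    if len(set(somatic_mosaic_parents)) > 1:
        raise AmbiguousInheritanceError(
            f"family {f.family_id}: both parents somatic-mosaic for one variant; manual review"
        )
    if somatic_mosaic_parents:
        return InheritanceCall("parental_somatic_mosaic", _origin_of(somatic_mosaic_parents[0]))

    # 3. germline-only mosaicism: sperm positive, somatic screen negative
    for s in f.samples:
        if s.member_role == "father" and s.tissue in GERMLINE_TISSUES:
            if _ensure_call(s, alpha, lower_cut, upper_cut) == "mosaic":
                return InheritanceCall("parental_germline_only_mosaic", "paternal")

    # 4. postzygotic mosaicism in the proband itself
    for s in proband_samples:
        if s.call == "mosaic":
            return InheritanceCall("proband_postzygotic_mosaic", "unknown")

    # 5. unresolved de novo; ASPCR may still give the parental haplotype
    origin = f.aspcr_origin if f.aspcr_origin in ("paternal", "maternal") else "unknown"
    return InheritanceCall("de_novo_unresolved", origin)


@dataclass
class CohortSummary:
    """Headline cohort fractions; percentages are half-up to one decimal."""

    n_probands: int
    n_variant_positive: int
    detection_rate_pct: Optional[float]
    n_trios_tested: int
    n_de_novo: int
    de_novo_pct: Optional[float]
    n_inherited: int
    n_screened: int
    n_sperm_donors: int
    n_parental_mosaic_blood: int
    n_parental_mosaic_sperm_only: int
    n_parental_mosaic_total: int
    parental_mosaic_pct: Optional[float]
    sperm_only_of_donors_pct: Optional[float]
    n_proband_mosaic: int
    n_aspcr_informative: int
    origin_paternal: int
    origin_maternal: int
    origin_paternal_pct: Optional[float]
    origin_maternal_pct: Optional[float]
    maf_range_pct: Optional[Tuple[float, float]]
    category_counts: dict
    note: str = (
        "sperm screening observes only the paternal germline; maternal "
        "germline-only mosaicism is undetectable and its share is likely "
        "underestimated"
    )

    def to_dict(self) -> dict:
        return asdict(self)


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else round_half_up(100.0 * num / den, 1)


def summarize_cohort(
    cohort: CohortTable,
    alpha: float = 0.05,
    lower_cut: float = LOWER_CUT,
    upper_cut: float = UPPER_CUT,
) -> CohortSummary:
    """Compute the cohort's headline counts and fractions.

    Counts that only exist at cohort level (probands screened, trio Sanger
    outcomes, ASPCR origins) come from ``cohort.tallies`` when present;
    everything tied to per-sample MAF calls (mosaic parents, sperm-only
    cases, the mosaic MAF range) is recomputed from the family records.
    Zero denominators yield ``None`` fields, never division errors.
    """
    t = dict(cohort.tallies or {})
    calls = {}
    for fam in cohort.families:
        calls[fam.family_id] = classify_family(fam, alpha, lower_cut, upper_cut)
        # classification short-circuits; the MAF range needs every parental
        # and proband sample called
        for s in fam.samples:
            if s.member_role in PARENT_ROLES or s.member_role == "proband":
                _ensure_call(s, alpha, lower_cut, upper_cut)

    category_counts: dict = {c: 0 for c in CATEGORIES}
    for call in calls.values():
        category_counts[call.category] += 1

    blood_mosaic, sperm_only = [], []
    mosaic_parent_mafs = []
    n_proband_mosaic = 0
    for fam in cohort.families:
        parent_blood_mosaic = False
        parent_sperm_mosaic = False
        for s in fam.samples:
            if s.call != "mosaic":
                continue
            if s.member_role in PARENT_ROLES:
                mosaic_parent_mafs.append(frac_to_pct(s.estimate.maf))
                if s.tissue in SOMATIC_TISSUES:
                    parent_blood_mosaic = True
                elif s.tissue in GERMLINE_TISSUES:
                    parent_sperm_mosaic = True
        if parent_blood_mosaic:
            blood_mosaic.append(fam.family_id)
        elif parent_sperm_mosaic:
            sperm_only.append(fam.family_id)
        if calls[fam.family_id].category == "proband_postzygotic_mosaic":
            n_proband_mosaic += 1

    n_probands = int(t.get("n_probands", len(cohort.families)))
    n_positive = int(t.get("n_variant_positive", len(cohort.families)))
    n_trios = int(t.get("n_trios_tested", len(cohort.families)))
    n_de_novo = int(
        t.get(
            "n_de_novo",
            sum(
                1
                for c in calls.values()
                if c.category
                in ("de_novo_unresolved", "parental_germline_only_mosaic",
                    "parental_somatic_mosaic", "proband_postzygotic_mosaic")
            ),
        )
    )
    n_inherited = int(t.get("n_inherited",
                            category_counts["inherited_affected_parent"]))
    n_screened = int(t.get("n_screened_families", len(cohort.families)))
    n_sperm_donors = int(t.get("n_sperm_donors",
                               sum(1 for fam in cohort.families
                                   if any(s.member_role == "father" and s.tissue in GERMLINE_TISSUES
                                          for s in fam.samples))))
    n_aspcr = int(t.get("n_aspcr_informative", 0))
    n_pat = int(t.get("n_origin_paternal", 0))
    n_mat = int(t.get("n_origin_maternal", 0))

    n_blood = len(blood_mosaic)
    n_sperm_only = len(sperm_only)
    n_parental_total = n_blood + n_sperm_only
    maf_range = (
        (round_half_up(min(mosaic_parent_mafs), 2),
         round_half_up(max(mosaic_parent_mafs), 2))
        if mosaic_parent_mafs
        else None
    )
    return CohortSummary(
        n_probands=n_probands,
        n_variant_positive=n_positive,
        detection_rate_pct=_pct(n_positive, n_probands),
        n_trios_tested=n_trios,
        n_de_novo=n_de_novo,
        de_novo_pct=_pct(n_de_novo, n_trios),
        n_inherited=n_inherited,
        n_screened=n_screened,
        n_sperm_donors=n_sperm_donors,
        n_parental_mosaic_blood=n_blood,
        n_parental_mosaic_sperm_only=n_sperm_only,
        n_parental_mosaic_total=n_parental_total,
        parental_mosaic_pct=_pct(n_parental_total, n_screened),
        sperm_only_of_donors_pct=_pct(n_sperm_only, n_sperm_donors),
        n_proband_mosaic=n_proband_mosaic,
        n_aspcr_informative=n_aspcr,
        origin_paternal=n_pat,
        origin_maternal=n_mat,
        origin_paternal_pct=_pct(n_pat, n_aspcr),
        origin_maternal_pct=_pct(n_mat, n_aspcr),
        maf_range_pct=maf_range,
        category_counts=category_counts,
    )
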