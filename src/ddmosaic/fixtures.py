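"""Packaged transcriptions of the published cohort tables.

Three data fixtures ship with the package:

* ``blood_maf``     — blood MAFs (mDDPCR + PASM, percent with 95% CI) for the
                      five mosaic-positive families, incl. parental, control
                      and proband columns;
* ``tissue_maf``    — multi-tissue MAFs (sperm, blood, buccal, saliva, hair,
                      urine, skin) for the six parental-mosaic families;
* ``cohort_tallies``— the printed cohort-level screening counts (105 probands,
                      98 variant-positive, 93 trios, 90 de novo, 80 screened
                      families, 51 sperm donors, 33 ASPCR-informative with
                      29 paternal / 4 maternal);
* ``phenotypes``    — descriptive phenotype fields for the five probands
                      sharing p.(Gly947Arg) (not used by any computation).

Values are verbatim transcriptions: percents keep their printed number of
decimals, NA cells stay missing and are never imputed at load time.
"""
from __future__ import annotations

import json
from importlib import resources
from typing import Union

import numpy as np
import pandas as pd

from .errors import FixtureError, ParameterError
from .records import (
    CohortTable,
    FamilyRecord,
    MemberRecord,
    SampleResult,
    VariantDescriptor,
)
from .stats import MAFEstimate

__all__ = ["load_fixture", "load_reference_cohort", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("blood_maf", "tissue_maf", "cohort_tallies", "phenotypes")

_TSV_FIXTURES = {"blood_maf": "blood_maf.tsv", "tissue_maf": "tissue_maf.tsv",
                 "phenotypes": "phenotypes.tsv"}


def _data_path(filename: str):
    return resources.files("ddmosaic.data").joinpath(filename)


def load_fixture(name: str) -> Union[pd.DataFrame, dict]:
    """Load one packaged fixture by name.

    TSV fixtures return a DataFrame in which the percent columns are kept as
    printed strings (``maf_pct``, ``ci_low_pct``, ``ci_high_pct``) alongside
    parsed float columns (``maf``, ``ci_low``, ``ci_high``, as percents;
    NaN for NA cells).  ``cohort_tallies`` returns a dict of counts.
    """
    if name == "cohort_tallies":
        with _data_path("cohort_tallies.json").open() as fh:
            return json.load(fh)
    if name not in _TSV_FIXTURES:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    with _data_path(_TSV_FIXTURES[name]).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if name == "phenotypes":
        return df
    for col, parsed in (("maf_pct", "maf"), ("ci_low_pct", "ci_low"),
                        ("ci_high_pct", "ci_high")):
        df[parsed] = pd.to_numeric(df[col].replace("NA", np.nan))
    return df


def _variant_from_row(row) -> VariantDescriptor:
    return VariantDescriptor(
        chrom=str(row["chr"]),
        pos=str(row["pos_hg19_1based"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        cdna=str(row["cdna"]),
        protein=str(row["protein"]),
    )


# Sanger trio status as reported: both weak-signal parents were the two
# blood-level mosaics found by re-inspection of traces; every other tested
# parent was clean-negative, probands were clean heterozygotes.
_SANGER_WEAK = {("A052", "mother"), ("A112", "father")}


def _placeholder_negative_family(fid: str) -> FamilyRecord:
    """A screened family with no published per-sample data.

    Encoded as proband het-consistent / parents negative, matching the
    printed totals; the per-family truth is not individually published.
    """
    fam = FamilyRecord(family_id=fid)
    fam.members["proband"] = MemberRecord("proband", affected=True,
                                          sanger_status="het_detected")
    for role in ("father", "mother"):
        fam.members[role] = MemberRecord(role, sanger_status="not_detected")
        fam.samples.append(
            SampleResult(role, "blood", "mDDPCR",
                         estimate=MAFEstimate.from_percent(0.00, 0.00, 0.01, "mDDPCR"))
        )
    fam.samples.append(
        SampleResult("proband", "blood", "mDDPCR",
                     estimate=MAFEstimate.from_percent(50.00, 49.70, 50.30, "mDDPCR"))
    )
    return fam


def load_reference_cohort(include_negative_screen: bool = True) -> CohortTable:
    """Assemble the published cohort as a :class:`CohortTable`.

    Families with published per-sample MAFs (the seven mosaic-positive
    tables' families) carry full per-member, per-tissue, per-platform
    estimates; when ``include_negative_screen`` is true the remaining
    screened families (to the printed total of 80) are added as
    screened-negative placeholders so family-level counts are conserved.
    The printed cohort tallies ride along for quantities not reconstructible
    per family.
    """
    blood = load_fixture("blood_maf")
    tissue = load_fixture("tissue_maf")
    tallies = load_fixture("cohort_tallies")

    families: dict[str, FamilyRecord] = {}
    for df in (blood, tissue):
        for _, row in df.iterrows():
            fid = row["family_id"]
            fam = families.get(fid)
            if fam is None:
                fam = FamilyRecord(
                    family_id=fid,
                    variant=_variant_from_row(row),
                    aspcr_origin=(row["origin"] if row["origin"] in
                                  ("paternal", "maternal") else "uninformative"),
                )
                families[fid] = fam
            role = row["member_role"]
            if role not in fam.members:
                if role == "proband":
                    status = "het_detected"
                elif role == "control":
                    status = "not_tested"
                else:
                    status = ("weak_signal" if (fid, role) in _SANGER_WEAK
                              else "not_detected")
                fam.members[role] = MemberRecord(
                    role, affected=(role == "proband"), sanger_status=status
                )
            if np.isnan(row["maf"]):
                continue  # NA cells stay missing, never imputed
            est = MAFEstimate.from_percent(
                float(row["maf"]), float(row["ci_low"]), float(row["ci_high"]),
                platform=row["platform"],
            )
            fam.samples.append(
                SampleResult(role, row["tissue"], row["platform"], estimate=est)
            )

    # the two sperm-screen families have no separate blood-table rows for the
    # proband; mark their probands as Sanger-het (both probands carried the
    # variant heterozygously)
    for fid in ("A015", "A065"):
        fam = families.get(fid)
        if fam is not None and "proband" not in fam.members:
            fam.members["proband"] = MemberRecord("proband", affected=True,
                                                  sanger_status="het_detected")
        for role in ("father", "mother"):
            if role not in fam.members:
                fam.members[role] = MemberRecord(role, sanger_status="not_detected")

    fam_list = [families[k] for k in sorted(families)]
    if include_negative_screen:
        n_extra = int(tallies["n_screened_families"]) - len(fam_list)
        if n_extra < 0:
            raise ParameterError("more detailed families than screened total")
        fam_list += [_placeholder_negative_family(f"N{i:03d}") for i in range(n_extra)]
    return CohortTable(families=fam_list, tallies=tallies,
                       provenance="published cohort transcription")
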