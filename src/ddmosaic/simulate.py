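"""Synthetic assay and cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* droplet assays — each droplet holds a template with probability
  ``occupancy_rate`` (single-template partitioning; no multi-occupancy
  correction, since MAFs are read directly off class counts); an informative
  droplet reads mutant with probability ``maf + (1 - maf) * fcr`` where
  ``fcr`` is the per-droplet false-mutant-call rate.  Two-channel
  fluorescence intensities are drawn from three well-separated cluster
  centres plus Gaussian noise;
* deep amplicon runs — alt reads are binomial at depth ~10,000x with a
  symmetric per-base error rate;
* families — per-member, per-tissue true MAFs with stronger correlation
  inside a germ-layer group (blood/saliva mesoderm-dominant;
  buccal/hair/skin ectoderm-containing; urine its own group; sperm
  germline), reflecting mosaic variants arising early in embryogenesis;
* Sanger genotyping — a hard detectability threshold at 10% MAF (full
  heterozygotes read as clean het calls, mosaics above threshold as weak
  signals).

All randomness flows through explicit integer seeds; there is no global
random state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .records import (
    AlleleCounts,
    DropletCounts,
    FamilyRecord,
    MemberRecord,
    SampleResult,
    check_fraction,
)

__all__ = [
    "RawDropletSet",
    "FamilyScenario",
    "AssayParams",
    "DEFAULT_CENTERS",
    "CLUSTER_SEPARATION",
    "GERM_LAYER",
    "SCENARIO_KINDS",
    "simulate_droplet_assay",
    "sample_droplet_counts",
    "simulate_amplicon_reads",
    "make_scenario",
    "simulate_mosaic_family",
    "simulate_cohort",
]

#: default cluster centres in (channel1, channel2) fluorescence space;
#: channel1 reports the wild-type probe, channel2 the mutant probe
DEFAULT_CENTERS = {
    "NA": (1000.0, 1000.0),
    "WT": (8000.0, 1200.0),
    "MU": (1200.0, 8000.0),
}
#: reference scale for ``noise_sd`` (expressed as a fraction of this)
CLUSTER_SEPARATION = 7000.0

#: germ-layer grouping used to correlate per-tissue MAFs within a carrier
GERM_LAYER = {
    "blood": "mesoderm",
    "saliva": "mesoderm",
    "buccal": "ectoderm",
    "hair": "ectoderm",
    "skin": "ectoderm",
    "urine": "urine",
    "sperm": "germline",
}

SCENARIO_KINDS = (
    "de_novo",
    "inherited_het",
    "parental_somatic_mosaic",
    "parental_germline_only_mosaic",
    "proband_mosaic",
)

DEFAULT_TISSUES = ("blood", "buccal", "saliva", "hair", "urine", "skin")

#: empirical per-droplet false-mutant-call rate pooled from negative
#: controls; used as the realistic default error level for simulations
EMPIRICAL_FALSE_CALL_RATE = 2.15664e-05

#: MAF detection floors of the three assays (fractions)
SANGER_LOD = 0.10
PASM_LOD = 0.005
MDDPCR_LOD = 0.0001


@dataclass(frozen=True)
class RawDropletSet:
    """Per-droplet two-channel intensities with latent class labels.

    ``droplets`` has columns ``droplet_id, ch1, ch2, true_class``; the latent
    ``true_class`` (MU/WT/NA) is the gating ground truth.
    """

    droplets: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.droplets)

    def true_counts(self) -> DropletCounts:
        c = self.droplets["true_class"].value_counts()
        return DropletCounts(
            mu=int(c.get("MU", 0)), wt=int(c.get("WT", 0)), na=int(c.get("NA", 0))
        )

    def to_csv(self, path) -> None:
        self.droplets.to_csv(path, index=False)


@dataclass(frozen=True)
class AssayParams:
    """Assay-level settings shared by all samples of a simulated family."""

    n_informative: int = 50_000
    occupancy_rate: float = 0.3
    false_call_rate: float = EMPIRICAL_FALSE_CALL_RATE
    pasm_depth: int = 10_000
    pasm_error_rate: float = 1e-4
    include_pasm: bool = False


@dataclass(frozen=True)
class FamilyScenario:
    """Generating truth for one simulated family.

    ``member_mean_mafs`` gives each member's carrier-level mean somatic MAF;
    a value of exactly 0.5 marks a constitutional heterozygote (MAF 0.5 in
    every tissue, no dispersion).  ``tissue_maf_overrides`` pins specific
    (role, tissue) cells — e.g. a germline-only father has sperm pinned to a
    positive MAF over a zero somatic mean.
    """

    kind: str
    parent_of_origin: str = "unknown"
    member_mean_mafs: Mapping[str, float] = field(default_factory=dict)
    tissue_maf_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tissues: Sequence[str] = DEFAULT_TISSUES
    sanger_lod: float = SANGER_LOD
    sigma_between_layers: float = 0.35
    sigma_within_layer: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ParameterError(f"scenario kind {self.kind!r} not in {SCENARIO_KINDS}")
        for role, m in self.member_mean_mafs.items():
            check_fraction(f"member_mean_mafs[{role!r}]", m)
        for role, tm in self.tissue_maf_overrides.items():
            for tissue, m in tm.items():
                if tissue not in GERM_LAYER:
                    raise ParameterError(f"unknown tissue {tissue!r} for {role!r}")
                check_fraction(f"tissue_maf_overrides[{role!r}][{tissue!r}]", m)
        for tissue in self.tissues:
            if tissue not in GERM_LAYER:
                raise ParameterError(f"unknown tissue {tissue!r} in tissues")


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ParameterError("seed must be an integer (explicit seeds everywhere)")
    return np.random.default_rng(int(seed))


def _check_droplet_params(n_droplets, occupancy_rate, true_maf, false_call_rate, noise_sd):
    if int(n_droplets) < 1:
        raise ParameterError(f"n_droplets must be >= 1, got {n_droplets!r}")
    check_fraction("occupancy_rate", occupancy_rate)
    check_fraction("true_maf", true_maf)
    check_fraction("false_call_rate", false_call_rate, upper_open=True)
    if not math.isfinite(noise_sd) or noise_sd < 0:
        raise ParameterError(f"noise_sd must be a finite non-negative number, got {noise_sd!r}")


def simulate_droplet_assay(
    n_droplets: int,
    occupancy_rate: float,
    true_maf: float,
    false_call_rate: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    centers: Optional[Mapping[str, Sequence[float]]] = None,
) -> RawDropletSet:
    """Simulate one two-channel droplet assay with latent class labels.

    Each droplet is independently non-informative (NA) with probability
    ``1 - occupancy_rate``; an informative droplet is mutant with probability
    ``true_maf + (1 - true_maf) * false_call_rate`` (a wild-type template is
    misread as mutant at the false-call rate) and wild-type otherwise.
    Intensities are the class centre plus isotropic Gaussian noise of
    standard deviation ``noise_sd * CLUSTER_SEPARATION``.
    """
    _check_droplet_params(n_droplets, occupancy_rate, true_maf, false_call_rate, noise_sd)
    n = int(n_droplets)
    rng = _rng(seed)
    centers = dict(DEFAULT_CENTERS if centers is None else centers)

    informative = rng.random(n) < occupancy_rate
    p_mu = true_maf + (1.0 - true_maf) * false_call_rate
    mutant = informative & (rng.random(n) < p_mu)
    true_class = np.where(~informative, "NA", np.where(mutant, "MU", "WT"))

    centre_arr = np.array([centers[c] for c in true_class], dtype=float)
    noise = rng.normal(0.0, noise_sd * CLUSTER_SEPARATION, size=(n, 2))
    intensities = centre_arr + noise

    df = pd.DataFrame(
        {
            "droplet_id": np.arange(n),
            "ch1": intensities[:, 0],
            "ch2": intensities[:, 1],
            "true_class": true_class,
        }
    )
    meta = {
        "n_droplets": n,
        "occupancy_rate": float(occupancy_rate),
        "true_maf": float(true_maf),
        "false_call_rate": float(false_call_rate),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return RawDropletSet(droplets=df, meta=meta)


def sample_droplet_counts(
    n_informative: int,
    true_maf: float,
    false_call_rate: float,
    rng: np.random.Generator,
    n_na: int = 0,
) -> DropletCounts:
    """Sample the count-level sufficient statistic of a droplet assay.

    Exactly the binomial marginal of :func:`simulate_droplet_assay` over its
    informative droplets; used when per-droplet intensities are not needed
    (cohort-scale simulation).
    """
    if int(n_informative) < 0:
        raise ParameterError(f"n_informative must be >= 0, got {n_informative!r}")
    check_fraction("true_maf", true_maf)
    check_fraction("false_call_rate", false_call_rate, upper_open=True)
    p_mu = true_maf + (1.0 - true_maf) * false_call_rate
    mu = int(rng.binomial(int(n_informative), p_mu))
    return DropletCounts(mu=mu, wt=int(n_informative) - mu, na=int(n_na))


def simulate_amplicon_reads(
    depth: int,
    true_maf: float,
    base_error_rate: float = 0.0,
    seed: int = 0,
) -> AlleleCounts:
    """Simulate allele counts for one deep amplicon (PASM-style) run.

    alt reads ~ Binomial(depth, maf*(1-e) + (1-maf)*e): a true mutant read
    can be miscalled back to reference and a reference read to mutant at the
    same symmetric per-base error rate ``e``.
    """
    if int(depth) < 1:
        raise ParameterError(f"depth must be >= 1, got {depth!r}")
    check_fraction("true_maf", true_maf)
    check_fraction("base_error_rate", base_error_rate, upper_open=True)
    rng = _rng(seed)
    p_alt = true_maf * (1.0 - base_error_rate) + (1.0 - true_maf) * base_error_rate
    alt = int(rng.binomial(int(depth), p_alt))
    return AlleleCounts(alt_reads=alt, ref_reads=int(depth) - alt)


def make_scenario(
    kind: str,
    *,
    parent_of_origin: Optional[str] = None,
    somatic_maf: float = 0.10,
    germline_maf: float = 0.12,
    proband_maf: float = 0.40,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    include_sperm: bool = True,
) -> FamilyScenario:
    """Build a canonical scenario of the given kind with sensible defaults.

    Default MAF levels sit in the range reported for real carriers
    (parental somatic ~7.5-18.8%, germline-only sperm ~12.4%, a mosaic
    proband at ~44%).
    """
    if parent_of_origin is None:
        parent_of_origin = {
            "de_novo": "unknown",
            "inherited_het": "maternal",
            "parental_somatic_mosaic": "maternal",
            "parental_germline_only_mosaic": "paternal",
            "proband_mosaic": "unknown",
        }[kind]
    means = {"proband": 0.5, "father": 0.0, "mother": 0.0}
    overrides: dict = {}
    if kind == "inherited_het":
        carrier = "father" if parent_of_origin == "paternal" else "mother"
        means[carrier] = 0.5
    elif kind == "parental_somatic_mosaic":
        carrier = "father" if parent_of_origin == "paternal" else "mother"
        means[carrier] = somatic_maf
    elif kind == "parental_germline_only_mosaic":
        parent_of_origin = "paternal"  # only male germ cells are collectable
        overrides = {"father": {"sperm": germline_maf}}
    elif kind == "proband_mosaic":
        means["proband"] = proband_maf
    scenario_tissues = tuple(tissues)
    if include_sperm and "sperm" not in scenario_tissues:
        scenario_tissues = scenario_tissues + ("sperm",)
    return FamilyScenario(
        kind=kind,
        parent_of_origin=parent_of_origin,
        member_mean_mafs=means,
        tissue_maf_overrides=overrides,
        tissues=scenario_tissues,
    )


def _draw_tissue_mafs(
    scenario: FamilyScenario, role: str, rng: np.random.Generator
) -> "dict[str, float]":
    """Per-tissue true MAFs for one member under the germ-layer model."""
    mean = float(scenario.member_mean_mafs.get(role, 0.0))
    overrides = dict(scenario.tissue_maf_overrides.get(role, {}))
    tissues = [t for t in scenario.tissues if t != "sperm" or role == "father"]
    out: dict[str, float] = {}
    if mean == 0.5:  # constitutional heterozygote: no mitotic dispersion
        out = {t: 0.5 for t in tissues}
    elif mean == 0.0:
        out = {t: 0.0 for t in tissues}
    else:
        # dispersion acts on the logit of the carrier-cell fraction c = 2*MAF,
        # so a mosaic's per-tissue MAF stays strictly inside (0, 0.5): a
        # heterozygous variant in a fraction c of cells gives MAF = c/2
        ell = math.log(2.0 * mean / (1.0 - 2.0 * mean)) if mean < 0.5 else math.inf
        layers = sorted({GERM_LAYER[t] for t in tissues})
        layer_shift = {
            l: rng.normal(0.0, scenario.sigma_between_layers) for l in layers
        }
        for t in tissues:
            z = ell + layer_shift[GERM_LAYER[t]] + rng.normal(
                0.0, scenario.sigma_within_layer
            )
            out[t] = 0.5 / (1.0 + math.exp(-z))
    out.update({t: v for t, v in overrides.items() if t in tissues or t == "sperm"})
    return out


def _sanger_status(blood_maf: float, lod: float) -> str:
    if blood_maf >= 0.5:
        return "het_detected"
    if blood_maf >= lod:
        return "weak_signal"
    return "not_detected"


def simulate_mosaic_family(
    scenario: FamilyScenario,
    assay: Optional[AssayParams] = None,
    seed: int = 0,
) -> FamilyRecord:
    """Simulate one trio's per-member, per-tissue assay counts.

    Tissue-level true MAFs are drawn around each member's carrier mean with
    tighter dispersion inside a germ-layer group; droplet counts then follow
    the binomial assay model at ``assay.n_informative`` informative droplets
    with the assay false-call rate.  Sanger trio status is a hard threshold
    on true blood MAF.  Deterministic for a fixed (scenario, assay, seed).
    """
    assay = assay or AssayParams()
    rng = _rng(seed)
    fam = FamilyRecord(
        family_id=f"SIM{int(seed):06d}",
        aspcr_origin=(
            scenario.parent_of_origin
            if scenario.parent_of_origin in ("paternal", "maternal")
            else "uninformative"
        ),
        scenario_kind=scenario.kind,
    )
    for role in ("proband", "father", "mother"):
        tissue_mafs = _draw_tissue_mafs(scenario, role, rng)
        blood_maf = tissue_mafs.get("blood", 0.0)
        affected = role == "proband" or (
            scenario.kind == "inherited_het"
            and scenario.member_mean_mafs.get(role) == 0.5
        )
        fam.members[role] = MemberRecord(
            role=role,
            affected=affected,
            sanger_status=_sanger_status(blood_maf, scenario.sanger_lod),
        )
        for tissue, maf in sorted(tissue_mafs.items()):
            counts = sample_droplet_counts(
                assay.n_informative, maf, assay.false_call_rate, rng
            )
            fam.samples.append(
                SampleResult(
                    member_role=role,
                    tissue=tissue,
                    platform="mDDPCR",
                    counts=counts,
                    true_maf=maf,
                )
            )
            if assay.include_pasm and tissue == "blood":
                p_alt = maf * (1 - assay.pasm_error_rate) + (1 - maf) * assay.pasm_error_rate
                alt = int(rng.binomial(assay.pasm_depth, p_alt))
                fam.samples.append(
                    SampleResult(
                        member_role=role,
                        tissue=tissue,
                        platform="PASM",
                        counts=AlleleCounts(alt, assay.pasm_depth - alt),
                        true_maf=maf,
                    )
                )
    return fam


def simulate_cohort(
    n_families: int,
    scenario_mix: Optional[Mapping[str, float]] = None,
    assay: Optional[AssayParams] = None,
    seed: int = 0,
    **scenario_kwargs,
):
    """Simulate a cohort of families with a given mix of scenario kinds.

    ``scenario_mix`` maps scenario kind to weight (defaults to uniform over
    the five kinds).  Family seeds are spawned deterministically from
    ``seed``.  Returns a list of :class:`FamilyRecord`.
    """
    from .records import CohortTable

    if n_families < 1:
        raise ParameterError(f"n_families must be >= 1, got {n_families!r}")
    mix = dict(scenario_mix or {k: 1.0 for k in SCENARIO_KINDS})
    for k in mix:
        if k not in SCENARIO_KINDS:
            raise ParameterError(f"unknown scenario kind {k!r} in scenario_mix")
    kinds = sorted(mix)
    weights = np.array([mix[k] for k in kinds], dtype=float)
    weights = weights / weights.sum()
    rng = _rng(seed)
    assigned = rng.choice(len(kinds), size=n_families, p=weights)
    families = []
    for i, ki in enumerate(assigned):
        scenario = make_scenario(kinds[int(ki)], **scenario_kwargs)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fam = simulate_mosaic_family(scenario, assay=assay, seed=sub_seed)
        fam = replace_family_id(fam, f"SIM{i:04d}")
        families.append(fam)
    return CohortTable(families=families, provenance=f"simulated(seed={seed})")


def replace_family_id(fam: FamilyRecord, new_id: str) -> FamilyRecord:
    fam.family_id = new_id
    return fam
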