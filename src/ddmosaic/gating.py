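"""Droplet gating: raw two-channel intensities -> MU/WT/NA counts.

Two gating methods are offered.  The default mirrors manual gating of a
scatter plot: explicit (or quantile-derived) rectangular regions per class,
half-open ``[min, max)``, with any droplet outside every region counted NA —
conservative for rare-allele calling, since an ambiguous droplet can never
inflate the mutant count.  The automated alternative fits three cluster
centres by k-means initialised at configured prototype locations and assigns
each droplet to the nearest centre.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import GatingError, ParameterError
from .records import DropletCounts
from .simulate import DEFAULT_CENTERS, RawDropletSet

__all__ = ["GateModel", "fit_gates", "count_droplets"]

logger = logging.getLogger(__name__)

CLASSES = ("MU", "WT", "NA")


@dataclass(frozen=True)
class GateModel:
    """Per-class regions in (ch1, ch2) space.

    ``method_tag`` is ``"thresholds"`` (rectangular regions, half-open
    [min, max)) or ``"nearest_center"`` (assignment to the nearest fitted
    cluster centre).
    """

    method_tag: str
    thresholds: Optional[Mapping[str, Mapping[str, float]]] = None
    centers: Optional[Mapping[str, tuple]] = None

    def __post_init__(self) -> None:
        if self.method_tag == "thresholds":
            if not self.thresholds:
                raise ParameterError("thresholds method requires region definitions")
            for cls, region in self.thresholds.items():
                missing = {"ch1_min", "ch1_max", "ch2_min", "ch2_max"} - set(region)
                if missing:
                    raise ParameterError(f"region {cls!r} missing bounds {sorted(missing)}")
        elif self.method_tag == "nearest_center":
            if not self.centers or set(self.centers) != set(CLASSES):
                raise ParameterError("nearest_center method requires centers for MU, WT, NA")
        else:
            raise ParameterError(f"unknown gating method {self.method_tag!r}")


def _as_frame(droplets) -> pd.DataFrame:
    if isinstance(droplets, RawDropletSet):
        return droplets.droplets
    if isinstance(droplets, pd.DataFrame):
        return droplets
    raise ParameterError("droplets must be a RawDropletSet or DataFrame with ch1/ch2 columns")


def _rect_gates_from_splits(s1: float, s2: float) -> dict:
    inf = float("inf")
    return {
        # mutant probe high, wild-type probe low
        "MU": {"ch1_min": -inf, "ch1_max": s1, "ch2_min": s2, "ch2_max": inf},
        # wild-type probe high, mutant probe low
        "WT": {"ch1_min": s1, "ch1_max": inf, "ch2_min": -inf, "ch2_max": s2},
        # double-low: empty or non-target template
        "NA": {"ch1_min": -inf, "ch1_max": s1, "ch2_min": -inf, "ch2_max": s2},
    }


def fit_gates(droplets, method: str = "thresholds", params: Optional[dict] = None) -> GateModel:
    """Fit (or echo) a gate model for a droplet set.

    thresholds:      ``params`` may carry explicit per-class regions
                     (echoed unchanged) or per-channel split points
                     ``{"ch1_split", "ch2_split"}``; with neither, splits
                     default to each channel's mid-range.
    nearest_center:  3-cluster k-means seeded at prototype centres
                     (``params["prototypes"]``, default the simulator's
                     cluster centres); fitted centres inherit the class of
                     their nearest prototype.
    """
    params = dict(params or {})
    df = _as_frame(droplets)
    if len(df) < 10:
        raise GatingError(f"need >= 10 droplets to fit gates, got {len(df)}")
    xy = df[["ch1", "ch2"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise GatingError("droplet intensities contain non-finite values")
    if np.allclose(xy, xy[0]):
        raise GatingError("degenerate input: all droplet intensities identical")

    if method == "thresholds":
        if "regions" in params:
            return GateModel(method_tag="thresholds", thresholds=params["regions"])
        s1 = params.get("ch1_split")
        s2 = params.get("ch2_split")
        if s1 is None:
            s1 = float((xy[:, 0].min() + xy[:, 0].max()) / 2.0)
        if s2 is None:
            s2 = float((xy[:, 1].min() + xy[:, 1].max()) / 2.0)
        return GateModel(method_tag="thresholds", thresholds=_rect_gates_from_splits(s1, s2))

    if method == "nearest_center":
        prototypes = params.get("prototypes", DEFAULT_CENTERS)
        if set(prototypes) != set(CLASSES):
            raise ParameterError("prototypes must define MU, WT and NA locations")
        order = sorted(prototypes)  # deterministic prototype ordering
        init = np.array([prototypes[c] for c in order], dtype=float)
        km = KMeans(n_clusters=3, init=init, n_init=1, random_state=0).fit(xy)
        fitted = {}
        for centre in km.cluster_centers_:
            d = {c: float(np.hypot(*(centre - np.asarray(prototypes[c])))) for c in order}
            fitted[min(d, key=d.get)] = (float(centre[0]), float(centre[1]))
        if set(fitted) != set(CLASSES):
            raise GatingError("fitted centres do not map one-to-one onto MU/WT/NA prototypes")
        return GateModel(method_tag="nearest_center", centers=fitted)

    raise ParameterError(f"unknown gating method {method!r}")


def assign_labels(droplets, gates: GateModel) -> np.ndarray:
    """Label each droplet MU/WT/NA under the gate model."""
    df = _as_frame(droplets)
    xy = df[["ch1", "ch2"]].to_numpy(dtype=float)
    if gates.method_tag == "thresholds":
        labels = np.full(len(df), "NA", dtype=object)
        claimed = np.zeros(len(df), dtype=bool)
        for cls in ("MU", "WT"):  # NA is the fall-through class
            r = gates.thresholds[cls]
            inside = (
                (xy[:, 0] >= r["ch1_min"]) & (xy[:, 0] < r["ch1_max"])
                & (xy[:, 1] >= r["ch2_min"]) & (xy[:, 1] < r["ch2_max"])
            )
            labels[inside & ~claimed] = cls
            claimed |= inside
        n_out = int((~claimed & (labels == "NA")).sum())
        if n_out:
            logger.info("%d droplets fell outside all MU/WT regions; counted NA", n_out)
        return labels.astype(str)
    centers = np.array([gates.centers[c] for c in CLASSES], dtype=float)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.array(CLASSES, dtype=object)[d2.argmin(axis=1)].astype(str)


def count_droplets(droplets, gates: GateModel) -> DropletCounts:
    """Count MU/WT/NA droplets under a gate model.

    Every droplet receives exactly one label; droplets outside all threshold
    regions are counted NA (and logged), never dropped.
    """
    labels = assign_labels(droplets, gates)
    mu = int((labels == "MU").sum())
    wt = int((labels == "WT").sum())
    na = int((labels == "NA").sum())
    return DropletCounts(mu=mu, wt=wt, na=na)
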