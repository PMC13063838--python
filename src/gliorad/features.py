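"""First-order, shape and location features; catalog-wide extraction.

:func:`extract_all` evaluates every entry of a :class:`FeatureCatalog` on a
validated :class:`Study`.  Per-feature failures (empty directions, too few
voxels, missing atlas) become NaN markers rather than exceptions; the
resulting vectors carry through to :func:`listwise_delete`, which drops any
patient with one or more missing features, mirroring the cohort-filtering
step of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .catalog import FeatureCatalog, build_catalog
from .preprocess import N_GRAY_LEVELS, QuantizedVolume, Study, VoiMask
from .texture import compute_glcm_set, glcm_feature, glrlm_features

logger = logging.getLogger(__name__)


def first_order_features(q: QuantizedVolume, mask: VoiMask) -> dict[str, float]:
    """Seven first-order statistics of the masked gray levels.

    ``energy`` is the mean squared level; ``entropy`` uses the 256-bin level
    histogram in bits.  Skewness and kurtosis (Fisher, excess) of a
    zero-variance region are defined as 0 so flat phantoms are not dropped;
    with fewer than 2 voxels SD, skewness and kurtosis are missing.
    """
    x = np.asarray(q.levels)[mask.mask].astype(float)
    if x.size == 0:
        return {s: float("nan") for s in
                ("mean", "SD", "median", "skewness", "kurtosis", "energy", "entropy")}
    counts = np.bincount(x.astype(int), minlength=N_GRAY_LEVELS)
    p = counts[counts > 0] / x.size
    out = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "energy": float(np.mean(x**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
    }
    if x.size < 2:
        out.update(SD=float("nan"), skewness=float("nan"), kurtosis=float("nan"))
        return out
    out["SD"] = float(x.std(ddof=1))
    if x.std() == 0:
        out.update(skewness=0.0, kurtosis=0.0)
    else:
        out["skewness"] = float(sps.skew(x))
        out["kurtosis"] = float(sps.kurtosis(x))  # Fisher (excess)
    return out


def _max_diameter(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) clouds: brute force below
    return float(pdist(points).max())


def shape_features(mask: VoiMask, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Seven shape descriptors of a binary VOI in physical units.

    volume (mm^3), surface area (mm^2, exposed voxel faces), sphericity
    ``pi^(1/3) (6V)^(2/3) / A``, compactness ``V / A^(3/2)``, elongation and
    flatness (sqrt of principal-axis eigenvalue ratios lambda2/lambda1 and
    lambda3/lambda1), and maximum 3D diameter over boundary voxel centers.
    """
    m = mask.mask
    n = int(m.sum())
    names = ("volume", "surface", "sphericity", "compactness",
             "elongation", "flatness", "maxdiameter")
    if n == 0:
        return {s: float("nan") for s in names}
    sx, sy, sz = (float(s) for s in spacing)
    voxvol = sx * sy * sz
    volume = n * voxvol
    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    boundary = np.zeros_like(m)
    for ax, fa in enumerate(face_areas):
        for sign in (1, -1):
            nb = np.roll(m, sign, axis=ax)
            # roll wraps; voxels at the grid face are exposed on that side
            edge = [slice(None)] * 3
            edge[ax] = 0 if sign == 1 else -1
            nb[tuple(edge)] = False
            exposed = m & ~nb
            surface += fa * exposed.sum()
            boundary |= exposed
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface)
    compactness = float(volume / surface**1.5)
    coords = np.argwhere(m).astype(float) * np.array([sx, sy, sz])
    if n == 1:
        elong = flat = 1.0
    else:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0, None)
        if eig[0] == 0:
            elong = flat = 1.0
        else:
            elong = float(np.sqrt(eig[1] / eig[0]))
            flat = float(np.sqrt(eig[2] / eig[0]))
    bcoords = np.argwhere(boundary).astype(float) * np.array([sx, sy, sz])
    return {
        "volume": volume,
        "surface": surface,
        "sphericity": sphericity,
        "compactness": compactness,
        "elongation": elong,
        "flatness": flat,
        "maxdiameter": _max_diameter(bcoords),
    }


def location_features(
    core: VoiMask, atlas: np.ndarray | None, region_groups: list[list[int]] | None = None
) -> dict[int, float]:
    """Occupancy rate of the core VOI in each configured atlas region group.

    Returns the fraction of core voxels whose atlas label falls in each
    group (default groups: single labels 1..5).  Fractions sum to at most 1;
    a missing atlas yields NaN for every region.
    """
    groups = region_groups or [[r] for r in range(1, 6)]
    if atlas is None:
        return {i + 1: float("nan") for i in range(len(groups))}
    labels = np.asarray(atlas)[core.mask]
    n = labels.size
    return {
        i + 1: (float(np.isin(labels, g).sum() / n) if n else float("nan"))
        for i, g in enumerate(groups)
    }


@dataclass
class FeatureVector:
    """Values for every catalog entry; NaN marks a missing feature."""

    patient_id: str
    values: dict[str, float]
    failure_reason: str | None = None

    @property
    def n_missing(self) -> int:
        return int(sum(np.isnan(v) for v in self.values.values()))


def extract_all(study: Study, catalog: FeatureCatalog | None = None) -> FeatureVector:
    """Evaluate the full catalog on one study.

    GLCM sets and GLRLM statistics are computed once per (channel, VOI,
    offset) and shared by all features that read them.  Any feature whose
    preconditions fail is a missing value; per-feature failures never raise.
    """
    cat = catalog or build_catalog()
    if not study.valid:
        return FeatureVector(
            patient_id=study.patient_id,
            values={name: float("nan") for name in cat.names},
            failure_reason="; ".join(study.errors),
        )
    glcm_cache: dict[tuple[str, str, int], object] = {}
    glrlm_cache: dict[tuple[str, str], dict[str, float]] = {}
    fo_cache: dict[tuple[str, str], dict[str, float]] = {}
    shape_cache: dict[str, dict[str, float]] = {}
    loc_cache: dict[int, float] | None = None
    values: dict[str, float] = {}
    for spec in cat.specs:
        try:
            if spec.family == "firstorder":
                key = (spec.channel, spec.voi)
                if key not in fo_cache:
                    fo_cache[key] = first_order_features(
                        study.channels[spec.channel], study.masks[spec.voi]
                    )
                values[spec.name] = fo_cache[key][spec.stat]
            elif spec.family == "GLCM":
                gkey = (spec.channel, spec.voi, spec.offset)
                if gkey not in glcm_cache:
                    glcm_cache[gkey] = compute_glcm_set(
                        study.channels[spec.channel], study.masks[spec.voi], spec.offset
                    )
                values[spec.name] = glcm_feature(glcm_cache[gkey], spec.stat, spec.agg)
            elif spec.family == "GLRLM":
                key = (spec.channel, spec.voi)
                if key not in glrlm_cache:
                    glrlm_cache[key] = glrlm_features(
                        study.channels[spec.channel], study.masks[spec.voi]
                    )
                values[spec.name] = glrlm_cache[key][spec.stat]
            elif spec.family == "shape":
                if spec.voi not in shape_cache:
                    shape_cache[spec.voi] = shape_features(
                        study.masks[spec.voi], study.spacing
                    )
                values[spec.name] = shape_cache[spec.voi][spec.stat]
            elif spec.family == "location":
                if loc_cache is None:
                    loc_cache = location_features(study.masks["core"], study.atlas)
                values[spec.name] = loc_cache[spec.region]
            else:
                values[spec.name] = float("nan")
        except Exception as exc:  # per-feature failure -> missing marker
            logger.warning("feature %s failed for %s: %s", spec.name, study.patient_id, exc)
            values[spec.name] = float("nan")
    return FeatureVector(patient_id=study.patient_id, values=values)


def vectors_to_table(vectors: list[FeatureVector], catalog: FeatureCatalog) -> pd.DataFrame:
    """Stack feature vectors into a patient x feature table in catalog order."""
    df = pd.DataFrame([v.values for v in vectors], columns=catalog.names)
    df.insert(0, "patient_id", [v.patient_id for v in vectors])
    return df


def listwise_delete(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every patient with one or more missing features.

    Returns the retained table and a report (patient_id, n_missing) of the
    dropped rows.  Dropping every patient logs a warning.
    """
    feat = table.drop(columns=["patient_id"], errors="ignore")
    n_missing = feat.isna().sum(axis=1)
    keep = n_missing == 0
    report = pd.DataFrame(
        {
            "patient_id": table.loc[~keep, "patient_id"]
            if "patient_id" in table
            else table.index[~keep],
            "n_missing": n_missing[~keep],
        }
    ).reset_index(drop=True)
    if not keep.any():
        logger.warning("listwise deletion removed every patient")
    if len(report):
        logger.info("listwise deletion dropped %d patients", len(report))
    return table.loc[keep].reset_index(drop=True), report
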