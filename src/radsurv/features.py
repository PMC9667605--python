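"""The 92-feature radiomic pool: 46 features per ROI x two ROIs.

Per ROI the pool is 32 texture features (GLCM 7, GLRLM 11, NGLDM 3,
GLZLM 11) plus 14 first-order features (shape 3, conventional 7,
histogram 4). Feature names follow the LIFEx naming scheme, including the
"SUV"-named indices applied verbatim to HU (``CONV_SUVstd`` is the
population standard deviation of HU; ``TLG_mL`` is mean HU x volume in mL).
Full column names carry the ROI prefix, e.g. ``TUMOR_GLRLM_SRE``,
``LUNG_SHAPE_Volume_mL``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateROIError, DomainError, SchemaError
from .imaging import (
    DEFAULT_SPACING,
    CTVolume,
    DiscretizedVolume,
    MaskedSubvolume,
    ROIMask,
    exclude_tumor_from_lung,
    preprocess_roi,
)
from .texture import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLZLM_FEATURES,
    NGLDM_FEATURES,
    compute_glcm_features,
    compute_glrlm_features,
    compute_glzlm_features,
    compute_ngldm_features,
)

ROI_LABELS = ("TUMOR", "LUNG")

SHAPE_FEATURES = ("SHAPE_Volume_mL", "SHAPE_Sphericity", "SHAPE_Compacity")
CONV_FEATURES = (
    "CONV_HUmin", "CONV_HUmean", "CONV_SUVstd", "CONV_HUmax",
    "CONV_HUQ1", "CONV_HUQ3", "TLG_mL",
)
HISTO_FEATURES = (
    "HISTO_Skewness", "HISTO_Kurtosis", "HISTO_Entropy_log10", "HISTO_Energy",
)

_FAMILY_MEMBERS = {
    "GLCM": tuple(f"GLCM_{n}" for n in GLCM_FEATURES),
    "GLRLM": tuple(f"GLRLM_{n}" for n in GLRLM_FEATURES),
    "NGLDM": tuple(f"NGLDM_{n}" for n in NGLDM_FEATURES),
    "GLZLM": tuple(f"GLZLM_{n}" for n in GLZLM_FEATURES),
    "SHAPE": SHAPE_FEATURES,
    "CONV": CONV_FEATURES,
    "HISTO": HISTO_FEATURES,
}


@dataclass(frozen=True)
class CatalogEntry:
    roi: str
    family: str
    name: str

    @property
    def column(self) -> str:
        return f"{self.roi}_{self.name}"


class FeatureCatalog:
    """The ordered list of (ROI, family, feature) triples — 92 entries."""

    def __init__(self, entries: list[CatalogEntry] | None = None):
        if entries is None:
            entries = [
                CatalogEntry(roi, family, name)
                for roi in ROI_LABELS
                for family, names in _FAMILY_MEMBERS.items()
                for name in names
            ]
        self.entries = list(entries)
        columns = [e.column for e in self.entries]
        if len(set(columns)) != len(columns):
            raise DomainError("catalog feature names must be unique")

    @property
    def columns(self) -> list[str]:
        return [e.column for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def per_roi(self, roi: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.roi == roi]

    def to_json(self, path) -> None:
        payload = [
            {"roi": e.roi, "family": e.family, "name": e.name} for e in self.entries
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([CatalogEntry(d["roi"], d["family"], d["name"]) for d in payload])


def default_catalog() -> FeatureCatalog:
    """46 features per ROI, 92 in total."""
    return FeatureCatalog()


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------

def compute_first_order(
    sub: MaskedSubvolume, dv: DiscretizedVolume | None = None
) -> dict[str, float]:
    """Conventional HU statistics plus histogram indices on the 400-bin
    discretized distribution.

    The standard deviation is the population (divide-by-N) convention;
    skewness/kurtosis (excess) are computed on the binned values and set to 0
    for a zero-variance ROI. ``TLG_mL = HUmean x Volume_mL``.
    """
    hu = sub.hu_values
    if hu.size == 0:
        raise DegenerateROIError("first-order features need a non-empty ROI")
    if dv is None:
        from .imaging import discretize

        dv = discretize(sub)
    volume_ml = hu.size * float(np.prod(sub.spacing)) / 1000.0
    mean = float(hu.mean())
    out = {
        "CONV_HUmin": float(hu.min()),
        "CONV_HUmean": mean,
        "CONV_SUVstd": float(hu.std(ddof=0)),
        "CONV_HUmax": float(hu.max()),
        "CONV_HUQ1": float(np.percentile(hu, 25)),
        "CONV_HUQ3": float(np.percentile(hu, 75)),
        "TLG_mL": mean * volume_ml,
    }
    binned = dv.bins[dv.valid]
    counts = np.bincount(binned, minlength=dv.n_bins).astype(float)
    p = counts[counts > 0] / binned.size
    if binned.std(ddof=0) > 0:
        skew = float(stats.skew(binned, bias=True))
        kurt = float(stats.kurtosis(binned, bias=True))  # excess
    else:
        skew, kurt = 0.0, 0.0
    out.update(
        {
            "HISTO_Skewness": skew,
            "HISTO_Kurtosis": kurt,
            "HISTO_Entropy_log10": float(-(p * np.log10(p)).sum()),
            "HISTO_Energy": float((p**2).sum()),
        }
    )
    return out


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------

def _voxel_face_area(mask: np.ndarray, spacing) -> float:
    """Exposed-face surface area in mm^2 by voxel-face counting."""
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, face in enumerate(face_areas):
        m = np.moveaxis(mask, axis, 0)
        # faces between neighbouring voxels along the axis
        interior = np.logical_xor(m[1:], m[:-1]).sum()
        boundary = m[0].sum() + m[-1].sum()  # faces on the array border
        area += float(interior + boundary) * face
    return area


def _mesh_area(mask: np.ndarray, spacing) -> float:
    """Surface area in mm^2 from a marching-cubes mesh of the mask."""
    from skimage import measure

    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def compute_shape(
    mask: np.ndarray, spacing=DEFAULT_SPACING, area_method: str = "mesh"
) -> dict[str, float]:
    """Volume (mL), sphericity and compacity of a binary ROI.

    Sphericity = pi^(1/3) (6V)^(2/3) / A with V in mm^3 and A the surface
    area in mm^2 (1 for a perfect ball, lower for rough shapes); A comes
    from a marching-cubes mesh by default (``area_method="mesh"``), which
    converges to the true area of smooth shapes, or from voxel-face
    counting (``"voxel"``), which overestimates smooth surfaces by up to
    ~50% but is exact for axis-aligned boxes. Compacity = A^(3/2) / V,
    dimensionless, increasing with surface irregularity.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateROIError("shape features need a non-empty mask")
    voxel_mm3 = float(np.prod(spacing))
    volume_mm3 = mask.sum() * voxel_mm3
    if area_method == "mesh":
        area_mm2 = _mesh_area(mask, spacing)
    elif area_method == "voxel":
        area_mm2 = _voxel_face_area(mask, spacing)
    else:
        raise DomainError(f"unknown area method '{area_method}'")
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume_mm3) ** (2.0 / 3.0) / area_mm2
    return {
        "SHAPE_Volume_mL": volume_mm3 / 1000.0,
        "SHAPE_Sphericity": float(sphericity),
        "SHAPE_Compacity": float(area_mm2 ** 1.5 / volume_mm3),
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_roi_features(
    volume: CTVolume, mask: ROIMask, target_spacing=DEFAULT_SPACING
) -> dict[str, float]:
    """All 46 features of one ROI (names without the ROI prefix)."""
    sub, dv = preprocess_roi(volume, mask, target_spacing)
    out: dict[str, float] = {}
    out.update(compute_glcm_features(dv))
    out.update(compute_glrlm_features(dv))
    out.update(compute_ngldm_features(dv))
    out.update(compute_glzlm_features(dv))
    out.update(compute_shape(sub.valid, sub.spacing))
    out.update(compute_first_order(sub, dv))
    return out


def extract_features(
    volume: CTVolume,
    tumor: ROIMask,
    lung: ROIMask,
    catalog: FeatureCatalog | None = None,
    target_spacing=DEFAULT_SPACING,
    exclude_gtv_from_lung: bool = True,
) -> dict[str, float]:
    """Run the full preprocessing + feature chain for both ROIs.

    Returns a mapping with exactly one finite value per catalog entry,
    names prefixed ``TUMOR_`` / ``LUNG_``. The tumor is subtracted from the
    lung mask first (lung delineations exclude the GTV).
    """
    catalog = catalog or default_catalog()
    if exclude_gtv_from_lung:
        lung = exclude_tumor_from_lung(lung, tumor)
    values: dict[str, float] = {}
    for roi_label, mask in (("TUMOR", tumor), ("LUNG", lung)):
        try:
            feats = extract_roi_features(volume, mask, target_spacing)
        except Exception as exc:
            raise type(exc)(f"{roi_label} ROI: {exc}") from exc
        for entry in catalog.per_roi(roi_label):
            if entry.name not in feats:
                raise SchemaError(f"feature {entry.name} missing for {roi_label}")
            values[entry.column] = feats[entry.name]
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise DomainError(f"non-finite feature values: {bad}")
    return values


def feature_table(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-patient feature dicts into a table (index = patient_id)."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
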