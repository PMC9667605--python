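"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without any external data:

* :func:`make_phantom` builds a CT subvolume in HU containing an ellipsoidal
  tumor inside a lung field. Texture heterogeneity is spatially correlated
  noise (smoothed white noise, kernel width = correlation length, rescaled
  to unit variance before amplitude scaling), which is enough to move
  run/zone statistics in the documented directions. It emulates the contrast
  between a heterogeneous and a homogeneous presentation; it does not
  attempt anatomically realistic lungs, vasculature or acquisition physics.
* :func:`make_feature_cohort` draws labelled feature tables with a planted
  subset of informative features at stated standardized effect sizes —
  the stand-in for a real per-patient radiomic table.
* :func:`make_survival` attaches per-class event times (exponential by
  default, Weibull optional) with independent censoring, in months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, SchemaError
from .imaging import CTVolume, ROIMask


@dataclass
class PhantomConfig:
    """Geometry and texture of a synthetic thoracic subvolume.

    HU baselines follow CT conventions: aerated lung around -850 HU,
    soft-tissue tumor around +30 HU. ``tumor_heterogeneity`` and
    ``lung_texture`` are noise standard deviations in HU;
    ``correlation_length_mm`` sets the smoothing kernel of the correlated
    noise field.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    tumor_center: tuple[float, float, float] | None = None  # voxels; default = grid centre
    tumor_semiaxes_mm: tuple[float, float, float] = (12.0, 10.0, 12.0)
    tumor_mean_hu: float = 30.0
    tumor_heterogeneity: float = 60.0
    lung_baseline_hu: float = -850.0
    lung_texture: float = 40.0
    body_hu: float = 40.0
    correlation_length_mm: float = 3.0
    seed: int | None = None

    def __post_init__(self):
        if self.tumor_heterogeneity < 0 or self.lung_texture < 0:
            raise ConfigError("noise amplitudes must be >= 0")


def _correlated_noise(shape, spacing, length_mm, rng) -> np.ndarray:
    """Unit-variance spatially correlated field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    sigma = [max(length_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_phantom(cfg: PhantomConfig) -> tuple[CTVolume, ROIMask, ROIMask]:
    """Build (CT volume, tumor mask, lung mask); reproducible from the seed.

    The lung field is an ellipsoidal region filling most of the grid; the
    tumor is a smaller ellipsoid inside it. The lung mask excludes the
    tumor. HU = tissue baseline + amplitude x correlated noise.
    """
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.shape
    centre = cfg.tumor_center or ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    def ellipsoid(c, semiaxes_mm):
        sx, sy, sz = cfg.spacing
        return (
            ((x - c[0]) * sx / semiaxes_mm[0]) ** 2
            + ((y - c[1]) * sy / semiaxes_mm[1]) ** 2
            + ((z - c[2]) * sz / semiaxes_mm[2]) ** 2
        ) <= 1.0

    tumor = ellipsoid(centre, cfg.tumor_semiaxes_mm)
    if not tumor.any():
        raise ConfigError("tumor ellipsoid misses the voxel grid entirely")
    if tumor[0, :, :].any() or tumor[-1, :, :].any() or tumor[:, 0, :].any() \
            or tumor[:, -1, :].any() or tumor[:, :, 0].any() or tumor[:, :, -1].any():
        raise ConfigError("tumor ellipsoid extends outside the grid")
    lung_semi = (
        (nx / 2 - 1) * cfg.spacing[0],
        (ny / 2 - 1) * cfg.spacing[1],
        (nz / 2) * cfg.spacing[2],
    )
    lung_all = ellipsoid(((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2), lung_semi)
    lung = lung_all & ~tumor

    grid = np.full(cfg.shape, cfg.body_hu, dtype=float)
    lung_noise = _correlated_noise(cfg.shape, cfg.spacing, cfg.correlation_length_mm, rng)
    tumor_noise = _correlated_noise(cfg.shape, cfg.spacing, cfg.correlation_length_mm, rng)
    grid[lung] = cfg.lung_baseline_hu + cfg.lung_texture * lung_noise[lung]
    grid[tumor] = cfg.tumor_mean_hu + cfg.tumor_heterogeneity * tumor_noise[tumor]

    volume = CTVolume(grid=grid, spacing=cfg.spacing)
    return volume, ROIMask(tumor.astype(np.uint8), "tumor"), ROIMask(lung.astype(np.uint8), "lung")


# ---------------------------------------------------------------------------
# feature cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """A labelled feature cohort with planted signal.

    ``informative`` maps feature names to standardized mean shifts between
    the classes (positive class shifted up). All other features are pure
    unit-variance noise. Survival: per-class exponential (or Weibull) event
    times in months with independent uniform censoring.
    """

    n: int = 60
    prevalence: float = 0.5
    informative: dict[str, float] = field(default_factory=dict)
    mean_survival_months: tuple[float, float] = (60.0, 12.0)  # (class 0, class 1)
    weibull_shape: float | None = None
    censoring_rate: float = 0.2
    followup_months: float = 120.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 6:
            raise ConfigError("cohort needs n >= 6")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must be in (0, 1)")
        if not all(np.isfinite(v) for v in self.informative.values()):
            raise ConfigError("effect sizes must be finite")


def make_feature_cohort(
    spec: CohortSpec, feature_names: list[str]
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Draw (feature table, labels, informative-feature list).

    Labels are Bernoulli(prevalence) with both classes forced present;
    informative columns get a +effect mean shift in the positive class.
    """
    unknown = [f for f in spec.informative if f not in feature_names]
    if unknown:
        raise SchemaError(f"informative features not in catalog: {unknown}")
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.prevalence).astype(int)
    if labels.sum() in (0, spec.n):  # force both classes
        labels[rng.integers(spec.n)] = 1 - labels[0]
    X = rng.standard_normal((spec.n, len(feature_names)))
    table = pd.DataFrame(X, columns=feature_names)
    for name, effect in spec.informative.items():
        table[name] += effect * labels
    table.index = [f"P{i:04d}" for i in range(spec.n)]
    table.index.name = "patient_id"
    return table, labels, list(spec.informative)


def make_survival(labels, spec: CohortSpec) -> pd.DataFrame:
    """Event times per class with independent censoring; months.

    Class means come from ``spec.mean_survival_months``; a mean of ``inf``
    yields no event within the follow-up horizon. ``censoring_rate`` is the
    expected fraction of records randomly censored before their event
    (uniform on (0, event time)); subjects alive at the follow-up horizon
    are administratively censored there. A censoring rate of 1 yields no
    events at all.
    """
    import math

    labels = np.asarray(labels).astype(int)
    means = spec.mean_survival_months
    if any(m <= 0 for m in means):
        raise ConfigError("mean survival must be positive (use inf for no events)")
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    n = labels.size
    event_time = np.empty(n)
    for cls in (0, 1):
        sel = labels == cls
        mean = means[cls]
        if np.isinf(mean):
            event_time[sel] = np.inf
        elif spec.weibull_shape:
            k = spec.weibull_shape
            lam = mean / math.gamma(1 + 1 / k)
            event_time[sel] = lam * rng.weibull(k, size=sel.sum())
        else:
            event_time[sel] = rng.exponential(mean, size=sel.sum())
    horizon = np.minimum(event_time, spec.followup_months)
    censored = rng.random(n) < spec.censoring_rate
    time = np.where(censored, rng.uniform(0, 1, size=n) * horizon, horizon)
    event = ((~censored) & (event_time <= spec.followup_months)).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "true_class": labels,
        }
    ).set_index("patient_id")
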