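"""Ground-truthed synthetic data: vascular tube phantoms and patient cohorts.

Two generators live here.

``generate_vb_phantom`` builds a TOF-like intensity volume containing a
Y-shaped vertebrobasilar system — two vertebral arteries (VA) of
configurable diameter joining at a confluence into one basilar artery (BA)
with a configurable planar lateral bow — together with the analytic
centerlines, radii, and planted dominance/bending labels, so every stage of
the measurement pipeline can be checked against closed-form ground truth.

``generate_cohort`` draws a synthetic patient table whose marginal
frequencies (vertebral dominance, basilar curve direction, WMH prevalence,
risk-factor rates, posterior-communicating-artery status) and whose planted
associations (dominance–curve anticorrelation, lateralized lesion burden)
match the observational cohort the analysis battery expects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import IntensityVolume

__all__ = [
    "ParametricCurve",
    "PhantomGroundTruth",
    "PhantomConfig",
    "IntensityParams",
    "EffectConfig",
    "make_parametric_centerline",
    "arc_through",
    "sweep_tube_volume",
    "generate_vb_phantom",
    "generate_cohort",
]

CURVE_KINDS = ("straight", "planar-arc", "helix", "composite")


# ---------------------------------------------------------------------------
# Parametric curves
# ---------------------------------------------------------------------------

@dataclass
class ParametricCurve:
    """A sampled space curve with its analytic curvature/torsion profiles.

    Points are ordered by arc length (mm); ``kappa`` and ``tau`` hold the
    closed-form Frenet curvature and torsion (1/mm) at each sample, used as
    the oracle for the discrete morphometry estimators.
    """

    kind: str
    params: dict
    points: np.ndarray  # (n, 3) mm
    kappa: np.ndarray   # (n,) 1/mm, >= 0
    tau: np.ndarray     # (n,) 1/mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("curve needs >= 2 sample points of dimension 3")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("sample points must be strictly ordered by arc length")
        if np.any(self.kappa < 0):
            raise ValueError("analytic curvature must be non-negative")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        """Arc/chord - 1 (dimensionless; 0 for a straight segment)."""
        chord = self.chord_length
        if chord <= 1e-12:
            raise ValueError("coincident endpoints: tortuosity undefined")
        return self.arc_length / chord - 1.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n <= 1e-12:
        raise ValueError("zero-length direction vector")
    return v / n


def make_parametric_centerline(kind: str, *, step: float = 0.25, **params) -> ParametricCurve:
    """Build a sampled curve of the given kind with analytic kappa/tau.

    Kinds
    -----
    straight : ``start``, ``end`` (mm). kappa = tau = 0.
    planar-arc : ``radius`` R (mm), ``angle`` (rad), optional ``center``,
        ``u``/``v`` orthonormal in-plane axes. kappa = 1/R, tau = 0.
    helix : ``a`` (radius, mm), ``b`` (pitch parameter, mm/rad), ``angle``
        (total turn, rad). kappa = a/(a^2+b^2), tau = b/(a^2+b^2).
    composite : ``segments`` — list of ParametricCurve joined end-to-start
        (each segment translated so it starts where the previous ended).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if kind == "straight":
        start = np.asarray(params["start"], dtype=float)
        end = np.asarray(params["end"], dtype=float)
        length = np.linalg.norm(end - start)
        if length <= 0:
            raise ValueError("straight segment needs distinct endpoints")
        n = max(int(math.ceil(length / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts = start + t * (end - start)
        return ParametricCurve(kind, dict(params), pts, np.zeros(n), np.zeros(n))
    if kind == "planar-arc":
        R = float(params["radius"])
        angle = float(params["angle"])
        if R <= 0 or angle <= 0:
            raise ValueError("planar-arc needs radius > 0 and angle > 0")
        center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), dtype=float)
        u = _unit(np.asarray(params.get("u", (1.0, 0.0, 0.0)), dtype=float))
        v = _unit(np.asarray(params.get("v", (0.0, 0.0, 1.0)), dtype=float))
        n = max(int(math.ceil(R * angle / step)) + 1, 2)
        th = np.linspace(0.0, angle, n)
        pts = center + R * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))
        return ParametricCurve(kind, dict(params), pts,
                               np.full(n, 1.0 / R), np.zeros(n))
    if kind == "helix":
        a = float(params["a"])
        b = float(params["b"])
        angle = float(params.get("angle", 2.0 * math.pi))
        if a <= 0 or angle <= 0:
            raise ValueError("helix needs a > 0 and angle > 0")
        speed = math.hypot(a, b)
        n = max(int(math.ceil(speed * angle / step)) + 1, 2)
        th = np.linspace(0.0, angle, n)
        pts = np.column_stack([a * np.cos(th), a * np.sin(th), b * th])
        denom = a * a + b * b
        return ParametricCurve(kind, dict(params), pts,
                               np.full(n, a / denom), np.full(n, b / denom))
    if kind == "composite":
        segments = list(params["segments"])
        if not segments:
            raise ValueError("composite needs at least one segment")
        pts, kap, tau = [segments[0].points], [segments[0].kappa], [segments[0].tau]
        for seg in segments[1:]:
            shift = pts[-1][-1] - seg.points[0]
            pts.append(seg.points[1:] + shift)
            kap.append(seg.kappa[1:])
            tau.append(seg.tau[1:])
        return ParametricCurve(kind, dict(params),
                               np.vstack(pts), np.concatenate(kap), np.concatenate(tau))
    raise ValueError(f"unknown curve kind {kind!r}")


def arc_through(start, end, sagitta: float, bulge_dir, *, step: float = 0.25) -> ParametricCurve:
    """Circular arc from ``start`` to ``end`` bowing ``sagitta`` mm toward
    ``bulge_dir`` (a direction with a component perpendicular to the chord).

    With sagitta s and chord c the circle radius is R = (c^2/4 + s^2) / (2 s);
    the arc's maximum distance from the chord is exactly s. sagitta = 0
    degenerates to the straight segment.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    chord_vec = end - start
    c = np.linalg.norm(chord_vec)
    if c <= 0:
        raise ValueError("arc endpoints coincide")
    if sagitta < 0:
        raise ValueError("sagitta must be non-negative")
    if sagitta < 1e-9:
        return make_parametric_centerline("straight", start=start, end=end, step=step)
    if sagitta >= c / 2.0:
        raise ValueError("sagitta must be smaller than half the chord length")
    t_hat = chord_vec / c
    b = np.asarray(bulge_dir, dtype=float)
    b = b - np.dot(b, t_hat) * t_hat  # component perpendicular to the chord
    n_hat = _unit(b)
    R = (c * c / 4.0 + sagitta * sagitta) / (2.0 * sagitta)
    half_angle = math.asin((c / 2.0) / R)
    center = (start + end) / 2.0 + (sagitta - R) * n_hat
    # parametrize from start to end through the bulge apex
    n = max(int(math.ceil(2.0 * R * half_angle / step)) + 1, 2)
    th = np.linspace(-half_angle, half_angle, n)
    pts = center[None, :] + R * (np.outer(np.sin(th), t_hat) + np.outer(np.cos(th), n_hat))
    return ParametricCurve("planar-arc",
                           {"radius": R, "angle": 2 * half_angle, "sagitta": sagitta},
                           pts, np.full(n, 1.0 / R), np.zeros(n))


# ---------------------------------------------------------------------------
# Tube phantom
# ---------------------------------------------------------------------------

@dataclass
class IntensityParams:
    """Gaussian intensity model compatible with 850/2500 double thresholds."""

    fg_mean: float = 1800.0
    fg_sd: float = 150.0
    bg_mean: float = 300.0
    bg_sd: float = 100.0


@dataclass
class PhantomGroundTruth:
    """Analytic description of a planted vertebrobasilar phantom."""

    curves: dict            # label -> ParametricCurve; labels va_left, va_right, ba
    radii: dict             # label -> tube radius (mm)
    confluence: np.ndarray  # (3,) mm
    basilar_top: np.ndarray  # (3,) mm
    deviation_extent_mm: float
    deviation_direction: str  # left | right | even

    def __post_init__(self) -> None:
        self.confluence = np.asarray(self.confluence, dtype=float)
        self.basilar_top = np.asarray(self.basilar_top, dtype=float)
        for lbl in ("va_left", "va_right"):
            if not np.allclose(self.curves[lbl].points[-1], self.confluence, atol=1e-6):
                raise ValueError(f"{lbl} must terminate at the confluence")
        if not np.allclose(self.curves["ba"].points[0], self.confluence, atol=1e-6):
            raise ValueError("ba must start at the confluence")
        sign = {"left": 1.0, "right": -1.0, "even": 0.0}[self.deviation_direction]
        if sign == 0.0 and self.deviation_extent_mm > 1e-6 and self.deviation_direction == "even":
            pass  # an 'even' phantom may still have sub-threshold extent
        if sign != 0.0 and self.deviation_extent_mm <= 0:
            raise ValueError("non-even direction requires positive deviation extent")

    @property
    def tortuosity(self) -> dict:
        return {lbl: c.tortuosity for lbl, c in self.curves.items()}


def sweep_tubes(centerlines: dict, radii: dict, spacing,
                intensity_params: IntensityParams | None = None,
                seed: int | None = 0,
                margin_mm: float = 3.0) -> IntensityVolume:
    """Rasterize tubes of constant radius around polyline centerlines into a
    TOF-like intensity volume (voxel centre in/out; no partial-volume model).

    ``centerlines`` maps label -> (n, 3) points in mm (or ParametricCurve);
    ``radii`` maps label -> tube radius in mm.
    """
    ip = intensity_params or IntensityParams()
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    min_r = min(radii.values())
    if np.max(spacing) > min_r / 2.0:
        raise ValueError(
            f"spacing {spacing.max():.3g} mm cannot resolve tube radius "
            f"{min_r:.3g} mm (need radius >= 2 voxels)")
    lines = {lbl: (c.points if isinstance(c, ParametricCurve) else np.asarray(c, float))
             for lbl, c in centerlines.items()}
    all_pts = np.vstack(list(lines.values()))
    max_r = max(radii.values())
    lo = all_pts.min(axis=0) - max_r - margin_mm
    hi = all_pts.max(axis=0) + max_r + margin_mm
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo
    idx = np.indices(shape).reshape(3, -1).T
    centers = origin + idx * spacing

    fg = np.zeros(len(centers), dtype=bool)
    for lbl, pts in lines.items():
        dense = _densify(pts, np.min(spacing) / 2.0)
        dist, _ = cKDTree(dense).query(centers, workers=-1)
        fg |= dist <= radii[lbl]
    fg = fg.reshape(shape)

    rng = np.random.default_rng(seed)
    data = rng.normal(ip.bg_mean, ip.bg_sd, size=tuple(shape))
    data[fg] = rng.normal(ip.fg_mean, ip.fg_sd, size=int(fg.sum()))
    np.clip(data, 0.0, None, out=data)
    return IntensityVolume(data, spacing, origin)


def sweep_tube_volume(ground_truth: PhantomGroundTruth, spacing,
                      intensity_params: IntensityParams | None = None,
                      seed: int | None = 0,
                      margin_mm: float = 3.0) -> IntensityVolume:
    """Rasterize a phantom's labeled tubes; see :func:`sweep_tubes`."""
    return sweep_tubes(ground_truth.curves, ground_truth.radii, spacing,
                       intensity_params, seed, margin_mm)


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    """Linear oversampling of a polyline so gaps never exceed ``step``."""
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        n = max(int(math.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


@dataclass
class PhantomConfig:
    """Geometry of the planted Y: VA diameters, BA diameter and lateral bow.

    Defaults are typical adult calibres: VA ~2.8-3.4 mm, BA ~3.2 mm, BA
    length ~24 mm, VAs ~28 mm descending at ~20 degrees lateral tilt.
    """

    va_diameter_left: float = 3.4
    va_diameter_right: float = 2.8
    ba_diameter: float = 3.2
    ba_length: float = 24.0
    ba_bend_mm: float = 0.0            # planted lateral bow (sagitta, mm)
    ba_bend_side: str = "even"         # left | right | even
    va_length_z: float = 22.0          # vertical drop of each VA (mm)
    va_offset_x: float = 9.0           # lateral start offset of each VA (mm)
    va_sagitta: float = 1.0            # gentle in-plane VA curvature (mm)
    dominance_threshold: float = 0.3   # mm, diameter-difference rule

    def validate(self) -> None:
        for name in ("va_diameter_left", "va_diameter_right", "ba_diameter",
                     "ba_length", "va_length_z", "va_offset_x"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ba_bend_side not in ("left", "right", "even"):
            raise ValueError("ba_bend_side must be left, right or even")
        if self.ba_bend_side == "even" and self.ba_bend_mm != 0.0:
            raise ValueError("even bend side requires ba_bend_mm == 0")
        if self.ba_bend_side != "even" and self.ba_bend_mm <= 0.0:
            raise ValueError("a left/right bend requires ba_bend_mm > 0")
        if self.ba_bend_mm >= self.ba_length / 2.0:
            raise ValueError("BA bend must be smaller than half the BA length")


def generate_vb_phantom(config: PhantomConfig | None = None, seed: int | None = 0,
                        spacing=0.5,
                        intensity_params: IntensityParams | None = None,
                        ) -> tuple[IntensityVolume, PhantomGroundTruth]:
    """Plant a connected Y-shaped vertebrobasilar phantom.

    The confluence sits at the origin; the BA rises along +z with an optional
    planar lateral bow (+x = left); the VAs descend from (+/-va_offset_x, 0,
    -va_length_z) to the confluence with a gentle outward arc.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    confluence = np.zeros(3)
    top = np.array([0.0, 0.0, cfg.ba_length])
    sign = {"left": 1.0, "right": -1.0, "even": 0.0}[cfg.ba_bend_side]
    ba = arc_through(confluence, top, cfg.ba_bend_mm if sign else 0.0,
                     np.array([sign if sign else 1.0, 0.0, 0.0]))
    curves = {"ba": ba}
    for lbl, sx in (("va_left", +1.0), ("va_right", -1.0)):
        start = np.array([sx * cfg.va_offset_x, 0.0, -cfg.va_length_z])
        curves[lbl] = arc_through(start, confluence, cfg.va_sagitta,
                                  np.array([sx, 0.0, 0.0]))
    radii = {"va_left": cfg.va_diameter_left / 2.0,
             "va_right": cfg.va_diameter_right / 2.0,
             "ba": cfg.ba_diameter / 2.0}
    gt = PhantomGroundTruth(curves=curves, radii=radii, confluence=confluence,
                            basilar_top=top,
                            deviation_extent_mm=cfg.ba_bend_mm,
                            deviation_direction=cfg.ba_bend_side)
    vol = sweep_tube_volume(gt, spacing, intensity_params, seed)
    return vol, gt


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

# Conditional P(curve direction | dominance), rows = dominance (left, even,
# right), columns = curve (left, even, right). Calibrated so the curve
# marginal matches the observed (41, 106, 143)/290 split and the population
# Spearman correlation between dominance and curve codes equals -0.56.
_CURVE_GIVEN_DOMINANCE = {
    "left": (0.05712486186201006, 0.14768866725300164, 0.7951864708849883),
    "even": (0.05712486186201006, 0.7119692917371487, 0.23090584640084122),
    "right": (0.34700028580884656, 0.45375934233097204, 0.19924037186018143),
}

_SIDES = ("left", "even", "right")
_REGIONS = ("VA", "BA", "PCA")


@dataclass
class EffectConfig:
    """Study conditions for the synthetic cohort.

    Marginal frequencies default to the observed cohort: n = 290,
    dominance split 139/84/66 (left/right/even, of 289 classifiable),
    WMH prevalence 204/290, group-specific age/sex/risk-factor rates,
    and PCom status 72/56/67/95 (both / left-absent / right-absent /
    both-absent). Effect strengths are log-odds of lesion burden landing
    on the side the hemodynamic model predicts (non-dominant side for the
    VA region; opposite the basilar curve for the BA region) and a per-mm
    logistic slope of PCA-region laterality on signed basilar deviation.
    """

    n: int = 290
    dominance_probs: tuple = (139 / 289, 66 / 289, 84 / 289)  # left, even, right
    curve_given_dominance: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in _CURVE_GIVEN_DOMINANCE.items()})
    wmh_prevalence: float = 204 / 290
    age_wmh: tuple = (57.6, 16.7)      # mean, SD (years)
    age_control: tuple = (40.2, 13.0)
    female_rate_wmh: float = 118 / 204
    female_rate_control: float = 54 / 86
    risk_rates_wmh: dict = field(default_factory=lambda: {
        "hypertension": 115 / 204, "diabetes": 34 / 204, "hyperlipidemia": 14 / 204})
    risk_rates_control: dict = field(default_factory=lambda: {
        "hypertension": 11 / 86, "diabetes": 4 / 86, "hyperlipidemia": 4 / 86})
    pcom_probs: tuple = (72 / 290, 56 / 290, 67 / 290, 95 / 290)
    # effect strengths
    va_laterality_strength: float = 2.0    # log-odds toward non-dominant side
    ba_laterality_strength: float = 2.8    # log-odds opposite the curve
    pca_slope_per_mm: float = 0.316        # logistic slope on signed deviation
    morphometry_group_shift: float = 0.5   # SD units, WMH vs control BA indices
    va_morphometry_effect: float = 0.3     # relative kappa/tau excess, non-dominant VA
    # nuisance / shape parameters
    region_probs: dict = field(default_factory=lambda: {"VA": 0.55, "BA": 0.55, "PCA": 0.70})
    lateral_even_prob: float = 0.25        # P(region laterality 'even') given affected
    even_threshold_mm: float = 1.0         # curve 'even' band on signed deviation
    deviation_scale_mm: float = 1.5        # Exp scale of |deviation| beyond the band

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name, vec in (("dominance_probs", self.dominance_probs),
                          ("pcom_probs", self.pcom_probs)):
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for k, row in self.curve_given_dominance.items():
            if abs(sum(row) - 1.0) > 1e-9 or min(row) < 0:
                raise ValueError(f"curve_given_dominance[{k}] must sum to 1")
        if not 0.0 <= self.wmh_prevalence <= 1.0:
            raise ValueError("wmh_prevalence must be in [0, 1]")
        for mu, sd in (self.age_wmh, self.age_control):
            if sd <= 0:
                raise ValueError("age SDs must be positive")

    @classmethod
    def null(cls, n: int = 2000) -> "EffectConfig":
        """Exchangeable configuration: every planted effect removed.

        Group age/sex/risk distributions are equalized, the curve direction
        is independent of dominance, and all laterality and morphometry
        effect strengths are zero — so every battery association is null.
        """
        marginal = (41 / 290, 106 / 290, 143 / 290)
        return cls(
            n=n,
            curve_given_dominance={k: marginal for k in _SIDES},
            age_wmh=(52.4, 17.6), age_control=(52.4, 17.6),
            female_rate_wmh=0.593, female_rate_control=0.593,
            risk_rates_wmh={"hypertension": 126 / 290, "diabetes": 38 / 290,
                            "hyperlipidemia": 18 / 290},
            risk_rates_control={"hypertension": 126 / 290, "diabetes": 38 / 290,
                                "hyperlipidemia": 18 / 290},
            va_laterality_strength=0.0,
            ba_laterality_strength=0.0,
            pca_slope_per_mm=0.0,
            morphometry_group_shift=0.0,
            va_morphometry_effect=0.0,
        )


_CODE = {"right": -1, "even": 0, "left": 1}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_cohort(effect_config: EffectConfig | None = None, seed: int | None = 0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort.

    Returns ``(subjects, lesions)``: one row per subject with covariates,
    dominance/curve labels, morphometry scalars and PCom status; and one row
    per WMH lesion (subject_id, region, side, diameter_mm, confluent,
    diffuse). Fully deterministic under a fixed seed.
    """
    cfg = effect_config or EffectConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n

    dominance = rng.choice(_SIDES, size=n, p=np.asarray(cfg.dominance_probs)[[0, 1, 2]])
    # curve direction conditional on dominance
    curve = np.empty(n, dtype=object)
    for d in _SIDES:
        m = dominance == d
        if m.any():
            curve[m] = rng.choice(_SIDES, size=int(m.sum()),
                                  p=np.asarray(cfg.curve_given_dominance[d]))

    is_wmh = rng.random(n) < cfg.wmh_prevalence
    age = np.where(is_wmh,
                   rng.normal(*cfg.age_wmh, size=n),
                   rng.normal(*cfg.age_control, size=n))
    age = np.clip(age, 20.0, 100.0).round(1)
    female = np.where(is_wmh,
                      rng.random(n) < cfg.female_rate_wmh,
                      rng.random(n) < cfg.female_rate_control)
    risks = {}
    for rf in ("hypertension", "diabetes", "hyperlipidemia"):
        risks[rf] = np.where(is_wmh,
                             rng.random(n) < cfg.risk_rates_wmh[rf],
                             rng.random(n) < cfg.risk_rates_control[rf])
    pcom = rng.choice(["both_detected", "left_absent", "right_absent", "both_absent"],
                      size=n, p=np.asarray(cfg.pcom_probs))

    # VA diameters consistent with the planted dominance label (0.3 mm rule)
    nd = np.clip(rng.normal(2.9, 0.3, size=n), 1.8, None)
    gap = 0.3 + rng.exponential(0.4, size=n)
    even_gap = rng.uniform(-0.25, 0.25, size=n)
    dia_l = np.where(dominance == "left", nd + gap,
                     np.where(dominance == "right", nd, nd + even_gap))
    dia_r = np.where(dominance == "right", nd + gap, nd)

    # signed basilar lateral deviation (+ = left), consistent with direction
    mag_even = rng.uniform(0.0, 0.95 * cfg.even_threshold_mm, size=n)
    mag_curved = cfg.even_threshold_mm + rng.exponential(cfg.deviation_scale_mm, size=n)
    sign_even = rng.choice([-1.0, 1.0], size=n)
    code = np.vectorize(_CODE.get)(curve).astype(float)
    deviation = np.where(code == 0.0, sign_even * mag_even, code * mag_curved)

    # morphometry scalars: BA indices shifted up in the WMH group; VA
    # curvature/torsion elevated on the non-dominant side
    shift = cfg.morphometry_group_shift * is_wmh.astype(float)
    ba_length = rng.normal(23.5, 3.0, size=n) + shift * 3.0
    ba_tort = np.exp(rng.normal(np.log(0.05), 0.5, size=n) + shift * 0.5)
    ba_area = rng.normal(10.3, 1.8, size=n) + shift * 1.8
    kap_base = np.exp(rng.normal(np.log(0.12), 0.4, size=(n, 2)))
    tau_base = np.exp(rng.normal(np.log(4.0), 0.4, size=(n, 2)))
    bump = 1.0 + cfg.va_morphometry_effect
    kap_l = np.where(dominance == "right", kap_base[:, 0] * bump, kap_base[:, 0])
    kap_r = np.where(dominance == "left", kap_base[:, 1] * bump, kap_base[:, 1])
    tau_l = np.where(dominance == "right", tau_base[:, 0] * bump, tau_base[:, 0])
    tau_r = np.where(dominance == "left", tau_base[:, 1] * bump, tau_base[:, 1])

    lesion_rows: list[dict] = []
    region_lat = {rg: np.full(n, "none", dtype=object) for rg in _REGIONS}
    for i in range(n):
        if not is_wmh[i]:
            continue
        affected = [rg for rg in _REGIONS if rng.random() < cfg.region_probs[rg]]
        if not affected:
            affected = [_REGIONS[rng.integers(3)]]
        for rg in affected:
            if rg == "VA":
                logit = -cfg.va_laterality_strength * _CODE[dominance[i]]
            elif rg == "BA":
                logit = -cfg.ba_laterality_strength * _CODE[curve[i]]
            else:
                logit = cfg.pca_slope_per_mm * deviation[i]
            if rng.random() < cfg.lateral_even_prob:
                lat = "even"
            else:
                lat = "left" if rng.random() < _sigmoid(logit) else "right"
            region_lat[rg][i] = lat
            lesion_rows.extend(_realize_lesions(i, rg, lat, rng))

    subjects = pd.DataFrame({
        "subject_id": np.arange(n),
        "age": age,
        "sex": np.where(female, "F", "M"),
        "hypertension": risks["hypertension"],
        "diabetes": risks["diabetes"],
        "hyperlipidemia": risks["hyperlipidemia"],
        "pcom_status": pcom,
        "dominance": dominance.astype(str),
        "va_diameter_left_mm": dia_l.round(2),
        "va_diameter_right_mm": dia_r.round(2),
        "curve_direction": curve.astype(str),
        "ba_deviation_signed_mm": deviation.round(3),
        "ba_deviation_extent_mm": np.abs(deviation).round(3),
        "ba_length_mm": ba_length.round(2),
        "ba_tortuosity": ba_tort.round(4),
        "ba_mean_area_mm2": ba_area.round(2),
        "va_curvature_left": kap_l.round(4),
        "va_curvature_right": kap_r.round(4),
        "va_torsion_left": tau_l.round(3),
        "va_torsion_right": tau_r.round(3),
    })
    lesions = pd.DataFrame(
        lesion_rows,
        columns=["subject_id", "region", "side", "diameter_mm", "confluent", "diffuse"])
    if len(lesions):
        lesions = lesions.astype({"subject_id": int, "diameter_mm": float,
                                  "confluent": bool, "diffuse": bool})
    return subjects, lesions


def _realize_lesions(sid: int, region: str, laterality: str, rng) -> list[dict]:
    """Emit lesion records whose ARWMC scores / >=5 mm counts realize the
    target region laterality exactly (higher score wins; ties broken by
    counting lesions >= 5 mm; double tie = even)."""
    def focal(side, big: bool):
        d = rng.uniform(5.0, 9.0) if big else rng.uniform(2.0, 4.5)
        return {"subject_id": sid, "region": region, "side": side,
                "diameter_mm": round(d, 1), "confluent": False, "diffuse": False}

    def confluent(side, diffuse: bool):
        d = rng.uniform(25.0, 40.0) if diffuse else rng.uniform(12.0, 20.0)
        return {"subject_id": sid, "region": region, "side": side,
                "diameter_mm": round(d, 1), "confluent": True, "diffuse": diffuse}

    def with_score(side, score: int, n_big: int) -> list[dict]:
        rows = []
        if score == 0:
            return rows
        if score >= 2:
            rows.append(confluent(side, diffuse=score == 3))
        for _ in range(n_big):
            rows.append(focal(side, big=True))
        if score == 1 and n_big == 0:
            rows.append(focal(side, big=False))
        if rng.random() < 0.3:  # incidental small focal lesion
            rows.append(focal(side, big=False))
        return rows

    if laterality == "even":
        s = int(rng.integers(1, 3))
        k = int(rng.integers(0, 3)) if s == 1 else int(rng.integers(0, 2))
        if s == 1 and k == 0:
            k = 1
        return with_score("left", s, k) + with_score("right", s, k)
    hi, lo = (laterality, "right" if laterality == "left" else "left")
    if rng.random() < 0.25:  # decided by the >=5 mm tie-break, equal scores
        k_lo = int(rng.integers(0, 2)) + 1
        return with_score(hi, 1, k_lo + 1 + int(rng.integers(0, 2))) + \
            with_score(lo, 1, k_lo)
    s_hi = int(rng.choice([1, 2, 3], p=[0.45, 0.40, 0.15]))
    s_lo = int(rng.integers(0, s_hi))
    rows = with_score(hi, s_hi, int(rng.integers(0, 3)) if s_hi == 1 else int(rng.integers(0, 2)))
    rows += with_score(lo, s_lo, int(rng.integers(0, 2)) if s_lo == 1 else 0)
    return rows
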