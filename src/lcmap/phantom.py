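"""Synthetic data: brainstem MT/non-MT phantoms and simulated cohorts.

No public imaging or subject-level data exist for this kind of study, so
validation runs on synthetic stand-ins with known truth:

* :func:`build_phantom` voxelizes, at the acquisition resolution of
  0.4 x 0.4 x 0.5 mm, an ellipsoidal brainstem containing a midline
  cylindrical fourth ventricle and two parallel LC tubes lateral to it with
  histology-matched geometry (14.5 mm long, 2 x 2 mm cross-section, i.e. an
  analytic bilateral volume of 2 x 58 = 116 mm^3, inside the 112-120 mm^3
  histological band), plus an optional distant neuromelanin distractor blob
  (a substantia-nigra stand-in) that the ventricle-dilation constraint must
  reject.  The MT image encodes the compartment contrast (piecewise-
  constant true enhancement ratio per tissue class); the non-MT image is a
  flat tissue level.  Both carry independent Gaussian noise.
* :func:`simulate_cohort` draws a two-group cohort with a specified
  standardized group difference in ``lc_norm`` and specified rank
  correlations between ``lc_norm`` and the six questionnaire scales, via a
  Gaussian copula followed by monotone marginal transforms.

Regeneration with the same spec and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .volumes import BinaryMask, VolumeGrid


@dataclass
class PhantomSpec:
    """Geometry and signal model of the synthetic brainstem phantom.

    Lengths are millimetres in world space; the grid is centred on the
    world origin.  ``class_ratio_means`` are the true MT/non-MT ratios of
    (fluid, neuromelanin, white matter): fluid highest (no macromolecular
    saturation), NM middle, WM lowest, so the middle-compartment selection
    rule of the classifier is exactly realizable.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 64)
    voxel_size: Tuple[float, float, float] = (0.4, 0.4, 0.5)
    tube_length_mm: float = 14.5
    tube_cross_section_mm: Tuple[float, float] = (2.0, 2.0)
    tube_lateral_offset_mm: float = 3.0  # ventricle wall -> tube centre
    ventricle_radius_mm: float = 2.0
    ventricle_length_mm: float = 24.0
    brainstem_semiaxes_mm: Tuple[float, float, float] = (16.0, 18.5, 15.0)
    #: (centre offset mm in world coords, radius mm) of NM-class blobs
    #: placed outside the constraint zone; default is a substantia-nigra
    #: stand-in 15 mm anterior of the ventricle axis
    distractor_blobs: List[Tuple[Tuple[float, float, float], float]] = field(
        default_factory=lambda: [((0.0, -15.0, 4.0), 2.0)]
    )
    class_ratio_means: Tuple[float, float, float] = (1.00, 0.80, 0.60)
    noise_sd: float = 1.25
    nomt_level: float = 100.0
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self) -> None:
        fov = np.asarray(self.grid_shape) * np.asarray(self.voxel_size)
        semi = np.asarray(self.brainstem_semiaxes_mm)
        if np.any(2 * semi > fov):
            raise ConfigurationError("brainstem ellipsoid does not fit in the grid")
        tube_far = (self.ventricle_radius_mm + self.tube_lateral_offset_mm
                    + self.tube_cross_section_mm[0] / 2)
        if tube_far > semi[0] or self.tube_length_mm / 2 > semi[2]:
            raise ConfigurationError("LC tubes do not fit inside the brainstem")
        if len(set(self.class_ratio_means)) != 3:
            raise ConfigurationError("class ratio means must be pairwise distinct")

    @property
    def analytic_lc_volume_mm3(self) -> float:
        w, h = self.tube_cross_section_mm
        return 2.0 * w * h * self.tube_length_mm

    def affine(self) -> np.ndarray:
        """Diagonal RAS affine with voxel centres symmetric about the origin."""
        vs = np.asarray(self.voxel_size, dtype=np.float64)
        shape = np.asarray(self.grid_shape, dtype=np.float64)
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = vs
        aff[:3, 3] = -vs * (shape - 1) / 2.0
        return aff


@dataclass
class PhantomBundle:
    """Paired images plus ground-truth masks for one synthetic subject."""

    mt: VolumeGrid
    nomt: VolumeGrid
    truth_lc: BinaryMask
    truth_lc_left: BinaryMask
    truth_lc_right: BinaryMask
    truth_ventricle: BinaryMask
    truth_brainstem: BinaryMask
    truth_distractors: BinaryMask
    spec: PhantomSpec
    seed: int


def _world_grids(spec: PhantomSpec):
    aff = spec.affine()
    idx = np.indices(spec.grid_shape, dtype=np.float64)
    x = aff[0, 0] * idx[0] + aff[0, 3]
    y = aff[1, 1] * idx[1] + aff[1, 3]
    z = aff[2, 2] * idx[2] + aff[2, 3]
    return x, y, z


def _tube_mask(x, y, z, cx: float, spec: PhantomSpec) -> np.ndarray:
    """Half-open axis-aligned box: avoids double-counting face voxels."""
    w, h = spec.tube_cross_section_mm
    L = spec.tube_length_mm
    return ((x >= cx - w / 2) & (x < cx + w / 2)
            & (y >= -h / 2) & (y < h / 2)
            & (z >= -L / 2) & (z < L / 2))


def build_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> PhantomBundle:
    """Voxelize the phantom geometry and synthesize the MT / non-MT pair."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    x, y, z = _world_grids(spec)
    aff = spec.affine()

    a, b, c = spec.brainstem_semiaxes_mm
    ellipsoid = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    ventricle = ((x ** 2 + y ** 2 <= spec.ventricle_radius_mm ** 2)
                 & (np.abs(z) <= spec.ventricle_length_mm / 2) & ellipsoid)
    tube_cx = spec.ventricle_radius_mm + spec.tube_lateral_offset_mm
    lc_right = _tube_mask(x, y, z, tube_cx, spec)
    lc_left = _tube_mask(x, y, z, -tube_cx, spec)
    lc = lc_left | lc_right
    distract = np.zeros(spec.grid_shape, dtype=bool)
    for (ox, oy, oz), r in spec.distractor_blobs:
        axis_dist = float(np.hypot(ox, oy)) - spec.ventricle_radius_mm
        if axis_dist <= 4.0:
            raise ConfigurationError(
                "distractor blob too close to the ventricle to be excluded"
            )
        distract |= (x - ox) ** 2 + (y - oy) ** 2 + (z - oz) ** 2 <= r ** 2
    distract &= ellipsoid
    brainstem = ellipsoid & ~ventricle
    lc &= brainstem
    distract &= brainstem & ~lc

    mu_fluid, mu_nm, mu_wm = spec.class_ratio_means
    ratio = np.zeros(spec.grid_shape, dtype=np.float64)
    ratio[brainstem] = mu_wm
    ratio[ventricle] = mu_fluid
    ratio[lc] = mu_nm
    ratio[distract] = mu_nm

    tissue = ellipsoid
    nomt_clean = spec.nomt_level * tissue
    mt_clean = spec.nomt_level * ratio
    noise_mt = rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    noise_nomt = rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    if spec.noise_model == "rician":
        # magnitude of a complex signal with independent channel noise
        q_mt = rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        q_nomt = rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        mt = np.hypot(mt_clean + noise_mt, q_mt)
        nomt = np.hypot(nomt_clean + noise_nomt, q_nomt)
    elif spec.noise_model == "gaussian":
        mt = mt_clean + noise_mt
        nomt = nomt_clean + noise_nomt
    else:
        raise ConfigurationError(f"unknown noise model {spec.noise_model!r}")

    return PhantomBundle(
        mt=VolumeGrid(mt, aff),
        nomt=VolumeGrid(nomt, aff),
        truth_lc=BinaryMask(lc, aff, label="truth_lc"),
        truth_lc_left=BinaryMask(lc_left & lc, aff, label="truth_lc_left"),
        truth_lc_right=BinaryMask(lc_right & lc, aff, label="truth_lc_right"),
        truth_ventricle=BinaryMask(ventricle, aff, label="truth_fourth_ventricle"),
        truth_brainstem=BinaryMask(brainstem, aff, label="truth_brainstem"),
        truth_distractors=BinaryMask(distract, aff, label="truth_distractors"),
        spec=spec,
        seed=seed,
    )


# ------------------------------------------------------------------ cohorts

#: simulation set-points for the dimensional scales: plausible pooled
#: (mean, SD) used as monotone marginal transforms of the copula draws
_SCALE_MARGINALS = {
    "masq_general_distress": (17.6, 9.5),
    "masq_anhedonic_depression": (33.6, 8.5),
    "masq_anxious_arousal": (16.3, 8.5),
    "atq_activation": (35.3, 8.8),
    "atq_attentional": (23.8, 8.8),
    "atq_inhibitory": (34.1, 8.0),
}

SCALE_NAMES = tuple(_SCALE_MARGINALS)


@dataclass
class CohortSimSpec:
    """Set-points of the two-group cohort simulation.

    Defaults echo the analyzed clinical cohort: 12 controls vs 15 patients,
    a standardized group difference of 1.08 in normalized LC volume, and
    the reported rank correlations between ``lc_norm`` and the six scales.
    """

    n_hc: int = 12
    n_pt: int = 15
    true_d: float = 1.08
    true_rhos: Tuple[float, ...] = (0.618, 0.349, 0.483, -0.357, -0.505, -0.545)
    age_range: Tuple[float, float] = (24.0, 57.0)
    male_fraction: float = 0.55
    lc_norm_mean_hc: float = 0.005
    lc_norm_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_pt < 2:
            raise ConfigurationError("need n >= 2 per group")
        if len(self.true_rhos) != len(SCALE_NAMES):
            raise ConfigurationError(f"true_rhos must have {len(SCALE_NAMES)} entries")
        if any(abs(r) >= 1 for r in self.true_rhos):
            raise ConfigurationError("|rho| must be < 1")


def simulate_cohort(spec: CohortSimSpec | None = None) -> pd.DataFrame:
    """Draw one cohort table with the specified effect structure.

    The latent LC variable is unit-variance within group with a mean shift
    of ``true_d`` for patients.  Each scale is coupled to the standardized
    total LC latent through a Gaussian copula whose Pearson correlation is
    chosen as r = 2 sin(pi * rho_s / 6) so that the *Spearman* correlation
    matches the requested value; scales are conditionally independent given
    the LC latent, which keeps the implied correlation matrix positive
    semi-definite for any |rho| < 1.
    """
    spec = spec or CohortSimSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_hc + spec.n_pt
    is_pt = np.concatenate([np.zeros(spec.n_hc), np.ones(spec.n_pt)])

    u = rng.standard_normal(n)
    lc_z = u + spec.true_d * is_pt
    p = spec.n_pt / n
    total_sd = np.sqrt(1.0 + spec.true_d ** 2 * p * (1 - p))
    t_std = (lc_z - spec.true_d * p) / total_sd

    data = {
        "subject_id": [f"S{i:03d}" for i in range(1, n + 1)],
        "group": np.where(is_pt > 0, "PT", "HC"),
        "age": rng.uniform(*spec.age_range, size=n),
        "sex": np.where(rng.random(n) < spec.male_fraction, "M", "F"),
        "lc_norm": spec.lc_norm_mean_hc + spec.lc_norm_sd * lc_z,
    }
    for name, rho in zip(SCALE_NAMES, spec.true_rhos):
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        latent = r * t_std + np.sqrt(1.0 - r ** 2) * rng.standard_normal(n)
        mu, sd = _SCALE_MARGINALS[name]
        data[name] = mu + sd * latent
    return pd.DataFrame(data)


def spec_to_dict(spec) -> dict:
    """JSON-serializable view of a phantom or cohort spec."""
    return asdict(spec)
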