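"""Synthetic paired MRI / synaptic-density-PET phantom cohorts.

Real paired T1-weighted MRI and [11C]UCB-J BP_ND data are clinical and not
redistributable, so this module generates brain-shaped phantoms that emulate
the statistical structure the translation analysis relies on:

* nested soft ellipsoids form a head, a cortical gray-matter ribbon around a
  white-matter core, ventricular CSF, and a separate cerebellum-analog blob
  that serves as the DVR reference region;
* a wedge-partition toy atlas names the regions used in the ROI analyses
  (frontal, insula, hippocampus, amygdala, occipital, parietal, precuneus,
  putamen, pallidum, temporal, anterior cingulate) plus the cerebellum;
* the synaptic-density image is a known deterministic function of local
  gray-matter density — BP_ND = base + gain * GM * regional multiplier — so
  ground truth is recoverable and parameter-recovery testing is possible;
* diagnosis effects co-vary structure and function: an atrophy factor shrinks
  GM probability before both the T1 and the BP_ND are synthesized, and
  regional SV2A multipliers depress binding in disease-typical regions
  (e.g. hippocampal/temporal reduction in the AD analog);
* measurement noise follows a count-statistics analogy: voxel noise SD is
  ``noise_scale / sqrt(dose)``, so low-injected-dose scans (< 5 mCi analog)
  are visibly noisier.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume

DIAGNOSES = ("HC", "SZ", "AD", "CUD")

#: cortical/subcortical ROI names of the published ROI tables, in label order
ROI_NAMES = (
    "frontal", "insula", "hippocampus", "amygdala", "occipital", "parietal",
    "precuneus", "putamen", "pallidum", "temporal", "anterior_cingulate",
)
REFERENCE_ROI = "cerebellum"

#: baseline SV2A multiplier per region; the reference region is modeled as
#: low in specific binding so that DVR contrast against it is informative
BASELINE_SV2A = {name: 1.0 for name in ROI_NAMES}
BASELINE_SV2A[REFERENCE_ROI] = 0.2


@dataclass
class PhantomParams:
    """Geometry, intensity and noise parameters of the generator.

    Defaults give a 64^3 grid at 2 mm for desk-scale work; the full-scale
    acquisition grid (256 x 256 x 207 at 1.219 x 1.219 x 1.231 mm) is
    available by configuration.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_rois: int = 11
    gm_to_sv2a_gain: float = 2.5
    base_bpnd: float = 0.3
    noise_scale: float = 0.5
    seed: int = 0
    #: per-tissue T1 intensity means (GM, WM, CSF), arbitrary units
    t1_tissue_means: tuple[float, float, float] = (0.45, 0.80, 0.08)
    t1_noise_sd: float = 0.01
    bias_field_amplitude: float = 0.05
    #: PET scanner resolution (Gaussian PSF FWHM, mm) applied to the BP_ND
    #: map before noise; parametric PET images are intrinsically smooth
    pet_psf_fwhm_mm: float = 6.0

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if self.gm_to_sv2a_gain <= 0:
            raise ValueError("gm_to_sv2a_gain must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 1 <= self.n_rois <= len(ROI_NAMES):
            raise ValueError(f"n_rois must be in [1, {len(ROI_NAMES)}]")


@dataclass
class DiseaseEffect:
    """Regional SV2A depression and global GM atrophy for one diagnosis."""

    diagnosis: str
    regional_sv2a_multipliers: dict[str, float] = field(default_factory=dict)
    atrophy_factor: float = 1.0

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")
        if not 0.0 < self.atrophy_factor <= 1.0:
            raise ValueError("atrophy_factor must be in (0, 1]")
        for name, m in self.regional_sv2a_multipliers.items():
            if not 0.0 < m <= 1.0:
                raise ValueError(f"multiplier for {name} must be in (0, 1], got {m}")
        if self.diagnosis == "HC":
            if self.atrophy_factor != 1.0 or any(
                m != 1.0 for m in self.regional_sv2a_multipliers.values()
            ):
                raise ValueError("the HC effect must be the identity")
        if self.diagnosis == "AD":
            for roi in ("hippocampus", "temporal"):
                if self.regional_sv2a_multipliers.get(roi, 1.0) >= 1.0:
                    raise ValueError(f"AD effect requires a multiplier < 1 in {roi}")


def default_effects() -> dict[str, DiseaseEffect]:
    """Default diagnosis effects.

    AD follows the reported pattern of widespread SV2A reduction strongest in
    hippocampal/temporal regions together with atrophy; CUD depresses
    hippocampal and prefrontal-analog density; SZ applies milder frontal /
    temporal / anterior-cingulate reductions.  SZ and CUD magnitudes are
    configurable modeling choices, not quantitative claims about the
    diseases.
    """
    return {
        "HC": DiseaseEffect("HC"),
        "AD": DiseaseEffect(
            "AD",
            {"hippocampus": 0.70, "temporal": 0.80, "amygdala": 0.85,
             "frontal": 0.90, "parietal": 0.90},
            atrophy_factor=0.88,
        ),
        "SZ": DiseaseEffect(
            "SZ",
            {"frontal": 0.90, "temporal": 0.92, "anterior_cingulate": 0.90},
            atrophy_factor=0.97,
        ),
        "CUD": DiseaseEffect(
            "CUD",
            {"hippocampus": 0.88, "frontal": 0.90},
            atrophy_factor=0.98,
        ),
    }


@dataclass
class PhantomCase:
    """One synthetic participant: volumes, segments, atlas and metadata."""

    id: str
    diagnosis: str
    dose_mCi: float
    t1: Volume
    bpnd_clean: Volume
    bpnd_noisy: Volume
    gm: Volume
    wm: Volume
    csf: Volume
    atlas: Volume
    roi_table: pd.DataFrame  # columns: label, name

    @property
    def reference_label(self) -> int:
        row = self.roi_table[self.roi_table["name"] == REFERENCE_ROI]
        return int(row["label"].iloc[0])

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.t1.save(d / "t1.nii.gz")
        self.bpnd_clean.save(d / "bpnd_clean.nii.gz")
        self.bpnd_noisy.save(d / "bpnd_noisy.nii.gz")
        self.gm.save(d / "seg_gm.nii.gz")
        self.wm.save(d / "seg_wm.nii.gz")
        self.csf.save(d / "seg_csf.nii.gz")
        self.atlas.save(d / "atlas.nii.gz")
        self.roi_table.to_csv(d / "atlas_labels.tsv", sep="\t", index=False)


def _ellipsoid(u: tuple[np.ndarray, ...], center, semi) -> np.ndarray:
    """Implicit ellipsoid function; < 1 inside, > 1 outside."""
    return sum(((ui - c) / a) ** 2 for ui, c, a in zip(u, center, semi))


def _soft(e: np.ndarray, softness: float = 0.06) -> np.ndarray:
    """Soft membership of the implicit value: sigmoid((1 - e)/softness)."""
    return 1.0 / (1.0 + np.exp(np.clip(-(1.0 - e) / softness, -60, 60)))


def _case_rng(seed: int, case_id: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(case_id.encode())])


def _geometry(params: PhantomParams):
    """Tissue memberships and the wedge atlas on the normalized [-1,1] cube."""
    u = np.meshgrid(
        *[(np.arange(n) + 0.5) / n * 2.0 - 1.0 for n in params.shape], indexing="ij"
    )
    head = _soft(_ellipsoid(u, (0.0, 0.0, 0.02), (0.92, 0.88, 0.85)))
    cerebrum = _soft(_ellipsoid(u, (0.0, 0.08, 0.12), (0.74, 0.66, 0.58)))
    wm_core = _soft(_ellipsoid(u, (0.0, 0.08, 0.12), (0.50, 0.44, 0.38)))
    vent = _soft(_ellipsoid(u, (0.0, 0.10, 0.10), (0.16, 0.22, 0.11)), 0.04)
    cereb = _soft(_ellipsoid(u, (0.0, -0.52, -0.44), (0.40, 0.30, 0.26)), 0.05)
    cereb = cereb * (1.0 - cerebrum)  # cerebellum never overlaps the cerebrum
    return u, head, cerebrum, wm_core, vent, cereb


def _atlas_from_geometry(u, cerebrum, cereb, params: PhantomParams):
    """Wedge-partition atlas: angular sectors of the cerebrum + cerebellum."""
    n = params.n_rois
    theta = np.arctan2(u[1] - 0.08, u[0])  # azimuth about the cerebrum center
    zband = (u[2] > 0.12).astype(int)  # split wedges into upper/lower tiers
    sector = np.floor((theta + np.pi) / (2 * np.pi) * ((n + 1) // 2)).astype(int)
    sector = np.clip(sector, 0, (n + 1) // 2 - 1)
    label = sector * 2 + zband + 1
    label = np.clip(label, 1, n)
    atlas = np.where(cerebrum > 0.5, label, 0)
    ref_label = n + 1
    atlas = np.where(cereb > 0.5, ref_label, atlas)
    names = list(ROI_NAMES[:n]) + [REFERENCE_ROI]
    table = pd.DataFrame({"label": list(range(1, n + 2)), "name": names})
    return atlas.astype(np.int16), table, ref_label


def make_phantom(params: PhantomParams, effect: DiseaseEffect, dose: float,
                 case_id: str) -> PhantomCase:
    """Generate one synthetic participant.

    Deterministic given ``(params.seed, case_id)``.  The T1 intensity is a
    per-tissue mixture modulated by a smooth multiplicative bias field plus
    Gaussian noise; BP_ND is ``base + gain * GM * multiplier(ROI)`` with the
    disease's regional multipliers, and the noisy BP_ND adds Gaussian noise
    of SD ``noise_scale / sqrt(dose)``, clipped at zero.  The atrophy factor
    shrinks GM probability (mass moving to CSF) before both syntheses, so
    structural and functional changes co-vary.
    """
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    if min(params.shape) < 16:
        raise ValueError(f"shape {params.shape} too small to contain the head phantom")
    rng = _case_rng(params.seed, case_id)

    u, head, cerebrum, wm_core, vent, cereb = _geometry(params)
    atlas_arr, roi_table, ref_label = _atlas_from_geometry(u, cerebrum, cereb, params)

    # per-participant anatomical variability: mild global scale jitter of GM
    gm_jitter = 1.0 + 0.04 * rng.standard_normal()

    ribbon = cerebrum * (1.0 - wm_core)
    gm = ribbon * (1.0 - vent) * 0.95 + cereb * 0.80
    wm = cerebrum * wm_core * (1.0 - vent) * 0.95 + cereb * 0.15
    csf = vent * cerebrum + (head - np.maximum(cerebrum, cereb)).clip(0) * 0.55

    gm = np.clip(gm * gm_jitter, 0.0, 1.0)
    # atrophy: GM probability shrinks, displaced volume becomes CSF
    lost = gm * (1.0 - effect.atrophy_factor)
    gm = gm - lost
    csf = np.clip(csf + lost, 0.0, 1.0)

    total = gm + wm + csf
    over = total > 1.0
    scale = np.where(over, 1.0 / np.maximum(total, 1e-9), 1.0)
    gm, wm, csf = gm * scale, wm * scale, csf * scale

    # T1: tissue mixture x smooth bias field + noise, zero outside the head
    mg, mw, mc = params.t1_tissue_means
    bias = rng.standard_normal(params.shape)
    bias = ndimage.gaussian_filter(bias, sigma=[n / 8 for n in params.shape])
    bias /= max(np.abs(bias).max(), 1e-12)
    bias = 1.0 + params.bias_field_amplitude * bias
    t1 = (mg * gm + mw * wm + mc * csf) * bias * head
    t1 = np.clip(t1 + params.t1_noise_sd * rng.standard_normal(params.shape), 0.0, None)

    # BP_ND: deterministic function of GM density and the voxel's region
    mult = np.ones(params.shape)
    for _, row in roi_table.iterrows():
        name, label = row["name"], int(row["label"])
        m = BASELINE_SV2A.get(name, 1.0) * effect.regional_sv2a_multipliers.get(name, 1.0)
        if m != 1.0:
            mult[atlas_arr == label] = m
    brain = np.maximum(cerebrum, cereb)
    bpnd_clean = (params.base_bpnd * brain + params.gm_to_sv2a_gain * gm * mult * brain)
    if params.pet_psf_fwhm_mm > 0:
        sigma_vox = [params.pet_psf_fwhm_mm / 2.355 / s for s in params.voxel_size]
        bpnd_clean = ndimage.gaussian_filter(bpnd_clean, sigma_vox)
    bpnd_clean = np.clip(bpnd_clean, 0.0, None)

    sd = params.noise_scale / np.sqrt(dose)
    bpnd_noisy = np.clip(bpnd_clean + sd * rng.standard_normal(params.shape), 0.0, None)

    vx = params.voxel_size
    f32 = lambda a: Volume(a.astype(np.float32), vx)
    return PhantomCase(
        id=case_id,
        diagnosis=effect.diagnosis,
        dose_mCi=float(dose),
        t1=f32(t1),
        bpnd_clean=f32(bpnd_clean),
        bpnd_noisy=f32(bpnd_noisy),
        gm=f32(gm),
        wm=f32(wm),
        csf=f32(csf),
        atlas=Volume(atlas_arr, vx),
        roi_table=roi_table,
    )


#: study-condition dose distribution (mCi analogs): cohort mean 15.71, SD 4.32
NORMAL_DOSE_MEAN = 15.71
NORMAL_DOSE_SD = 4.32
LOW_DOSE_THRESHOLD = 5.0


def make_cohort(params: PhantomParams, n: int, diagnosis_ratio: dict[str, int],
                n_low_dose: int, seed: int,
                low_dose_threshold: float = LOW_DOSE_THRESHOLD,
                effects: dict[str, DiseaseEffect] | None = None,
                ) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate a cohort and its manifest.

    ``diagnosis_ratio`` maps diagnosis -> participant count and must sum to
    ``n`` (the published cohort is HC:SZ:AD:CUD = 83:24:34:19).  Exactly
    ``n_low_dose`` participants get a dose below ``low_dose_threshold``; the
    rest draw from a normal-dose distribution with mean 15.71 and SD 4.32.
    """
    if sum(diagnosis_ratio.values()) != n:
        raise ValueError(
            f"diagnosis_ratio sums to {sum(diagnosis_ratio.values())}, expected n={n}"
        )
    if n_low_dose > n:
        raise ValueError("n_low_dose cannot exceed n")
    for d in diagnosis_ratio:
        if d not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {d!r}")
    effects = effects or default_effects()
    rng = np.random.default_rng(int(seed) % 2**31)

    diags = [d for d, c in sorted(diagnosis_ratio.items()) for _ in range(c)]
    rng.shuffle(diags)
    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    low_ids = set(rng.choice(ids, size=n_low_dose, replace=False)) if n_low_dose else set()

    doses = []
    for cid in ids:
        if cid in low_ids:
            doses.append(float(rng.uniform(2.2, 0.96 * low_dose_threshold)))
        else:
            d = float(rng.normal(NORMAL_DOSE_MEAN, NORMAL_DOSE_SD))
            doses.append(max(d, low_dose_threshold * 1.2))
    manifest = pd.DataFrame(
        {
            "id": ids,
            "diagnosis": diags,
            "dose_mCi": doses,
            "low_dose": [d < low_dose_threshold for d in doses],
        }
    )
    cases = [
        make_phantom(params, effects[row.diagnosis], row.dose_mCi, row.id)
        for row in manifest.itertuples()
    ]
    return cases, manifest
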