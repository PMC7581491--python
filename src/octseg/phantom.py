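"""Synthetic Stargardt-like OCT phantom generator.

Produces seeded, ground-truthed B-scans, volumes and multi-participant
cohorts that emulate the features of macular SD-OCT in Stargardt
disease: a smooth inner (ILM) and outer (RPE-base/Bruch's membrane)
boundary with a central foveal pit, variable-severity outer-retinal
atrophy with RPE loss and hypertransmission, hyperreflective flecks,
multiplicative speckle, vessel shadows, and low/high macular-volume
participant groups.

Geometry defaults to a desk scale of 256 x 128 px B-scans, 15 slices
per volume, with resolutions chosen so the volume covers the central
6 mm ETDRS zone; the full clinical geometry (1536 x 496 px, 61 slices,
5.7 / 3.9 / 119 um) is available via :meth:`PhantomConfig.paper_scale`.

Boundary rows are stored as fractional pixels; rasterization to region
maps uses floor(row) as the first row of the region below the boundary.
Boundary surfaces are sums of low-frequency cosines plus Gaussian
(en-face) foveal-pit and atrophy profiles whose combined analytic slope
bound is kept at or below 1 px/column, the maximum step the boundary
graph search can follow.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

PIT_SLOPE_FACTOR = np.exp(-0.5)  # max slope of a Gaussian = depth * e^-0.5 / sigma

#: fraction of baseline thickness lost inside a full-severity atrophy lesion
MAX_ATROPHY_FRACTION = 0.45


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BScan:
    """One grayscale OCT slice (rows = depth, columns = lateral)."""

    pixels: np.ndarray  # (H, W) uint8
    lateral_res_um: float = 5.7
    axial_res_um: float = 3.9
    scan_spacing_um: float = 119.0
    participant_id: str = ""
    eye: str = "OD"
    visit: int = 0
    scan_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("BScan pixels must be 2-D")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("BScan intensities must lie in [0, 255]")
            self.pixels = np.round(self.pixels).astype(np.uint8)
        if min(self.lateral_res_um, self.axial_res_um, self.scan_spacing_um) <= 0:
            raise ValueError("resolutions must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def physical_width_mm(self) -> float:
        """Lateral extent in mm (width_px x lateral resolution)."""
        return self.width_px * self.lateral_res_um / 1000.0

    @property
    def physical_depth_mm(self) -> float:
        """Axial extent in mm (height_px x axial resolution)."""
        return self.height_px * self.axial_res_um / 1000.0


@dataclass
class BoundarySet:
    """Per-column ILM and RPE-base row positions (fractional pixels)."""

    ilm_rows: np.ndarray
    rpe_rows: np.ndarray
    valid_start: int = 0
    valid_end: int | None = None

    def __post_init__(self):
        self.ilm_rows = np.asarray(self.ilm_rows, dtype=np.float64)
        self.rpe_rows = np.asarray(self.rpe_rows, dtype=np.float64)
        if self.ilm_rows.shape != self.rpe_rows.shape or self.ilm_rows.ndim != 1:
            raise ValueError("ilm_rows and rpe_rows must be equal-length 1-D arrays")
        if self.valid_end is None:
            self.valid_end = len(self.ilm_rows) - 1
        if not (0 <= self.valid_start <= self.valid_end < len(self.ilm_rows)):
            raise ValueError("invalid valid column range")
        if np.any(self.ilm_rows > self.rpe_rows + 1e-9):
            raise ValueError("ILM must lie at or above the RPE in every column")
        if np.any(self.ilm_rows < 0):
            raise ValueError("boundary rows must be non-negative")

    @property
    def width(self) -> int:
        return len(self.ilm_rows)

    def check_height(self, height_px: int):
        if np.any(self.rpe_rows > height_px - 1):
            raise ValueError("boundary rows exceed image height")

    def copy(self) -> "BoundarySet":
        return BoundarySet(self.ilm_rows.copy(), self.rpe_rows.copy(),
                           self.valid_start, self.valid_end)


@dataclass
class PhantomConfig:
    """Knobs of the synthetic phantom (sizes px, distances um unless noted)."""

    # geometry
    height_px: int = 128
    width_px: int = 256
    n_slices: int = 15
    lateral_res_um: float = 26.0
    axial_res_um: float = 7.5
    scan_spacing_um: float = 450.0

    # boundary surfaces
    base_thickness_um: float = 390.0
    pit_depth_um: float = 150.0
    pit_sigma_um: float = 600.0
    undulation_amp_px: float = 1.0
    undulation_cycles: float = 2.0
    rpe_depth_frac: float = 0.62  # baseline RPE row as a fraction of height

    # atrophy lesions (outer-retinal / RPE loss)
    atrophy_lesions: int = 1
    atrophy_sigma_um: float = 1000.0
    atrophy_severity: float = 0.0  # 0 = healthy, 1 = maximal thinning/RPE loss

    # hyperreflective flecks
    fleck_count: int = 6
    fleck_radius_px: float = 2.0
    fleck_brightness: float = 60.0

    # speckle (multiplicative, Gamma); scale = relative standard deviation
    speckle_scale: float = 0.25

    # vessel shadows
    shadow_count: int = 2
    shadow_sigma_px: float = 4.0
    shadow_attenuation: float = 0.35

    # layer mean intensities (8-bit)
    intensity_vitreous: float = 25.0
    intensity_retina: float = 110.0
    intensity_rpe: float = 200.0
    intensity_choroid: float = 90.0
    intensity_sclera: float = 50.0
    rpe_band_um: float = 30.0
    choroid_band_um: float = 225.0
    hypertransmission_boost: float = 60.0

    def __post_init__(self):
        if min(self.height_px, self.width_px, self.n_slices) <= 0:
            raise ValueError("image sizes must be positive")
        if min(self.lateral_res_um, self.axial_res_um, self.scan_spacing_um) <= 0:
            raise ValueError("resolutions must be positive")
        if not 0.0 <= self.atrophy_severity <= 1.0:
            raise ValueError("atrophy severity must lie in [0, 1]")
        for name in ("intensity_vitreous", "intensity_retina", "intensity_rpe",
                     "intensity_choroid", "intensity_sclera"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.speckle_scale < 0 or self.fleck_count < 0 or self.shadow_count < 0:
            raise ValueError("noise/feature counts must be non-negative")
        self._check_thickness()
        self._check_slope()

    # -- validity of the implied surfaces ---------------------------------
    def _check_thickness(self):
        min_thick = (self.base_thickness_um - self.pit_depth_um
                     - self.atrophy_severity * MAX_ATROPHY_FRACTION
                     * self.base_thickness_um)
        if min_thick < 0:
            raise ValueError(
                "thickness parameters force ILM below RPE: baseline "
                f"{self.base_thickness_um} um cannot absorb pit depth "
                f"{self.pit_depth_um} um plus atrophy thinning"
            )
        max_thick_px = self.base_thickness_um / self.axial_res_um
        top = self.rpe_depth_frac * self.height_px - max_thick_px \
            - self.undulation_amp_px
        if top < 0:
            raise ValueError("ILM would leave the top of the image")
        if self.rpe_depth_frac * self.height_px + self.undulation_amp_px \
                > self.height_px - 1:
            raise ValueError("RPE would leave the bottom of the image")

    def max_boundary_slope(self) -> float:
        """Conservative analytic bound on |d row / d column| of either surface."""
        s_und = (2 * np.pi * self.undulation_cycles * self.undulation_amp_px
                 / self.width_px)
        px = self.axial_res_um  # um per row
        s_pit = (self.pit_depth_um / px) * PIT_SLOPE_FACTOR \
            / max(self.pit_sigma_um / self.lateral_res_um, 1e-9)
        s_atr = (self.atrophy_severity * MAX_ATROPHY_FRACTION
                 * self.base_thickness_um / px) * PIT_SLOPE_FACTOR \
            / max(self.atrophy_sigma_um / self.lateral_res_um, 1e-9)
        return s_und + s_pit + s_atr

    def _check_slope(self):
        s = self.max_boundary_slope()
        if s > 1.0:
            raise ValueError(
                f"configured surfaces may exceed 1 px/column slope ({s:.2f}); "
                "the boundary graph only permits +-1 row per column step"
            )

    # -- en-face coordinate helpers ---------------------------------------
    def column_x_mm(self) -> np.ndarray:
        c = np.arange(self.width_px)
        return (c - (self.width_px - 1) / 2.0) * self.lateral_res_um / 1000.0

    def slice_y_mm(self) -> np.ndarray:
        s = np.arange(self.n_slices)
        return (s - (self.n_slices - 1) / 2.0) * self.scan_spacing_um / 1000.0

    @classmethod
    def paper_scale(cls, **overrides) -> "PhantomConfig":
        """Full clinical geometry: 1536 x 496 px, 61 slices, 5.7/3.9/119 um."""
        kw = dict(height_px=496, width_px=1536, n_slices=61,
                  lateral_res_um=5.7, axial_res_um=3.9, scan_spacing_um=119.0,
                  pit_sigma_um=600.0)
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class VolumeRecord:
    """One OCT volume: parallel lists of B-scans and their ground truths."""

    participant_id: str
    visit: int
    bscans: list = field(default_factory=list)
    boundaries: list = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return len(self.bscans)


@dataclass
class Participant:
    participant_id: str
    group: str = ""  # "low" | "high" macular volume
    atrophy_severity: float = 0.0
    baseline_volume_mm3: float = 0.0
    volumes: list = field(default_factory=list)


@dataclass
class CohortManifest:
    participants: list
    config: PhantomConfig
    seed: int = 0

    def __post_init__(self):
        for p in self.participants:
            if not p.volumes:
                raise ValueError(f"participant {p.participant_id} has no volumes")

    def participant_ids(self):
        return [p.participant_id for p in self.participants]

    def by_id(self, pid):
        for p in self.participants:
            if p.participant_id == pid:
                return p
        raise KeyError(pid)

    def groups(self):
        return {p.participant_id: p.group for p in self.participants}


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

@dataclass
class Surfaces:
    """Ground-truth boundary surfaces of one volume (rows; slices x columns)."""

    ilm: np.ndarray        # (n_slices, W) fractional rows
    rpe: np.ndarray        # (n_slices, W)
    atrophy_frac: np.ndarray  # (n_slices, W) local RPE-loss fraction in [0, 1]

    @property
    def thickness_px(self) -> np.ndarray:
        return self.rpe - self.ilm


def generate_boundary_surfaces(config: PhantomConfig, rng_seed: int) -> Surfaces:
    """Smooth per-volume ILM and RPE surfaces with a central foveal pit.

    Deterministic for a fixed seed.  The RPE follows low-frequency cosine
    undulation; the ILM lies above it by the local retinal thickness
    (baseline minus the en-face Gaussian pit minus atrophy thinning).
    """
    rng = np.random.default_rng(rng_seed)
    H, W, S = config.height_px, config.width_px, config.n_slices
    x_mm = config.column_x_mm()[None, :]      # (1, W)
    y_mm = config.slice_y_mm()[:, None]       # (S, 1)

    # RPE: baseline depth + up to two cosine undulation components
    rpe = np.full((S, W), config.rpe_depth_frac * H, dtype=np.float64)
    if config.undulation_amp_px > 0:
        amps = config.undulation_amp_px * np.array([0.7, 0.3])
        cycles = config.undulation_cycles * np.array([1.0, 0.5])
        for a, f in zip(amps, cycles):
            phase = rng.uniform(0, 2 * np.pi)
            sphase = rng.uniform(0, 2 * np.pi, size=(S, 1))
            rpe += a * np.cos(2 * np.pi * f * np.arange(W) / W + phase
                              + 0.2 * np.sin(sphase))

    # thickness field (um) in the en-face plane
    r2 = x_mm ** 2 + y_mm ** 2
    sigma_mm = config.pit_sigma_um / 1000.0
    thickness_um = config.base_thickness_um \
        - config.pit_depth_um * np.exp(-r2 / (2 * sigma_mm ** 2))

    atrophy_frac = np.zeros((S, W))
    if config.atrophy_lesions > 0 and config.atrophy_severity > 0:
        sig_l = config.atrophy_sigma_um / 1000.0
        for _ in range(config.atrophy_lesions):
            cx = rng.uniform(-1.5, 1.5)
            cy = rng.uniform(-1.0, 1.0)
            d2 = (x_mm - cx) ** 2 + (y_mm - cy) ** 2
            atrophy_frac += config.atrophy_severity * np.exp(-d2 / (2 * sig_l ** 2))
        np.clip(atrophy_frac, 0.0, 1.0, out=atrophy_frac)
        thickness_um = thickness_um - atrophy_frac * MAX_ATROPHY_FRACTION \
            * config.base_thickness_um

    if np.any(thickness_um < 0):
        raise ValueError("thickness parameters force ILM below RPE")

    ilm = rpe - thickness_um / config.axial_res_um
    if np.any(ilm < 0) or np.any(rpe > H - 1):
        raise ValueError("surfaces leave the image bounds")
    return Surfaces(ilm=ilm, rpe=rpe, atrophy_frac=atrophy_frac)


def ground_truth_boundaries(surfaces: Surfaces, scan_index: int) -> BoundarySet:
    return BoundarySet(surfaces.ilm[scan_index].copy(),
                       surfaces.rpe[scan_index].copy())


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_bscan(surfaces: Surfaces, config: PhantomConfig, rng_seed: int,
                 scan_index: int = 0, participant_id: str = "",
                 eye: str = "OD", visit: int = 0) -> BScan:
    """Render one slice of the phantom volume to an 8-bit B-scan.

    Piecewise-constant mean intensity per region (dark vitreous, brighter
    retina, bright RPE band, decaying choroid, dark sclera), with the RPE
    band suppressed and the sub-RPE signal brightened inside atrophy
    lesions (hypertransmission), plus additive hyperreflective flecks,
    multiplicative Gamma speckle and columnar vessel shadows.
    """
    rng = np.random.default_rng(rng_seed)
    H, W = config.height_px, config.width_px
    ilm = surfaces.ilm[scan_index]
    rpe = surfaces.rpe[scan_index]
    atro = surfaces.atrophy_frac[scan_index]

    rows = np.arange(H)[:, None]
    ilm_r = np.floor(ilm)[None, :]
    rpe_r = np.floor(rpe)[None, :]
    band_px = config.rpe_band_um / config.axial_res_um
    band_r = np.floor(rpe - band_px)[None, :]
    chor_px = config.choroid_band_um / config.axial_res_um
    chor_r = np.floor(rpe + chor_px)[None, :]

    # RPE band intensity drops toward retina level with local atrophy;
    # sub-RPE signal brightens (hypertransmission)
    i_band = (config.intensity_rpe
              - atro * (config.intensity_rpe - config.intensity_retina))[None, :]
    i_chor0 = np.clip(config.intensity_choroid
                      + atro * config.hypertransmission_boost, 0, 255)[None, :]

    img = np.full((H, W), config.intensity_vitreous, dtype=np.float64)
    retina = (rows >= ilm_r) & (rows < band_r)
    band = (rows >= band_r) & (rows < rpe_r)
    chor = (rows >= rpe_r) & (rows < chor_r)
    scler = rows >= chor_r
    img[retina] = config.intensity_retina
    img[band] = np.broadcast_to(i_band, (H, W))[band]
    # linear decay from (possibly hypertransmissive) choroid level to sclera
    frac = np.clip((rows - rpe_r) / max(chor_px, 1e-9), 0.0, 1.0)
    chor_img = i_chor0 + (config.intensity_sclera - i_chor0) * frac
    img[chor] = chor_img[chor]
    img[scler] = config.intensity_sclera

    # hyperreflective flecks: Gaussian blobs in the outer half of the retina
    for _ in range(config.fleck_count):
        c = rng.uniform(0, W)
        lo = ilm[int(np.clip(c, 0, W - 1))]
        hi = rpe[int(np.clip(c, 0, W - 1))] - band_px
        if hi <= lo:
            continue
        r = rng.uniform((lo + hi) / 2.0, hi)
        rad = max(config.fleck_radius_px, 0.5)
        dr2 = (rows - r) ** 2 + (np.arange(W)[None, :] - c) ** 2
        img += config.fleck_brightness * np.exp(-dr2 / (2 * rad ** 2))

    # multiplicative speckle: Gamma with mean 1, relative std = speckle_scale
    if config.speckle_scale > 0:
        shape = 1.0 / config.speckle_scale ** 2
        img *= rng.gamma(shape, 1.0 / shape, size=(H, W))

    # columnar vessel shadows below the inner retina
    if config.shadow_count > 0 and config.shadow_attenuation > 0:
        centers = rng.uniform(0, W, size=config.shadow_count)
        profile = np.zeros(W)
        for c in centers:
            profile += np.exp(-(np.arange(W) - c) ** 2
                              / (2 * config.shadow_sigma_px ** 2))
        profile = np.clip(profile, 0.0, 1.0) * config.shadow_attenuation
        depth_mask = rows >= (ilm_r + 2)
        img = np.where(depth_mask, img * (1.0 - profile[None, :]), img)

    np.clip(img, 0, 255, out=img)
    return BScan(np.round(img).astype(np.uint8),
                 lateral_res_um=config.lateral_res_um,
                 axial_res_um=config.axial_res_um,
                 scan_spacing_um=config.scan_spacing_um,
                 participant_id=participant_id, eye=eye, visit=visit,
                 scan_index=scan_index)


def render_volume(surfaces: Surfaces, config: PhantomConfig, rng_seed: int,
                  participant_id: str = "", eye: str = "OD",
                  visit: int = 0) -> VolumeRecord:
    vol = VolumeRecord(participant_id=participant_id, visit=visit)
    for s in range(surfaces.ilm.shape[0]):
        vol.bscans.append(render_bscan(surfaces, config, rng_seed + 7919 * s,
                                       scan_index=s,
                                       participant_id=participant_id,
                                       eye=eye, visit=visit))
        vol.boundaries.append(ground_truth_boundaries(surfaces, s))
    return vol


# ---------------------------------------------------------------------------
# ground-truth macular volume & cohorts
# ---------------------------------------------------------------------------

def gt_macular_volume_mm3(surfaces: Surfaces, config: PhantomConfig,
                          radius_mm: float = 3.0) -> float:
    """Macular volume over the central disc from the ground-truth surfaces.

    Sums thickness x cell area over en-face cells whose centre lies
    within ``radius_mm`` of the volume centre.
    """
    x = config.column_x_mm()[None, :]
    y = config.slice_y_mm()[:, None]
    inside = x ** 2 + y ** 2 <= radius_mm ** 2
    thick_mm = surfaces.thickness_px * config.axial_res_um / 1000.0
    cell_mm2 = (config.lateral_res_um / 1000.0) * (config.scan_spacing_um / 1000.0)
    return float(np.sum(thick_mm[inside]) * cell_mm2)


def generate_cohort(n_participants: int, volumes_each: int,
                    scans_per_volume: int, config: PhantomConfig,
                    rng_seed: int) -> CohortManifest:
    """Seeded multi-participant cohort with low/high macular-volume groups.

    Half the participants receive mild atrophy severity draws (thick
    retina, high volume) and half severe draws (thin retina, low volume),
    so baseline volumes straddle the cohort median.  Group labels are
    then assigned by the median split of the measured baseline ground
    truth volumes, with deterministic tie-breaking on participant id.
    """
    if n_participants % 2:
        raise ValueError("n_participants must be even to balance the groups")
    if volumes_each < 1:
        raise ValueError("each participant needs at least one volume")
    if scans_per_volume < 3:
        raise ValueError("scans_per_volume must be >= 3 (ETDRS grid coverage)")
    rng = np.random.default_rng(rng_seed)
    config = config.replace(n_slices=scans_per_volume)

    participants = []
    for i in range(n_participants):
        pid = f"P{i:03d}"
        severe = i >= n_participants // 2
        sev = rng.uniform(0.55, 0.9) if severe else rng.uniform(0.0, 0.2)
        thick = config.base_thickness_um + rng.uniform(-15.0, 15.0)
        pcfg = config.replace(atrophy_severity=float(sev),
                              base_thickness_um=float(thick),
                              atrophy_lesions=max(config.atrophy_lesions, 1))
        p = Participant(participant_id=pid, atrophy_severity=float(sev))
        for v in range(volumes_each):
            vseed = int(rng.integers(0, 2 ** 31 - 1))
            surf = generate_boundary_surfaces(pcfg, vseed)
            vol = render_volume(surf, pcfg, vseed + 1, participant_id=pid,
                                visit=v)
            p.volumes.append(vol)
            if v == 0:
                p.baseline_volume_mm3 = gt_macular_volume_mm3(surf, pcfg)
        participants.append(p)

    # median split on baseline volume; ties broken by participant id order
    order = sorted(participants, key=lambda p: (p.baseline_volume_mm3,
                                                p.participant_id))
    for rank, p in enumerate(order):
        p.group = "low" if rank < n_participants // 2 else "high"
    return CohortManifest(participants=participants, config=config,
                          seed=rng_seed)
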