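"""Synthetic DBS-PET cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline is
built to detect, on a desk-scale 4 mm grid:

* a smooth template "tremor treatment network" with positive hubs in
  motor-cortical and cerebellar territory and negative frontal/occipital
  regions;
* per-patient Stim-Off uptake = smooth baseline + severity-coupled
  template expression + smooth spatial noise;
* per-patient Stim-On uptake = Stim-Off + an amplitude-driven local
  component centered on the stimulation site + a network-aligned
  component scaled by a patient gain g_i + smooth noise;
* tremor severity and relative improvement linearly coupled to the
  planted quantities with additive Gaussian noise;
* spherical VTA masks whose radius grows with stimulation amplitude, and
  connectivity maps equal to the template plus smooth patient noise.

Every random quantity is drawn from a named per-patient substream of the
master seed (``numpy.random.SeedSequence(seed).spawn``), so cohorts are
bitwise reproducible and individual patients can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError
from .volumes import BrainMap, VolumeGrid, gaussian_smooth, read_volume, write_mask, write_volume

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class Patient:
    """One synthetic patient: paired maps, clinical scores, stimulation."""

    id: str
    off_map: BrainMap
    on_map: BrainMap
    trs_off: float
    trs_on: float
    amplitude: float        # mA, mean of both hemispheres
    pulse_width: float      # microseconds
    frequency: float        # Hz
    vta_mask: np.ndarray
    conn_map: BrainMap


@dataclass
class Cohort:
    patients: list[Patient]
    template_grid: VolumeGrid
    analysis_mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.patients)

    def clinical_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.patients],
                "trs_off": [p.trs_off for p in self.patients],
                "trs_on": [p.trs_on for p in self.patients],
                "amplitude_mA": [p.amplitude for p in self.patients],
                "pulse_width_us": [p.pulse_width for p in self.patients],
                "frequency_Hz": [p.frequency for p in self.patients],
            }
        )


@dataclass
class GroundTruth:
    """Everything needed to check that the pipeline recovers the plant."""

    template_network: BrainMap
    local_kernel: BrainMap
    network_gain: np.ndarray         # g_i
    severity: np.ndarray             # s_i
    amplitude: np.ndarray            # a_i (mA)
    improvement_true: np.ndarray     # planted relative improvement (%)
    noise_fwhm_mm: float
    noise_sd: float
    clinical_coefficients: dict
    config: "CohortConfig"
    seed: int
    seeding_rule: str = "SeedSequence(seed).spawn(n_patients + 1); child 0 = cohort level"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self.config), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# Hub layout: (center_mm, radius_mm, sign, weight). Positive motor-cortical
# and cerebellar hubs, negative frontal and occipital regions, mirroring the
# sign structure of the published tremor treatment network.
DEFAULT_HUBS: tuple = (
    ((-26.0, -14.0, 28.0), 10.0, +1, 1.0),   # left motor cortex
    ((26.0, -14.0, 28.0), 10.0, +1, 1.0),    # right motor cortex
    ((-14.0, -36.0, -24.0), 9.0, +1, 1.0),   # left cerebellum
    ((14.0, -36.0, -24.0), 9.0, +1, 1.0),    # right cerebellum
    ((-18.0, 32.0, 16.0), 9.0, -1, 1.0),     # left frontal
    ((18.0, 32.0, 16.0), 9.0, -1, 1.0),      # right frontal
    ((-12.0, -44.0, 2.0), 8.0, -1, 1.0),     # left occipital
    ((12.0, -44.0, 2.0), 8.0, -1, 1.0),      # right occipital
)

#: Bilateral stimulation loci (ventral intermediate thalamus territory).
DEFAULT_STIM_CENTERS: tuple = ((-12.0, -6.0, 2.0), (12.0, -6.0, 2.0))


@dataclass
class CohortConfig:
    """Generator settings; the defaults define the study conditions."""

    n_patients: int = 14
    shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 4.0
    hubs: tuple = DEFAULT_HUBS
    hub_smooth_fwhm_mm: float = 8.0
    template_support_rel_threshold: float = 0.01
    stim_centers_mm: tuple = DEFAULT_STIM_CENTERS
    local_fwhm_mm: float = 6.0
    # map model
    baseline_level: float = 1.0          # intensity-normalized uptake scale
    baseline_sd: float = 0.10
    noise_fwhm_mm: float = 8.0
    noise_sd: float = 0.05               # spatial noise per condition map
    c_local: float = 0.02                # uptake change per mA at the VTA
    c_template: float = 0.05             # uptake change per unit gain
    gain_mean: float = 1.0               # g_i ~ N(gain_mean, gain_sd)
    gain_sd: float = 1.0
    severity_mean: float = 0.05          # s_i scales template in Stim-Off
    severity_sd: float = 0.02
    # stimulation parameters
    amplitude_range: tuple[float, float] = (1.5, 4.5)     # mA
    pulse_width_range: tuple[float, float] = (40.0, 60.0)  # us
    frequency_range: tuple[float, float] = (130.0, 180.0)  # Hz
    vta_radius_base_mm: float = 3.0
    vta_radius_per_ma_mm: float = 1.0
    conn_noise_sd: float = 0.10
    # clinical model
    alpha0: float = 8.0                  # trs_off = alpha0 + alpha1 s_i + eta
    alpha1: float = 130.0
    trs_noise_sd: float = 1.5
    beta0: float = 50.0                  # improvement = beta0 + beta1 g_i + eta'
    beta1: float = 15.0
    improvement_noise_sd: float = 12.0
    round_scores: bool = False

    def grid(self) -> VolumeGrid:
        return VolumeGrid.centered(self.shape, self.voxel_size_mm)

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ConfigError("need at least 3 patients")
        if self.noise_sd < 0 or self.trs_noise_sd < 0 or self.improvement_noise_sd < 0:
            raise ConfigError("noise standard deviations must be nonnegative")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def default_analysis_mask(grid: VolumeGrid) -> np.ndarray:
    """Brain-shaped ellipsoid inscribed in the grid's world extent."""
    coords = grid.world_coords().reshape(*grid.shape, 3)
    semi = np.array(
        [grid.shape[a] / 2.0 * grid.voxel_size_mm[a] for a in range(3)]
    )
    r2 = ((coords / semi) ** 2).sum(axis=-1)
    return r2 <= 1.0


def make_template_network(
    grid: VolumeGrid,
    hubs=DEFAULT_HUBS,
    smooth_fwhm_mm: float = 8.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    support_rel_threshold: float = 0.01,
) -> BrainMap:
    """Signed spherical hubs, Gaussian-smoothed, on the analysis mask.

    Deterministic given its arguments (``seed`` is accepted for interface
    symmetry; no randomness is involved). After smoothing, voxels with
    |value| below ``support_rel_threshold * max|value|`` are zeroed so the
    template keeps a genuine nonzero support around its hubs.
    """
    del seed
    if mask is None:
        mask = default_analysis_mask(grid)
    coords = grid.world_coords().reshape(*grid.shape, 3)
    lo = coords.reshape(-1, 3).min(axis=0)
    hi = coords.reshape(-1, 3).max(axis=0)
    data = np.zeros(grid.shape)
    for center, radius, sign, weight in hubs:
        center = np.asarray(center, dtype=float)
        if np.any(center < lo) or np.any(center > hi):
            raise PlacementError(f"hub center {tuple(center)} lies outside the grid")
        d2 = ((coords - center) ** 2).sum(axis=-1)
        data += float(sign) * float(weight) * (d2 <= radius**2)
    bmap = BrainMap(grid, data, mask)
    if smooth_fwhm_mm > 0:
        bmap = gaussian_smooth(bmap, smooth_fwhm_mm)
        peak = np.max(np.abs(bmap.values))
        if peak > 0 and support_rel_threshold > 0:
            d = bmap.data.copy()
            d[np.abs(d) < support_rel_threshold * peak] = 0.0
            bmap = BrainMap(grid, d, bmap.mask)
    return bmap


def make_local_kernel(
    grid: VolumeGrid,
    centers_mm=DEFAULT_STIM_CENTERS,
    fwhm_mm: float = 6.0,
    mask: np.ndarray | None = None,
) -> BrainMap:
    """Unit-peak Gaussian blobs at the stimulation loci (local effect)."""
    if mask is None:
        mask = default_analysis_mask(grid)
    coords = grid.world_coords().reshape(*grid.shape, 3)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    data = np.zeros(grid.shape)
    for center in centers_mm:
        d2 = ((coords - np.asarray(center)) ** 2).sum(axis=-1)
        data += np.exp(-d2 / (2.0 * sigma**2))
    data[data < 1e-6] = 0.0
    return BrainMap(grid, data, mask)


def smooth_noise_field(
    grid: VolumeGrid,
    mask: np.ndarray,
    fwhm_mm: float,
    sd: float,
    rng: np.random.Generator,
) -> BrainMap:
    """Gaussian random field smoothed to ``fwhm_mm``, rescaled so the
    in-mask standard deviation equals ``sd`` (zero-mean over the mask)."""
    white = rng.standard_normal(grid.shape)
    if sd == 0:
        return BrainMap(grid, np.zeros(grid.shape), mask)
    bmap = gaussian_smooth(BrainMap(grid, white, mask), fwhm_mm)
    v = bmap.values
    v = v - v.mean()
    s = v.std()
    if s == 0:
        raise ConfigError("degenerate noise field")
    return bmap.with_values(v * (sd / s))


def sphere_mask(grid: VolumeGrid, center_mm, radius_mm: float) -> np.ndarray:
    coords = grid.world_coords().reshape(*grid.shape, 3)
    return ((coords - np.asarray(center_mm)) ** 2).sum(axis=-1) <= radius_mm**2


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> tuple[Cohort, GroundTruth]:
    """Simulate a cohort and its ground truth.

    Per patient i (all noise fields smoothed to ``noise_fwhm_mm``):

    * ``off_i = baseline + s_i * T + eps_off``
    * ``on_i  = off_i + a_i * c_local * L + g_i * c_template * T + eps_on``
    * ``trs_off_i = alpha0 + alpha1 * s_i + eta``
    * ``improvement_i = beta0 + beta1 * g_i + eta'`` (percent)
    * ``trs_on_i = trs_off_i * (1 - improvement_i / 100)`` clipped at 0

    With all noise SDs set to 0 every downstream stage recovers its
    planted quantity exactly; this is used heavily by the test suite.
    """
    config = config or CohortConfig()
    config.validate()
    grid = config.grid()
    mask = default_analysis_mask(grid)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_patients + 1)
    rng_cohort = np.random.default_rng(children[0])

    template = make_template_network(
        grid, config.hubs, config.hub_smooth_fwhm_mm, mask=mask,
        support_rel_threshold=config.template_support_rel_threshold,
    )
    local = make_local_kernel(grid, config.stim_centers_mm, config.local_fwhm_mm, mask=mask)
    baseline = smooth_noise_field(grid, mask, config.noise_fwhm_mm, config.baseline_sd, rng_cohort)
    baseline = baseline.with_values(baseline.values + config.baseline_level)

    patients = []
    g_all = np.empty(config.n_patients)
    s_all = np.empty(config.n_patients)
    a_all = np.empty(config.n_patients)
    imp_all = np.empty(config.n_patients)

    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i + 1])
        g_i = rng.normal(config.gain_mean, config.gain_sd)
        s_i = rng.normal(config.severity_mean, config.severity_sd)
        a_i = rng.uniform(*config.amplitude_range)
        pw_i = rng.uniform(*config.pulse_width_range)
        fr_i = rng.uniform(*config.frequency_range)

        eps_off = smooth_noise_field(grid, mask, config.noise_fwhm_mm, config.noise_sd, rng)
        eps_on = smooth_noise_field(grid, mask, config.noise_fwhm_mm, config.noise_sd, rng)
        off = baseline.with_values(
            baseline.values + s_i * template.values + eps_off.values
        )
        on = off.with_values(
            off.values
            + a_i * config.c_local * local.values
            + g_i * config.c_template * template.values
            + eps_on.values
        )

        trs_off = config.alpha0 + config.alpha1 * s_i + rng.normal(0.0, config.trs_noise_sd)
        trs_off = max(trs_off, 0.0)
        improvement = config.beta0 + config.beta1 * g_i + rng.normal(
            0.0, config.improvement_noise_sd
        )
        trs_on = max(trs_off * (1.0 - improvement / 100.0), 0.0)
        if config.round_scores:
            trs_off, trs_on = round(trs_off), round(trs_on)

        radius = config.vta_radius_base_mm + config.vta_radius_per_ma_mm * a_i
        vta = np.zeros(grid.shape, dtype=bool)
        for center in config.stim_centers_mm:
            vta |= sphere_mask(grid, center, radius)
        vta &= mask

        conn_noise = smooth_noise_field(grid, mask, config.noise_fwhm_mm, config.conn_noise_sd, rng)
        conn = template.with_values(template.values + conn_noise.values)

        patients.append(
            Patient(
                id=f"sub-{i + 1:02d}",
                off_map=off, on_map=on,
                trs_off=float(trs_off), trs_on=float(trs_on),
                amplitude=float(a_i), pulse_width=float(pw_i), frequency=float(fr_i),
                vta_mask=vta, conn_map=conn,
            )
        )
        g_all[i], s_all[i], a_all[i], imp_all[i] = g_i, s_i, a_i, improvement

    cohort = Cohort(patients=patients, template_grid=grid, analysis_mask=mask)
    truth = GroundTruth(
        template_network=template,
        local_kernel=local,
        network_gain=g_all,
        severity=s_all,
        amplitude=a_all,
        improvement_true=imp_all,
        noise_fwhm_mm=config.noise_fwhm_mm,
        noise_sd=config.noise_sd,
        clinical_coefficients={
            "alpha0": config.alpha0, "alpha1": config.alpha1,
            "trs_noise_sd": config.trs_noise_sd,
            "beta0": config.beta0, "beta1": config.beta1,
            "improvement_noise_sd": config.improvement_noise_sd,
        },
        config=config,
        seed=seed,
    )
    return cohort, truth


def simulate_connectivity_effect(
    grid: VolumeGrid | None = None,
    mask: np.ndarray | None = None,
    n_patients: int = 14,
    effect_size: float = 2.0,
    effect_center_mm=(-16.0, -10.0, 14.0),
    effect_radius_mm: float = 10.0,
    conn_noise_sd: float = 0.1,
    noise_sd: float = 0.05,
    noise_fwhm_mm: float = 8.0,
    hubs=None,
    seed: int = 0,
) -> tuple[list[BrainMap], list[BrainMap], np.ndarray, np.ndarray]:
    """Cohort of change maps with a compact planted connectivity effect.

    Per patient, ``conn_i = template + smooth noise`` and
    ``delta_i = effect_size * pos(conn_i) * sphere(center, radius) + smooth
    noise``: the positive-connectivity predictor truly drives metabolic
    change inside one compact region and nowhere else. ``effect_size = 0``
    gives the matching null. Returns ``(delta_maps, conn_maps, amplitude,
    effect_region_mask)``.
    """
    if grid is None:
        grid = VolumeGrid.centered((16, 18, 16), 4.0)
    if mask is None:
        mask = default_analysis_mask(grid)
    if hubs is None:
        hubs = (
            ((-16.0, -10.0, 14.0), 8.0, +1, 1.0),
            ((16.0, -10.0, 14.0), 8.0, +1, 1.0),
            ((-10.0, -22.0, -14.0), 7.0, -1, 1.0),
            ((10.0, -22.0, -14.0), 7.0, -1, 1.0),
        )
    template = make_template_network(grid, hubs, mask=mask)
    region = sphere_mask(grid, effect_center_mm, effect_radius_mm) & mask
    rng = np.random.default_rng(seed)
    deltas, conns = [], []
    for _ in range(n_patients):
        conn_noise = smooth_noise_field(grid, mask, noise_fwhm_mm, conn_noise_sd, rng)
        conn = template.with_values(template.values + conn_noise.values)
        pos = np.where(conn.data > 0, conn.data, 0.0)
        noise = smooth_noise_field(grid, mask, noise_fwhm_mm, noise_sd, rng)
        delta = effect_size * pos * region + noise.data
        deltas.append(BrainMap(grid, np.where(mask, delta, 0.0), mask))
        conns.append(conn)
    amplitude = rng.uniform(1.5, 4.5, size=n_patients)
    return deltas, conns, amplitude, region


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, truth: GroundTruth, directory) -> None:
    """Write NIfTI maps, the clinical TSV, and the ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mask(cohort.analysis_mask, cohort.template_grid, directory / "analysis_mask.nii.gz")
    write_volume(truth.template_network, directory / "template_network.nii.gz")
    write_volume(truth.local_kernel, directory / "local_kernel.nii.gz")
    for p in cohort.patients:
        write_volume(p.off_map, directory / f"{p.id}_off.nii.gz")
        write_volume(p.on_map, directory / f"{p.id}_on.nii.gz")
        write_volume(p.conn_map, directory / f"{p.id}_conn.nii.gz")
        write_mask(p.vta_mask, cohort.template_grid, directory / f"{p.id}_vta.nii.gz")
    cohort.clinical_table().to_csv(directory / "clinical.tsv", sep="\t", index=False)
    record = {
        "seed": truth.seed,
        "seeding_rule": truth.seeding_rule,
        "config": dataclasses.asdict(truth.config),
        "config_hash": truth.config_hash(),
        "network_gain": truth.network_gain.tolist(),
        "severity": truth.severity.tolist(),
        "amplitude": truth.amplitude.tolist(),
        "improvement_true": truth.improvement_true.tolist(),
        "clinical_coefficients": truth.clinical_coefficients,
        "noise_fwhm_mm": truth.noise_fwhm_mm,
        "noise_sd": truth.noise_sd,
    }
    (directory / "ground_truth.json").write_text(json.dumps(record, indent=2, default=list))


def read_cohort(directory) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    clin = pd.read_csv(directory / "clinical.tsv", sep="\t")
    mask_map = read_volume(directory / "analysis_mask.nii.gz", mask=None)
    mask = mask_map.data > 0.5
    grid = mask_map.grid
    patients = []
    for _, row in clin.iterrows():
        pid = row["id"]
        off = read_volume(directory / f"{pid}_off.nii.gz", mask=mask)
        on = read_volume(directory / f"{pid}_on.nii.gz", mask=mask)
        conn = read_volume(directory / f"{pid}_conn.nii.gz", mask=mask)
        vta = read_volume(directory / f"{pid}_vta.nii.gz", mask=None).data > 0.5
        patients.append(
            Patient(
                id=pid, off_map=off, on_map=on,
                trs_off=float(row["trs_off"]), trs_on=float(row["trs_on"]),
                amplitude=float(row["amplitude_mA"]),
                pulse_width=float(row["pulse_width_us"]),
                frequency=float(row["frequency_Hz"]),
                vta_mask=vta, conn_map=conn,
            )
        )
    if not patients:
        raise ConfigError("cohort directory contains no patients")
    return Cohort(patients=patients, template_grid=grid, analysis_mask=mask)
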