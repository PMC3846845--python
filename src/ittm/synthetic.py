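"""Study-like synthetic datasets with known ground truth.

Emulates the measurement structure of the imaging study: a one-
compartment exponentially decaying plasma curve sampled at the imaging
schedule, a tumor curve generated by the forward transport model plus a
vascular compartment f_v * C_blood, conversion to CT enhancement via
the species calibration factor, and multiplicative log-normal
measurement noise.  Each preset carries its generating truth so every
pipeline stage can be tested end-to-end without external data.

The three presets mirror the study's tumor models:

* ``ME180-like`` — orthotopic cervix xenograft in mice: plasma peak
  11.2 mgI cm^-3, half-life 38 h, R = 0.41 cm, imaging at pre, 5 min,
  1, 8, 24, 48, 72, 96, 120 and 144 h; transport truth alpha = 3 with
  MVP 6.71 mmHg (central IFP 4.70 mmHg).
* ``H520-like`` — small subcutaneous lung xenograft: 8.0 mgI cm^-3,
  35 h, R = 0.12 cm; same schedule minus the 1 h and 120 h scans;
  truth alpha = 2 with MVP 6.46 mmHg (central IFP 2.90 mmHg).
* ``VX2-like`` — large intramuscular rabbit tumor: 5.1 mgI cm^-3,
  64 h, R = 1.1 cm, imaging to 336 h, rabbit calibration 38.0 HU per
  mgI cm^-3; truth alpha = 8 with MVP 20 mmHg (central IFP 19.9 mmHg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import PlasmaDecayModel
from .imaging import CALIBRATION_MOUSE, CALIBRATION_RABBIT, DEFAULT_HEMATOCRIT, ImagingSeries
from .params import TransportParameters
from .pressure import central_ifp_fraction
from .transport import simulate_radial_transport, volume_average

__all__ = [
    "ScenarioPreset",
    "me180_like",
    "h520_like",
    "vx2_like",
    "default_presets",
    "generate_series",
    "write_fixture_bundle",
]

#: Imaging schedules, hours post-injection (the pre scan is implicit).
SCHEDULE_ME180 = (1.0 / 12.0, 1.0, 8.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0)
SCHEDULE_H520 = (1.0 / 12.0, 8.0, 24.0, 48.0, 72.0, 96.0, 144.0)
SCHEDULE_VX2 = (0.5, 24.0, 48.0, 72.0, 120.0, 168.0, 240.0, 336.0)


@dataclass(frozen=True)
class ScenarioPreset:
    """Everything needed to simulate one study-like imaging series."""

    name: str
    schedule_hr: tuple               # post-injection sample times, hours
    c0: float                        # peak plasma concentration, mgI cm^-3
    t_half_hr: float                 # plasma half-life, hours
    params: TransportParameters      # generating transport truth
    f_v: float                       # plasma volume fraction
    calibration: float               # HU per mgI cm^-3
    hematocrit: float = DEFAULT_HEMATOCRIT
    noise_sd: float = 0.05           # multiplicative log-normal SD
    seed: int = 0
    baseline_tumor_hu: float = 35.0
    baseline_blood_hu: float = 55.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.f_v < 1.0:
            raise ValueError("f_v must be in [0, 1)")
        if any(t <= 0 for t in self.schedule_hr) or any(
            b <= a for a, b in zip(self.schedule_hr, self.schedule_hr[1:])
        ):
            raise ValueError("schedule_hr must be positive and strictly increasing")

    @property
    def plasma(self) -> PlasmaDecayModel:
        return PlasmaDecayModel(c0=self.c0, t_half=self.t_half_hr)

    def replace(self, **changes) -> "ScenarioPreset":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "schedule_hr": list(self.schedule_hr),
            "c0_mgI_per_cm3": self.c0,
            "t_half_hr": self.t_half_hr,
            "params": self.params.to_dict(),
            "f_v": self.f_v,
            "calibration_hu_per_mgi_cm3": self.calibration,
            "hematocrit": self.hematocrit,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "baseline_tumor_hu": self.baseline_tumor_hu,
            "baseline_blood_hu": self.baseline_blood_hu,
        }


def _params_for_alpha(alpha: float, radius: float, k_int: float, p_v: float):
    """Transport truth with cfc chosen so R*sqrt(cfc/k_int) = alpha exactly."""
    return TransportParameters(
        cfc=k_int * (alpha / radius) ** 2,
        k_int=k_int,
        p_v=p_v,
        radius=radius,
        sigma=0.9,
        r_f=1.0,
    )


def me180_like(seed: int = 0, noise_sd: float = 0.05) -> ScenarioPreset:
    """Orthotopic cervix-tumor scenario (mouse)."""
    return ScenarioPreset(
        name="ME180-like",
        schedule_hr=SCHEDULE_ME180,
        c0=11.2,
        t_half_hr=38.0,
        params=_params_for_alpha(3.0, radius=0.41, k_int=2.0e-7, p_v=6.71),
        f_v=0.05,
        calibration=CALIBRATION_MOUSE,
        noise_sd=noise_sd,
        seed=seed,
    )


def h520_like(seed: int = 0, noise_sd: float = 0.05) -> ScenarioPreset:
    """Small subcutaneous lung-tumor scenario (mouse)."""
    return ScenarioPreset(
        name="H520-like",
        schedule_hr=SCHEDULE_H520,
        c0=8.0,
        t_half_hr=35.0,
        params=_params_for_alpha(2.0, radius=0.12, k_int=2.16e-7, p_v=6.46),
        f_v=0.08,
        calibration=CALIBRATION_MOUSE,
        noise_sd=noise_sd,
        seed=seed,
    )


def vx2_like(seed: int = 0, noise_sd: float = 0.05) -> ScenarioPreset:
    """Large intramuscular rabbit-tumor scenario."""
    return ScenarioPreset(
        name="VX2-like",
        schedule_hr=SCHEDULE_VX2,
        c0=5.1,
        t_half_hr=64.0,
        params=_params_for_alpha(8.0, radius=1.1, k_int=3.0e-7, p_v=20.0),
        f_v=0.04,
        calibration=CALIBRATION_RABBIT,
        noise_sd=noise_sd,
        seed=seed,
    )


def default_presets(seed: int = 0, noise_sd: float = 0.05) -> tuple:
    """The three study-like scenarios with a shared seed."""
    return (
        me180_like(seed=seed, noise_sd=noise_sd),
        h520_like(seed=seed + 1, noise_sd=noise_sd),
        vx2_like(seed=seed + 2, noise_sd=noise_sd),
    )


def generate_series(
    preset: ScenarioPreset, n_nodes: int = 201
) -> tuple[ImagingSeries, dict]:
    """Simulate one imaging series and return it with its ground truth.

    The blood curve is the plasma model on a whole-blood basis
    (scaled by 1 - Hct); the tumor curve is the forward-model
    interstitial concentration plus f_v times the blood curve.  Both
    are converted to HU enhancement via the calibration factor, offset
    by the baseline HU, and perturbed with multiplicative log-normal
    noise (the pre-injection row stays at baseline).  Identical seeds
    give bit-identical series.
    """
    t_post = np.asarray(preset.schedule_hr, dtype=float)
    plasma = preset.plasma
    blood_conc = plasma(t_post) * (1.0 - preset.hematocrit)

    fld = simulate_radial_transport(
        preset.params, plasma, times_hr=t_post, n_nodes=n_nodes
    )
    ci = volume_average(fld).conc[1:]  # drop t=0
    tumor_conc = ci + preset.f_v * blood_conc

    tumor_enh = tumor_conc * preset.calibration
    blood_enh = blood_conc * preset.calibration
    rng = np.random.default_rng(preset.seed)
    if preset.noise_sd > 0:
        tumor_enh = tumor_enh * np.exp(rng.normal(0.0, preset.noise_sd, t_post.size))
        blood_enh = blood_enh * np.exp(rng.normal(0.0, preset.noise_sd, t_post.size))

    times = np.concatenate([[0.0], t_post])
    tumor_hu = np.concatenate(
        [[preset.baseline_tumor_hu], preset.baseline_tumor_hu + tumor_enh]
    )
    blood_hu = np.concatenate(
        [[preset.baseline_blood_hu], preset.baseline_blood_hu + blood_enh]
    )
    volume = np.full(times.size, 4.0 / 3.0 * np.pi * preset.params.radius**3 * 1e3)

    series = ImagingSeries(
        times=times,
        tumor=tumor_hu,
        blood=blood_hu,
        volume_mm3=volume,
        units="HU",
        calibration=preset.calibration,
        hematocrit=preset.hematocrit,
        species_label=preset.name,
    )
    truth = preset.to_dict()
    truth["alpha"] = preset.params.alpha
    truth["p_peak_mmHg"] = preset.params.p_v * central_ifp_fraction(preset.params.alpha)
    truth["solver_n_nodes"] = n_nodes
    truth["interstitial_conc_mgI_per_cm3"] = [float(v) for v in ci]
    return series, truth


def write_fixture_bundle(presets, directory) -> list[Path]:
    """Write one CSV per series plus a JSON ground-truth manifest.

    Filenames are stable (derived from preset names); re-running with
    the same seeds reproduces the files byte for byte.  Returns the
    paths written (CSVs first, manifest last).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    manifest = {}
    for preset in presets:
        series, truth = generate_series(preset)
        stem = preset.name.lower().replace(" ", "-")
        csv_path = directory / f"{stem}.csv"
        pd.DataFrame(
            {
                "time_hr": series.times,
                "tumor_hu": series.tumor,
                "aorta_hu": series.blood,
                "volume_mm3": series.volume_mm3,
            }
        ).to_csv(csv_path, index=False, float_format="%.12g")
        manifest[stem] = {"csv": csv_path.name, "truth": truth}
        paths.append(csv_path)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths.append(manifest_path)
    return paths
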