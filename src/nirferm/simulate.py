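"""Synthetic coffee-fermentation NIR datasets with planted ground truth.

The generator emulates the structure of a fermentation monitoring study:
three varieties sampled at seven fermentation times with two sub-samples per
time and fifty spectrometer profiles per sub-sample (3 x 7 x 2 x 50 = 2100
profiles), with per-sample pH and total soluble solids (TSS) references.

Chemistry follows normalised exponential decay from a variety-specific start
to an end value, pinned exactly at both endpoints and nearly flat after
16-20 h.  Spectra are built Beer-Lambert style in absorbance space — a
smooth baseline plus Gaussian absorption bands at the classic coffee NIR
assignments (1205, 1451, 1729, 1839, 1927 nm) — and converted to reflectance
R = 10^(-A), so the pipeline's absorbance conversion is exercised in its
intended direction.  A declared subset of bands has its amplitude coupled
linearly to pH or TSS, which plants a known set of informative wavelengths
for selection-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import ReferenceTable, SpectrumSet


class ScenarioError(ValueError):
    """Raised on non-physical scenario parameters."""


@dataclass(frozen=True)
class TrajectorySpec:
    """Exponential decay-to-plateau from start to end over the run."""

    start: float
    end: float
    rate: float  # 1/h; larger = earlier plateau

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ScenarioError("decay rate must be positive")

    def value(self, t: np.ndarray, t_final: float) -> np.ndarray:
        """Curve pinned exactly at start (t=0) and end (t=t_final).

        Normalised exponential decay; as rate -> infinity the curve becomes
        a step to the end value.
        """
        t = np.asarray(t, dtype=float)
        with np.errstate(over="ignore"):
            num = np.exp(-self.rate * t) - np.exp(-self.rate * t_final)
            den = 1.0 - np.exp(-self.rate * t_final)
        return self.end + (self.start - self.end) * num / den


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption band, optionally coupled to pH and/or TSS.

    Amplitude at a given sample is
    ``amplitude + ph_coupling * (pH - 5.0) + tss_coupling * (TSS - 12.0)``,
    so nonzero couplings make the band informative for that response.
    """

    center: float       # nm
    width: float        # nm (Gaussian sigma)
    amplitude: float    # absorbance units
    ph_coupling: float = 0.0
    tss_coupling: float = 0.0

    PH_REF = 5.0
    TSS_REF = 12.0


def _default_ph() -> dict:
    # unfermented pH per variety and 24 h endpoint; plateau near 16-20 h
    return {
        "Typica": TrajectorySpec(5.60, 4.77, 0.25),
        "Caturra": TrajectorySpec(5.43, 4.60, 0.25),
        "Catimor": TrajectorySpec(5.57, 4.67, 0.25),
    }


def _default_tss() -> dict:
    # initial degrees Brix per variety; endpoints reflect sugar consumption
    return {
        "Typica": TrajectorySpec(15.87, 9.40, 0.15),
        "Caturra": TrajectorySpec(15.13, 8.80, 0.15),
        "Catimor": TrajectorySpec(16.53, 10.00, 0.15),
    }


def _default_bands() -> tuple[BandSpec, ...]:
    return (
        BandSpec(1205.0, 10.0, 0.18, tss_coupling=0.014),   # C-H: lipids, sugars
        BandSpec(1451.0, 10.0, 0.45, ph_coupling=-0.10),    # O-H: water
        BandSpec(1729.0, 10.0, 0.12, tss_coupling=0.012),   # C-H: caffeine region
        BandSpec(1839.0, 12.0, 0.10),                        # C-H: cellulose (inert)
        BandSpec(1927.0, 10.0, 0.50, ph_coupling=-0.08),    # O-H: water
    )


@dataclass(frozen=True)
class FermentationScenario:
    """Study design and noise model for one synthetic dataset."""

    varieties: tuple[str, ...] = ("Typica", "Caturra", "Catimor")
    times_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    subsamples: int = 2
    profiles_per_sample: int = 50
    ph: dict = field(default_factory=_default_ph)
    tss: dict = field(default_factory=_default_tss)
    bands: tuple[BandSpec, ...] = field(default_factory=_default_bands)
    wavelength_start: float = 1100.0
    wavelength_end: float = 2100.0
    wavelength_step: float = 2.0
    # chemistry jitter applied per sub-sample (shared by its profiles)
    ph_jitter_sd: float = 0.02
    tss_jitter_sd: float = 0.15
    # analytical error on the *reported* reference values
    ph_ref_error_sd: float = 0.05
    tss_ref_error_sd: float = 0.40
    # spectral noise: per-point iid noise and per-profile baseline offset,
    # calibrated so a full-spectrum PLSR reaches R2_cv near 0.95
    noise_sd: float = 0.008
    drift_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in self.ph.values():
            if spec.end > spec.start:
                raise ScenarioError("pH must not rise during fermentation")
        lo, hi = self.wavelength_start, self.wavelength_end
        for band in self.bands:
            if not lo <= band.center <= hi:
                raise ScenarioError(f"band center {band.center} nm outside axis")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start,
            self.wavelength_end + 0.5 * self.wavelength_step,
            self.wavelength_step,
        )

    @property
    def n_profiles(self) -> int:
        return (
            len(self.varieties)
            * len(self.times_h)
            * self.subsamples
            * self.profiles_per_sample
        )

    def noiseless(self) -> "FermentationScenario":
        """Copy with every stochastic term switched off."""
        return replace(
            self,
            ph_jitter_sd=0.0, tss_jitter_sd=0.0,
            ph_ref_error_sd=0.0, tss_ref_error_sd=0.0,
            noise_sd=0.0, drift_sd=0.0,
        )

    def informative_indices(self, response: str) -> np.ndarray:
        """Planted informative wavelength indices for ``response``.

        A wavelength counts as planted when it lies within one Gaussian
        width of the center of a band coupled to the response; by
        construction this is a subset of the coupled bands' support.
        """
        wl = self.wavelengths
        mask = np.zeros(wl.size, dtype=bool)
        for band in self.bands:
            coupling = band.ph_coupling if response == "pH" else band.tss_coupling
            if coupling != 0.0:
                mask |= np.abs(wl - band.center) <= band.width
        return np.flatnonzero(mask)


def shrunken_scenario(seed: int = 0, **overrides) -> FermentationScenario:
    """A 15-profile scenario (1 variety x 3 times x 1 x 5) for fast tests."""
    scenario = FermentationScenario(
        varieties=("Typica",),
        times_h=(0.0, 12.0, 24.0),
        subsamples=1,
        profiles_per_sample=5,
        seed=seed,
    )
    return replace(scenario, **overrides) if overrides else scenario


def small_scenario(seed: int = 0, **overrides) -> FermentationScenario:
    """A 126-profile scenario (3 x 7 x 2 x 3) keeping the full design grid."""
    scenario = FermentationScenario(profiles_per_sample=3, seed=seed)
    return replace(scenario, **overrides) if overrides else scenario


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def simulate_trajectories(scenario: FermentationScenario) -> pd.DataFrame:
    """Per-profile chemistry table.

    Columns: sample_id, variety, time_h, subsample, replicate, and four
    chemistry columns — ``ph``/``tss`` are the latent values that drive the
    spectra (jittered per sub-sample), ``ph_ref``/``tss_ref`` add the
    analytical error of the reported reference measurement.
    """
    rng = np.random.default_rng(scenario.seed)
    t_final = max(scenario.times_h)
    records = []
    for variety in scenario.varieties:
        for t in scenario.times_h:
            ph_curve = float(scenario.ph[variety].value(np.array(t), t_final))
            tss_curve = float(scenario.tss[variety].value(np.array(t), t_final))
            for sub in range(scenario.subsamples):
                ph = ph_curve + rng.normal(0.0, scenario.ph_jitter_sd) if scenario.ph_jitter_sd else ph_curve
                tss = tss_curve + rng.normal(0.0, scenario.tss_jitter_sd) if scenario.tss_jitter_sd else tss_curve
                ph_ref = ph + (rng.normal(0.0, scenario.ph_ref_error_sd) if scenario.ph_ref_error_sd else 0.0)
                tss_ref = tss + (rng.normal(0.0, scenario.tss_ref_error_sd) if scenario.tss_ref_error_sd else 0.0)
                for rep in range(scenario.profiles_per_sample):
                    records.append(
                        {
                            "sample_id": f"{variety}_t{t:g}_s{sub}_r{rep}",
                            "variety": variety,
                            "time_h": t,
                            "subsample": sub,
                            "replicate": rep,
                            "ph": ph,
                            "tss": tss,
                            "ph_ref": ph_ref,
                            "tss_ref": max(tss_ref, 0.0),
                        }
                    )
    return pd.DataFrame.from_records(records)


def simulate_spectra(
    scenario: FermentationScenario, trajectories: pd.DataFrame
) -> SpectrumSet:
    """Reflectance spectra for every profile row of the trajectory table."""
    rng = np.random.default_rng(scenario.seed + 1)
    wl = scenario.wavelengths
    n = len(trajectories)

    # smooth instrument baseline in absorbance units
    rel = (wl - scenario.wavelength_start) / (
        scenario.wavelength_end - scenario.wavelength_start
    )
    baseline = 0.35 + 0.10 * rel

    profiles = np.broadcast_to(baseline, (n, wl.size)).copy()
    ph = trajectories["ph"].to_numpy()
    tss = trajectories["tss"].to_numpy()
    for band in scenario.bands:
        amp = (
            band.amplitude
            + band.ph_coupling * (ph - BandSpec.PH_REF)
            + band.tss_coupling * (tss - BandSpec.TSS_REF)
        )
        shape = np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
        profiles += amp[:, None] * shape[None, :]
    if scenario.drift_sd:
        profiles += rng.normal(0.0, scenario.drift_sd, size=(n, 1))
    if scenario.noise_sd:
        profiles += rng.normal(0.0, scenario.noise_sd, size=profiles.shape)

    n_clipped = int(np.sum(profiles <= 0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} absorbance values <= 0 clipped to keep reflectance in (0, 1]"
        )
        profiles = np.clip(profiles, 1e-6, None)
    reflectance = np.power(10.0, -profiles)

    return SpectrumSet(
        wavelengths=wl,
        values=reflectance,
        mode="reflectance",
        sample_ids=list(trajectories["sample_id"]),
        metadata=trajectories[["variety", "time_h", "subsample", "replicate"]].copy(),
    )


@dataclass
class Benchmark:
    """A complete synthetic dataset plus its planted ground truth."""

    spectra: SpectrumSet
    ph_ref: ReferenceTable
    tss_ref: ReferenceTable
    informative: dict[str, np.ndarray]
    trajectories: pd.DataFrame


def make_benchmark(scenario: FermentationScenario | None = None) -> Benchmark:
    """Generate spectra, reference tables and ground-truth indices.

    Bit-reproducible for a fixed scenario (including its seed).
    """
    scenario = scenario or FermentationScenario()
    trajectories = simulate_trajectories(scenario)
    spectra = simulate_spectra(scenario, trajectories)
    ph_ref = ReferenceTable(
        sample_ids=list(trajectories["sample_id"]),
        y=trajectories["ph_ref"].to_numpy(),
        response_name="pH",
    )
    tss_ref = ReferenceTable(
        sample_ids=list(trajectories["sample_id"]),
        y=trajectories["tss_ref"].to_numpy(),
        response_name="TSS",
    )
    return Benchmark(
        spectra=spectra,
        ph_ref=ph_ref,
        tss_ref=tss_ref,
        informative={
            "pH": scenario.informative_indices("pH"),
            "TSS": scenario.informative_indices("TSS"),
        },
        trajectories=trajectories,
    )
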