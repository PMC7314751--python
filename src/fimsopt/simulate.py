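"""Forward model of flow-injection Orbitrap acquisition with ion competition.

The mechanism this package exists to defeat is modelled directly: ions
transmitted by the quadrupole accumulate in the C-trap until either the
automatic gain control (AGC) target ``N_max`` is reached or the maximum
injection time ``T_max`` elapses.  For a total in-range ion flux Phi
(ions/ms) the realized injection time is therefore

    t = min(T_max, N_max / Phi)

and each ion contributes an accumulated count of ``flux * t``.  When a
scan range contains abundant ions, t collapses and low-flux ions fall
below the detection floor — ion competition.  A separate, much weaker
electrospray-suppression term scales *all* fluxes by ``1/(1 + k * L)``
where L is the total analyte load reaching the source, independent of the
quadrupole setting.

The synthetic metabolome emulates the statistical structure of a serum
sample: a skewed m/z density (a dense region near 500 m/z, a sparse one
near 1650), log-uniform ion fluxes spanning several orders of magnitude,
first 13C isotopologue satellites with abundance 1-(1-0.0107)^k for a
compound with k carbons, occasional adduct satellites, and low-flux
background contaminant ions that also appear in blank injections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import C13_C12_SPACING, ADDUCTS
from .ranges import ScanRangeSet

__all__ = [
    "IonSpecies",
    "AcquisitionConfig",
    "DensityProfile",
    "Compound",
    "SyntheticMetabolome",
    "ScanEvent",
    "injection_time",
    "generate_metabolome",
    "simulate_scan",
    "simulate_injection_series",
    "cohort_intensity_matrix",
]

#: Natural abundance of 13C.
C13_ABUNDANCE = 0.0107


@dataclass(frozen=True)
class IonSpecies:
    """One ion reaching the trap: true m/z, flux (ions/ms) and provenance."""

    mz: float
    flux: float
    polarity: str = "negative"
    compound_id: Optional[int] = None
    role: str = "monoisotopic"  # monoisotopic | 13C | adduct | background | spike

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("ion flux must be non-negative")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument model parameters.

    Defaults mirror a Q Exactive style method: AGC target 5e6 ions,
    maximum injection time 100 ms, 3 averaged micro scans.  The detection
    floor (accumulated ions) and multiplicative intensity noise CV are
    free model parameters; the ESI suppression coefficient k enters as
    ``flux_effective = flux / (1 + k * total_load)``.
    """

    agc_target: float = 5e6
    max_injection_time_ms: float = 100.0
    detection_floor: float = 500.0
    noise_cv: float = 0.10
    mz_sigma_ppm: float = 1.0
    esi_suppression_k: float = 1e-8
    micro_scans: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.agc_target <= 0 or self.max_injection_time_ms <= 0:
            raise ValueError("AGC target and max injection time must be positive")
        if self.noise_cv < 0 or self.mz_sigma_ppm < 0:
            raise ValueError("noise levels must be non-negative")
        if not (0 <= self.esi_suppression_k < 1):
            raise ValueError("ESI suppression coefficient must be in [0, 1)")
        if self.micro_scans < 1:
            raise ValueError("micro scan count must be >= 1")

    def noiseless(self) -> "AcquisitionConfig":
        """Copy with intensity and m/z noise switched off."""
        return replace(self, noise_cv=0.0, mz_sigma_ppm=0.0)


@dataclass(frozen=True)
class DensityProfile:
    """Mixture-of-Gaussians m/z density, truncated to the scan interval.

    ``components`` is a tuple of (weight, center, sd); weights are
    normalized.  The default emulates a serum-like profile: 80% of
    compounds in a dense region around 500 m/z and 20% in a sparse region
    around 1650 m/z.
    """

    components: Tuple[Tuple[float, float, float], ...] = (
        (0.8, 500.0, 100.0),
        (0.2, 1650.0, 300.0),
    )

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components], dtype=float)
        if (w <= 0).any():
            raise ValueError("component weights must be positive")

    @classmethod
    def point(cls, center: float) -> "DensityProfile":
        return cls(components=((1.0, center, 0.0),))

    def sample(
        self, n: int, interval: Tuple[float, float], rng: np.random.Generator
    ) -> np.ndarray:
        lo, hi = interval
        weights = np.array([c[0] for c in self.components], dtype=float)
        weights /= weights.sum()
        comp = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, c in enumerate(comp):
            _, center, sd = self.components[c]
            if sd == 0:
                out[i] = min(max(center, lo), hi)
                continue
            x = rng.normal(center, sd)
            while not (lo <= x < hi):  # truncation by rejection
                x = rng.normal(center, sd)
            out[i] = x
        return out


@dataclass(frozen=True)
class Compound:
    """A neutral compound and the ions it contributes to the spray."""

    compound_id: int
    monoisotopic_mz: float
    base_flux: float
    carbon_count: int
    ions: Tuple[IonSpecies, ...]


@dataclass
class SyntheticMetabolome:
    """Ground-truth ion content of a simulated biological sample."""

    compounds: List[Compound]
    background_ions: List[IonSpecies]
    polarity: str
    mz_interval: Tuple[float, float]

    def analyte_ions(self) -> List[IonSpecies]:
        return [ion for c in self.compounds for ion in c.ions]

    def all_ions(self) -> List[IonSpecies]:
        return self.analyte_ions() + list(self.background_ions)


@dataclass
class ScanEvent:
    """One quadrupole-isolated scan: realized injection time plus peaks."""

    range_low: float
    range_high: float
    injection_time_ms: float
    mz: np.ndarray
    intensity: np.ndarray
    injection_id: int = 0
    blank: bool = False
    polarity: str = "negative"

    @property
    def n_peaks(self) -> int:
        return len(self.mz)


def injection_time(total_flux: float, config: AcquisitionConfig) -> float:
    """Realized C-trap accumulation time t = min(T_max, N_max / Phi).

    An empty range (zero flux) accumulates for the full T_max.
    """
    if total_flux <= 0:
        return config.max_injection_time_ms
    return min(config.max_injection_time_ms, config.agc_target / total_flux)


def generate_metabolome(
    n_compounds: int,
    density: Optional[DensityProfile] = None,
    seed: int = 0,
    mz_interval: Tuple[float, float] = (70.0, 2500.0),
    flux_log10_range: Tuple[float, float] = (1.5, 5.0),
    adduct_probability: float = 0.2,
    polarity: str = "negative",
    n_background: int = 30,
    background_flux_range: Tuple[float, float] = (20.0, 300.0),
) -> SyntheticMetabolome:
    """Draw a synthetic metabolome with isotopologue and adduct satellites.

    Fluxes are log-uniform over ``flux_log10_range`` (default 3.5 decades,
    reproducing intensity-ordered dropout under competition).  Each
    compound with k carbons emits a first 13C isotopologue at
    +1.0033554 m/z with relative flux 1-(1-0.0107)^k; with probability
    ``adduct_probability`` it also emits an adduct satellite
    ([M-H2O-H]- in negative mode, [M+Na]+ in positive).  Deterministic
    under a fixed seed.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    density = density or DensityProfile()
    rng = np.random.default_rng(seed)
    lo, hi = mz_interval

    mzs = density.sample(n_compounds, mz_interval, rng)
    fluxes = 10.0 ** rng.uniform(*flux_log10_range, size=n_compounds)
    # crude carbon count from mass (~50% carbon by weight for organics)
    carbons = np.maximum(
        1, np.round(mzs / 24.0 * rng.uniform(0.7, 1.3, size=n_compounds))
    ).astype(int)
    has_adduct = rng.uniform(size=n_compounds) < adduct_probability
    adduct_rel = rng.uniform(0.1, 0.5, size=n_compounds)

    if polarity == "negative":
        adduct_offset = (
            ADDUCTS["[M-H2O-H]-"].mass_delta - ADDUCTS["[M-H]-"].mass_delta
        )
    elif polarity == "positive":
        adduct_offset = ADDUCTS["[M+Na]+"].mass_delta - ADDUCTS["[M+H]+"].mass_delta
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    compounds = []
    for i in range(n_compounds):
        ions = [
            IonSpecies(float(mzs[i]), float(fluxes[i]), polarity, i, "monoisotopic")
        ]
        sat_rel = 1.0 - (1.0 - C13_ABUNDANCE) ** int(carbons[i])
        ions.append(
            IonSpecies(
                float(mzs[i] + C13_C12_SPACING),
                float(fluxes[i] * sat_rel),
                polarity,
                i,
                "13C",
            )
        )
        if has_adduct[i]:
            ions.append(
                IonSpecies(
                    float(mzs[i] + adduct_offset),
                    float(fluxes[i] * adduct_rel[i]),
                    polarity,
                    i,
                    "adduct",
                )
            )
        compounds.append(
            Compound(i, float(mzs[i]), float(fluxes[i]), int(carbons[i]), tuple(ions))
        )

    background = [
        IonSpecies(
            float(rng.uniform(lo, hi)),
            float(rng.uniform(*background_flux_range)),
            polarity,
            None,
            "background",
        )
        for _ in range(n_background)
    ]
    return SyntheticMetabolome(compounds, background, polarity, mz_interval)


def _assemble_ions(
    metabolome: SyntheticMetabolome,
    spike: Optional[Sequence[IonSpecies]],
    blank: bool,
) -> List[IonSpecies]:
    ions = list(metabolome.background_ions)
    if not blank:
        ions.extend(metabolome.analyte_ions())
        if spike:
            ions.extend(spike)
    return ions


def simulate_scan(
    metabolome: SyntheticMetabolome,
    scan_range: Tuple[float, float],
    config: AcquisitionConfig,
    rng: Optional[np.random.Generator] = None,
    spike: Optional[Sequence[IonSpecies]] = None,
    blank: bool = False,
    injection_id: int = 0,
) -> ScanEvent:
    """Simulate one scan event over ``scan_range`` = [low, high).

    ESI suppression rescales every flux by 1/(1 + k*L) with L the total
    load of the spray (all ions, in range or not).  The injection time is
    then set by the AGC from the total *in-range* flux, and each in-range
    ion accumulates ``flux * t`` ions, perturbed by multiplicative
    Gaussian noise (CV reduced by averaging over micro scans) and a ppm-
    scale m/z measurement error.  Peaks below the detection floor are not
    reported.  Blank injections contain only background contaminant ions.
    """
    low, high = scan_range
    if not low < high:
        raise ValueError("scan range low must be below high")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    ions = _assemble_ions(metabolome, spike, blank)
    flux = np.array([i.flux for i in ions], dtype=float)
    mz = np.array([i.mz for i in ions], dtype=float)

    esi_factor = 1.0 / (1.0 + config.esi_suppression_k * flux.sum())
    eff_flux = flux * esi_factor

    in_range = (mz >= low) & (mz < high)
    t = injection_time(float(eff_flux[in_range].sum()), config)

    mz_in = mz[in_range]
    accumulated = eff_flux[in_range] * t
    if config.noise_cv > 0:
        eps = rng.normal(0.0, config.noise_cv, size=(config.micro_scans, len(mz_in)))
        accumulated = accumulated * np.clip(1.0 + eps.mean(axis=0), 0.0, None)
    if config.mz_sigma_ppm > 0:
        mz_obs = mz_in * (1.0 + rng.normal(0.0, config.mz_sigma_ppm * 1e-6, len(mz_in)))
    else:
        mz_obs = mz_in.copy()

    detected = accumulated >= config.detection_floor
    order = np.argsort(mz_obs[detected])
    return ScanEvent(
        range_low=float(low),
        range_high=float(high),
        injection_time_ms=float(t),
        mz=mz_obs[detected][order],
        intensity=accumulated[detected][order],
        injection_id=injection_id,
        blank=blank,
        polarity=metabolome.polarity,
    )


def simulate_injection_series(
    metabolome: SyntheticMetabolome,
    ranges: "ScanRangeSet | Sequence[Tuple[float, float]]",
    config: AcquisitionConfig,
    n_bio: int = 6,
    n_blank: int = 6,
    spike: Optional[Sequence[IonSpecies]] = None,
) -> List[ScanEvent]:
    """Replicate injections of a sample followed by blank injections.

    The ground truth is identical across the biological injections; only
    measurement noise differs (independent per scan).  Blanks share only
    the background ions.  Returns ``(n_bio + n_blank) * n_ranges`` scan
    events; deterministic for a fixed config seed.
    """
    if n_bio < 1 or n_blank < 0:
        raise ValueError("need at least one biological injection")
    range_list = list(ranges.ranges) if isinstance(ranges, ScanRangeSet) else list(ranges)
    rng = np.random.default_rng(config.seed)
    events: List[ScanEvent] = []
    for inj in range(n_bio + n_blank):
        blank = inj >= n_bio
        for rg in range_list:
            events.append(
                simulate_scan(
                    metabolome, rg, config, rng=rng, spike=spike,
                    blank=blank, injection_id=inj,
                )
            )
    return events


def cohort_intensity_matrix(
    metabolome: SyntheticMetabolome,
    n_samples: int,
    noise_cv: float = 0.10,
    biological_sigma: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-sample intensity profiles for the metabolome's analyte ions.

    Emulates a cohort of distinct biological samples: each compound gets
    an independent log-normal abundance factor per sample (sigma in log
    space ``biological_sigma``) shared by all its ions — monoisotopic,
    13C satellite and adduct — on top of which each ion receives
    independent multiplicative measurement noise of the given CV.  Rows
    are indexed by true ion m/z (sorted); columns are sample labels.
    Satellites therefore correlate tightly with their parent across
    samples, which is what correlation clustering exploits.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    ions = metabolome.analyte_ions()
    n_comp = len(metabolome.compounds)
    factors = rng.lognormal(0.0, biological_sigma, size=(n_comp, n_samples))
    data = np.empty((len(ions), n_samples))
    for r, ion in enumerate(ions):
        level = ion.flux * factors[ion.compound_id]
        noise = np.clip(1.0 + rng.normal(0.0, noise_cv, n_samples), 0.0, None)
        data[r] = level * noise
    df = pd.DataFrame(
        data,
        index=pd.Index([ion.mz for ion in ions], name="mz"),
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
    return df.sort_index()
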