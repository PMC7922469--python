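"""Synthetic soybean 1H-NMR cohorts.

Emulates the study design the analysis pipeline assumes: 68 spectra from
8 Korean regions and 9 Chinese provinces (3 provinces in each of the
northeastern/middle/southern regions), 4 experimental replicates per
region. Concentrations are lognormally perturbed around group means defined
by a base-concentration table and per-group fold-change effects; spectra are
rendered from the 25-metabolite assignment library as Lorentzian multiplets
on a 600-MHz instrument with a TSP reference singlet at 0.00 ppm and a
water-suppression notch at 4.7-5.0 ppm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library import MetaboliteLibrary, MetabolitePeak, build_metabolite_library

__all__ = [
    "GroupSpec",
    "CohortDesign",
    "SpectrumSet",
    "default_design",
    "simulate_cohort",
    "render_spectra",
    "simulate_spectra",
    "multiplet_lines",
    "MULTIPLET_WEIGHTS",
    "SPECTROMETER_MHZ",
]

#: Proton Larmor frequency (MHz); fixes the Hz -> ppm conversion J/600.
SPECTROMETER_MHZ = 600.0

#: Relative line intensities per multiplicity (first-order patterns; "m" is a
#: symmetric 5-line convention, "dd" is the outer product of two doublets).
MULTIPLET_WEIGHTS = {
    "s": (1.0,),
    "d": (1.0, 1.0),
    "t": (1.0, 2.0, 1.0),
    "q": (1.0, 3.0, 3.0, 1.0),
    "m": (1.0, 2.0, 3.0, 2.0, 1.0),
    "br_s": (1.0,),
}

#: Default J (Hz) used to space the 5-line "m" rendering, which has no
#: tabulated coupling constant.
DEFAULT_MULTIPLET_J = 7.0

#: Water-suppression window (ppm) and residual attenuation factor.
WATER_REGION = (4.7, 5.0)
WATER_ATTENUATION = 0.01


@dataclass(frozen=True)
class GroupSpec:
    """One sampling site: a country, a named region and its replicate count.

    ``tags`` carry the labels effect multipliers can attach to — the country
    plus, for Chinese provinces, the macro-region code (NR/MR/SR).
    """

    country: str
    region: str
    n_replicates: int = 4
    tags: tuple[str, ...] = ()

    @property
    def region_class(self) -> str:
        for t in self.tags:
            if t in ("NR", "MR", "SR"):
                return t
        return self.country


@dataclass
class CohortDesign:
    """Full specification of a simulated cohort.

    Parameters
    ----------
    groups : list of GroupSpec
        Sampling sites; the default design has 8 Korean + 9 Chinese sites,
        4 replicates each (68 samples).
    base_concentration : dict
        Metabolite -> group-mean concentration in arbitrary units.
    effects : dict
        Metabolite -> {tag: fold-change}. A sample's mean concentration is
        the base times the product of fold-changes whose tag appears in its
        group's tags. All fold-changes must be positive.
    replicate_cv : float
        Coefficient of variation of the multiplicative lognormal replicate
        noise on concentrations.
    shift_jitter_sd : float
        SD (ppm) of the per-sample, per-peak chemical-shift jitter.
    noise_sd : float
        SD of the additive Gaussian noise on rendered intensities.
    reference_area : float
        Area of the TSP reference singlet at 0.00 ppm (arbitrary units).
    instrument_drift_cv : float
        CV of the lognormal per-sample drift factor applied to the reference
        peak area (emulates internal-standard/instrument variability, which
        is what makes total-area and standardized-area normalization differ).
    ppm_min, ppm_max, ppm_step : float
        Acquisition grid.
    linewidth_fwhm : float
        Lorentzian full width at half maximum, ppm (1.2 Hz at 600 MHz).
    """

    groups: tuple[GroupSpec, ...]
    base_concentration: dict[str, float]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    replicate_cv: float = 0.10
    shift_jitter_sd: float = 0.002
    noise_sd: float = 3.0
    reference_area: float = 5.0
    instrument_drift_cv: float = 0.05
    ppm_min: float = 0.0
    ppm_max: float = 10.0
    ppm_step: float = 0.0005
    linewidth_fwhm: float = 0.002

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        for m, tags in self.effects.items():
            if m not in self.base_concentration:
                raise ValueError(
                    f"effects refer to unknown metabolite {m!r}"
                )
            for tag, fc in tags.items():
                if fc <= 0:
                    raise ValueError(
                        f"fold-change for {m!r}/{tag!r} must be > 0, got {fc}"
                    )

    @property
    def n_samples(self) -> int:
        return sum(g.n_replicates for g in self.groups)

    def ppm_axis(self) -> np.ndarray:
        n = int(round((self.ppm_max - self.ppm_min) / self.ppm_step)) + 1
        return self.ppm_min + self.ppm_step * np.arange(n)

    def with_(self, **kwargs) -> "CohortDesign":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def fold_change(self, metabolite: str, group: GroupSpec) -> float:
        fc = 1.0
        for tag, mult in self.effects.get(metabolite, {}).items():
            if tag == group.country or tag in group.tags:
                fc *= mult
        return fc


@dataclass
class SpectrumSet:
    """Aligned spectra plus per-sample metadata.

    Attributes
    ----------
    ppm : ndarray, shape (n_points,)
        Shared, monotonically increasing chemical-shift axis.
    intensities : ndarray, shape (n_samples, n_points)
    metadata : DataFrame
        Columns ``sample_id, country, region, region_class, replicate``.
    concentrations : DataFrame or None
        True simulated concentrations (samples x metabolites); kept for
        parameter-recovery tests, absent for spectra read from disk.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame
    concentrations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")
        if self.intensities.shape != (len(self.metadata), len(self.ppm)):
            raise ValueError(
                "intensities shape does not match metadata rows and ppm axis"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])


_KOREAN_REGIONS = (
    "Anseong", "Yeongwol", "Eumseong", "Cheonan",
    "Imsil", "Yeonggwang", "Uiseong", "Geochang",
)
_CHINESE_PROVINCES = (
    ("Heilongjiang", "NR"), ("Jilin", "NR"), ("Liaoning", "NR"),
    ("Hebei", "MR"), ("Shandong", "MR"), ("Hubei", "MR"),
    ("Zhejiang", "SR"), ("Guangdong", "SR"), ("Guangxi", "SR"),
)

# Group-mean concentrations, arbitrary units chosen to echo the gross
# composition of aqueous-methanol soybean extracts: sugars dominate, free
# amino and organic acids sit one order of magnitude lower.
_BASE_CONCENTRATION = {
    "2-hydroxyisobutyrate": 0.3,
    "2-oxoglutarate": 0.5,
    "acetate": 0.6,
    "acetoacetate": 0.3,
    "alanine": 1.2,
    "asparagine": 1.5,
    "aspartate": 1.0,
    "choline": 0.8,
    "citrate": 1.5,
    "formate": 0.2,
    "fumarate": 0.1,
    "galactarate": 0.6,
    "glucose": 4.0,
    "glutamate": 1.5,
    "hypoxanthine": 0.3,
    "isoleucine": 0.7,
    "leucine": 0.9,
    "malonate": 0.7,
    "oxypurinol": 0.2,
    "raffinose/stachyose": 5.0,
    "succinate": 0.5,
    "sucrose": 10.0,
    "tartarate": 0.8,
    "tryptophan": 0.4,
    "valine": 0.8,
}

#: Country-level discriminators (fold 1.30) and Chinese-region markers
#: (fold 1.40), in the directions the two-class and three-class analyses
#: report as significant.
_DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    # higher in Korean soybeans
    "alanine": {"Korea": 1.30, "SR": 1.40},
    "citrate": {"Korea": 1.30},
    "isoleucine": {"Korea": 1.30},
    "tartarate": {"Korea": 1.30, "NR": 1.40},
    "valine": {"Korea": 1.30},
    # higher in Chinese soybeans
    "asparagine": {"China": 1.30},
    "choline": {"China": 1.30},
    "galactarate": {"China": 1.30},
    "tryptophan": {"China": 1.30},
    # higher in the northeastern region of China
    "glucose": {"NR": 1.40},
    "hypoxanthine": {"NR": 1.40},
    "leucine": {"NR": 1.40},
    # higher in the southern region of China
    "malonate": {"SR": 1.40},
}

#: The nine metabolites planted as Korea-vs-China discriminators.
KOREA_CHINA_MARKERS = (
    "alanine", "citrate", "isoleucine", "tartarate", "valine",
    "asparagine", "choline", "galactarate", "tryptophan",
)

#: Markers planted with Chinese-region effects.
CHINA_REGION_MARKERS = (
    "glucose", "hypoxanthine", "leucine", "tartarate", "malonate", "alanine",
)


def default_design() -> CohortDesign:
    """The default 68-sample Korea/China cohort design."""
    groups = [GroupSpec("Korea", r, 4, ("Korea",)) for r in _KOREAN_REGIONS]
    groups += [
        GroupSpec("China", prov, 4, ("China", reg))
        for prov, reg in _CHINESE_PROVINCES
    ]
    return CohortDesign(
        groups=tuple(groups),
        base_concentration=dict(_BASE_CONCENTRATION),
        effects={m: dict(t) for m, t in _DEFAULT_EFFECTS.items()},
    )


def simulate_cohort(
    design: CohortDesign, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample metabolite concentrations for a cohort design.

    Concentration of metabolite *m* in sample *i* is
    ``base[m] * fold_change(group(i), m) * exp(eps)`` with lognormal ``eps``
    tuned so the multiplicative noise has CV ``design.replicate_cv``.

    Returns
    -------
    concentrations : DataFrame, samples x metabolites
    metadata : DataFrame
        Columns ``sample_id, country, region, region_class, replicate``.
    """
    rng = np.random.default_rng(seed)
    names = list(design.base_concentration)
    sigma = math.sqrt(math.log(1.0 + design.replicate_cv**2))
    rows, meta = [], []
    for g in design.groups:
        mean = np.array(
            [design.base_concentration[m] * design.fold_change(m, g) for m in names]
        )
        for rep in range(1, g.n_replicates + 1):
            noise = (
                np.exp(rng.normal(0.0, sigma, size=len(names)))
                if sigma > 0
                else np.ones(len(names))
            )
            rows.append(mean * noise)
            meta.append(
                {
                    "sample_id": f"{g.country[:2].upper()}-{g.region}-{rep}",
                    "country": g.country,
                    "region": g.region,
                    "region_class": g.region_class,
                    "replicate": rep,
                }
            )
    metadata = pd.DataFrame(meta)
    conc = pd.DataFrame(rows, index=metadata["sample_id"], columns=names)
    return conc, metadata


def multiplet_lines(peak: MetabolitePeak) -> tuple[np.ndarray, np.ndarray]:
    """Line positions (Hz, relative to multiplet centre) and unit-sum weights."""
    m = peak.multiplicity
    if m == "dd":
        j1, j2 = peak.j_values
        offs, wts = [], []
        for s1 in (-0.5, 0.5):
            for s2 in (-0.5, 0.5):
                offs.append(s1 * j1 + s2 * j2)
                wts.append(1.0)
    else:
        w = MULTIPLET_WEIGHTS[m]
        n = len(w)
        j = peak.j_values[0] if peak.j_values else DEFAULT_MULTIPLET_J
        offs = [(k - (n - 1) / 2.0) * j for k in range(n)]
        wts = list(w)
    offs = np.asarray(offs)
    wts = np.asarray(wts, dtype=float)
    return offs, wts / wts.sum()


def _lorentzian(ppm: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    gamma = fwhm / 2.0  # HWHM
    return area * gamma / (np.pi * ((ppm - center) ** 2 + gamma**2))


def render_spectra(
    concentrations: pd.DataFrame,
    library: MetaboliteLibrary,
    design: CohortDesign,
    seed: int,
    metadata: pd.DataFrame | None = None,
) -> SpectrumSet:
    """Render concentration vectors into Lorentzian multiplet spectra.

    Every peak of every metabolite becomes a first-order multiplet of
    Lorentzian lines centred at ``center_shift`` plus per-sample jitter; line
    offsets are ``k * J / 600`` ppm with binomial intensity ratios, and the
    total multiplet area equals the metabolite concentration (one proton
    equivalent per assignment row). A TSP reference singlet at 0.00 ppm has
    area ``reference_area`` times a per-sample drift factor. Intensities in
    the 4.7-5.0 ppm water-suppression window are attenuated by 0.01 before
    additive Gaussian noise.

    Deterministic given ``seed``.
    """
    ppm = design.ppm_axis()
    for p in library.peaks:
        if not (ppm[0] <= p.center_shift <= ppm[-1]):
            raise ValueError(
                f"ppm grid [{ppm[0]}, {ppm[-1]}] does not cover peak "
                f"{p.metabolite_name!r} at {p.center_shift} ppm"
            )
    if np.any(concentrations.values <= 0):
        raise ValueError("concentrations must be positive")

    rng = np.random.default_rng(seed)
    n = len(concentrations)
    out = np.zeros((n, len(ppm)))
    drift_sigma = math.sqrt(math.log(1.0 + design.instrument_drift_cv**2))
    water = (ppm >= WATER_REGION[0]) & (ppm <= WATER_REGION[1])

    for i in range(n):
        conc = concentrations.iloc[i]
        spec = np.zeros_like(ppm)
        for peak in library.peaks:
            c = float(conc.get(peak.metabolite_name, 0.0))
            if c <= 0:
                continue
            jitter = (
                rng.normal(0.0, design.shift_jitter_sd)
                if design.shift_jitter_sd > 0
                else 0.0
            )
            offs_hz, wts = multiplet_lines(peak)
            fwhm = design.linewidth_fwhm * (4.0 if peak.multiplicity == "br_s" else 1.0)
            center = peak.center_shift + jitter
            for off, wt in zip(offs_hz / SPECTROMETER_MHZ, wts):
                spec += _lorentzian(ppm, center + off, fwhm, c * wt)
        drift = math.exp(rng.normal(0.0, drift_sigma)) if drift_sigma > 0 else 1.0
        spec += _lorentzian(ppm, 0.0, design.linewidth_fwhm, design.reference_area * drift)
        spec[water] *= WATER_ATTENUATION
        if design.noise_sd > 0:
            spec += rng.normal(0.0, design.noise_sd, size=len(ppm))
        out[i] = spec

    if metadata is None:
        metadata = pd.DataFrame(
            {
                "sample_id": list(concentrations.index),
                "country": "",
                "region": "",
                "region_class": "",
                "replicate": 0,
            }
        )
    return SpectrumSet(
        ppm=ppm,
        intensities=out,
        metadata=metadata.reset_index(drop=True),
        concentrations=concentrations,
    )


def simulate_spectra(design: CohortDesign, seed: int) -> SpectrumSet:
    """Simulate concentrations and render spectra in one deterministic step.

    The cohort draw uses ``seed`` and the spectral render ``seed + 1``
    (both derived from the one seed the caller supplies).
    """
    library = build_metabolite_library()
    conc, meta = simulate_cohort(design, seed)
    return render_spectra(conc, library, design, seed + 1, metadata=meta)
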