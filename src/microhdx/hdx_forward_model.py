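"""Forward simulation of post-HDX deuterium isotope ladders.

The model: each labile (heteroatom-bound) proton of an ion is an independent
Bernoulli trial with a functional-group-dependent exchange probability; the
number of incorporated deuteriums therefore follows a Poisson-binomial
distribution.  For proton-bearing adducts ([M+H]+, [2M+H]+) the charging
proton itself can be picked up as a deuteron from heavy water, which is why a
compound with no exchangeable site still shows one deuterated peak.  The
deuterium-count distribution is convolved with the ion's natural-abundance
isotope pattern (the instrument cannot separate a 2H shift from 13C/15N at a
resolving power of 120,000), multiplicative log-normal noise emulates
shot-to-shot intensity variation, and channels below a relative floor are
dropped as they would be in a real centroided spectrum.

Liquid-phase microdroplet HDX is incomplete — back exchange with residual
protic solvent lowers every effective probability — and that incompleteness
is what encodes functional-group information.  Gas-phase HDX exchanges
essentially to completion, so in gas-phase mode every effective probability
is 1 and isobaric ions with equal site counts become indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem_core import Adduct, DEUTERIUM_STEP, Formula, ion_mz, natural_pattern

__all__ = [
    "SITE_CLASSES",
    "DEFAULT_SITE_PROBABILITIES",
    "DEFAULT_CHARGE_SITE_PROBABILITY",
    "ExchangeSite",
    "ExchangeSiteSet",
    "HDXConditions",
    "DeuteriumDistribution",
    "InstrumentModel",
    "DeuteriumLadder",
    "effective_probabilities",
    "deuterium_distribution",
    "simulate_ladder",
    "replicate_ladders",
]

SITE_CLASSES = ("hydroxyl", "phenol", "amine", "imine_NH", "amide_NH", "carboxyl")

# Per-class exchange probabilities under the reference liquid-phase condition
# (7:3 methanol : D2O spray solvent).  These are calibration constants of the
# forward model, chosen so that the simulated base peaks and ladder lengths of
# the reference compound panel match their observed qualitative behaviour:
# alcohols exchange faster than phenols, sugar base peaks sit at D2 (glucose) /
# D3 (inositol), and a charge-site probability below ~0.4 keeps D0 as the base
# peak of single-phenol opioids.  Overridable per run via HDXConditions.
DEFAULT_SITE_PROBABILITIES: dict[str, float] = {
    "hydroxyl": 0.45,
    "phenol": 0.20,
    "amine": 0.50,
    "imine_NH": 0.50,
    "amide_NH": 0.30,
    "carboxyl": 0.60,
}
DEFAULT_CHARGE_SITE_PROBABILITY = 0.25


@dataclass(frozen=True)
class ExchangeSite:
    site_class: str
    exchange_probability: float

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if not 0.0 <= self.exchange_probability <= 1.0:
            raise ValueError("exchange probability outside [0, 1]")


@dataclass(frozen=True)
class ExchangeSiteSet:
    """The exchangeable protons of one compound; may be empty."""

    sites: tuple[ExchangeSite, ...] = ()
    compound: str = ""

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_classes(
        cls,
        classes: dict[str, int],
        compound: str = "",
        probabilities: dict[str, float] | None = None,
    ) -> "ExchangeSiteSet":
        probs = {**DEFAULT_SITE_PROBABILITIES, **(probabilities or {})}
        sites = tuple(
            ExchangeSite(c, probs[c]) for c, n in classes.items() for _ in range(n)
        )
        return cls(sites, compound)


@dataclass(frozen=True)
class HDXConditions:
    """Spray-solvent and exchange-phase parameters.

    d2o_fraction is the deuterium fraction of the exchangeable hydrogen pool
    supplied by the aqueous part of the solvent (1.0 for pure D2O, as in a
    7:3 methanol:D2O spray); back_exchange_factor scales every probability
    down for re-protonation in flight.  Gas phase forces complete exchange.
    """

    d2o_fraction: float = 1.0
    back_exchange_factor: float = 1.0
    charge_site_exchange: bool = True
    charge_site_probability: float = DEFAULT_CHARGE_SITE_PROBABILITY
    phase: str = "liquid"

    def __post_init__(self) -> None:
        for name in ("d2o_fraction", "back_exchange_factor", "charge_site_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.phase not in ("liquid", "gas"):
            raise ValueError(f"phase must be 'liquid' or 'gas', got {self.phase!r}")


@dataclass(frozen=True)
class DeuteriumDistribution:
    """Pmf over deuterium counts 0..n_max."""

    pmf: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", p)
        if (p < -1e-12).any():
            raise ValueError("negative probability mass")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"pmf sums to {p.sum()}, not 1")

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.pmf)) @ self.pmf)


@dataclass(frozen=True)
class InstrumentModel:
    resolution: float = 120_000.0
    noise_cv: float = 0.05
    intensity_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0.0 <= self.intensity_floor < 1.0:
            raise ValueError("intensity_floor must be in [0, 1)")


@dataclass(frozen=True)
class DeuteriumLadder:
    """Intensities at integer deuteration channels D0..Dn of one precursor."""

    precursor_mz: float
    intensities: np.ndarray
    compound: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", a)
        if (a < 0).any():
            raise ValueError("ladder intensities must be non-negative")

    @property
    def n(self) -> int:
        """Highest channel index with signal."""
        nz = np.nonzero(self.intensities)[0]
        return int(nz[-1]) if nz.size else 0

    @property
    def channel_mz(self) -> np.ndarray:
        return self.precursor_mz + np.arange(len(self.intensities)) * DEUTERIUM_STEP

    @property
    def relative(self) -> np.ndarray:
        """Base-peak-normalized pattern, max = 100."""
        bp = self.intensities.max()
        if bp <= 0:
            raise ValueError("all-zero ladder cannot be normalized")
        return 100.0 * self.intensities / bp


def effective_probabilities(
    sites: ExchangeSiteSet, cond: HDXConditions
) -> list[float]:
    """Per-site exchange probabilities under the given conditions."""
    if cond.phase == "gas":
        return [1.0] * len(sites)
    scale = cond.d2o_fraction * cond.back_exchange_factor
    return [s.exchange_probability * scale for s in sites.sites]


def deuterium_distribution(
    probabilities: list[float] | np.ndarray,
    charge_extra: float | None = None,
) -> DeuteriumDistribution:
    """Poisson-binomial pmf of the deuterium count by iterative convolution.

    ``charge_extra`` appends the charge-site deuteron as one more independent
    Bernoulli trial.  Support length is n_sites (+1 for the charge site) + 1.
    """
    probs = list(probabilities)
    if charge_extra is not None:
        probs.append(charge_extra)
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for i, p in enumerate(probs):
        # DP step: P_{k} <- P_k (1-p) + P_{k-1} p
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - p) + pmf[: i + 1] * p
        pmf[0] *= 1 - p
    return DeuteriumDistribution(pmf)


def _charge_extra(adduct: Adduct, cond: HDXConditions) -> float | None:
    if not (adduct.proton_bearing and cond.charge_site_exchange):
        return None
    if cond.phase == "gas":
        return 1.0
    return (
        cond.charge_site_probability * cond.d2o_fraction * cond.back_exchange_factor
    )


def _multimer_sites(sites: ExchangeSiteSet, adduct: Adduct) -> ExchangeSiteSet:
    """For [2M+H]+ and higher multimers every monomer unit exchanges."""
    if adduct.multimer == 1:
        return sites
    return ExchangeSiteSet(sites.sites * adduct.multimer, sites.compound)


def noiseless_ladder(
    formula: Formula,
    adduct: Adduct,
    sites: ExchangeSiteSet,
    cond: HDXConditions,
    pattern_length: int | None = None,
) -> DeuteriumLadder:
    """Expected (noise-free) ladder: deuterium pmf convolved with the natural
    isotope pattern of the full ion (multimer included)."""
    all_sites = _multimer_sites(sites, adduct)
    dist = deuterium_distribution(
        effective_probabilities(all_sites, cond), _charge_extra(adduct, cond)
    )
    if pattern_length is None:
        pattern_length = len(dist.pmf) + 3  # deuterium channels + natural tail
    nat = natural_pattern(formula * adduct.multimer, pattern_length)
    chan = np.convolve(dist.pmf, nat.abundances)[:pattern_length]
    return DeuteriumLadder(ion_mz(formula, adduct), chan, sites.compound)


def simulate_ladder(
    formula: Formula,
    adduct: Adduct,
    sites: ExchangeSiteSet,
    cond: HDXConditions,
    instrument: InstrumentModel,
    scale: float = 1.0,
) -> DeuteriumLadder:
    """One noisy realization of the post-HDX ladder.

    Channel k of the noiseless ladder is sum_{d+j=k} pmf(d) * natural(j);
    per-channel multiplicative log-normal noise with CV = noise_cv is applied
    (mean-one, seeded), then channels below intensity_floor * max are dropped.
    ``scale`` sets the overall (per-mole) intensity.
    """
    clean = noiseless_ladder(formula, adduct, sites, cond)
    chan = clean.intensities * scale
    if instrument.noise_cv > 0:
        rng = np.random.default_rng(instrument.seed)
        sigma = np.sqrt(np.log1p(instrument.noise_cv**2))
        chan = chan * rng.lognormal(-sigma**2 / 2, sigma, size=chan.shape)
    if instrument.intensity_floor > 0:
        chan = np.where(chan >= instrument.intensity_floor * chan.max(), chan, 0.0)
    return DeuteriumLadder(clean.precursor_mz, chan, sites.compound)


def replicate_ladders(
    formula: Formula,
    adduct: Adduct,
    sites: ExchangeSiteSet,
    cond: HDXConditions,
    instrument: InstrumentModel,
    n_reps: int,
) -> list[DeuteriumLadder]:
    """Independent seeded noise realizations (deterministic given the seed)."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seeds = np.random.SeedSequence(instrument.seed).generate_state(n_reps)
    return [
        simulate_ladder(
            formula, adduct, sites, cond, replace(instrument, seed=int(s) % 2**31)
        )
        for s in seeds
    ]
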