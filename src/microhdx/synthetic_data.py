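"""Synthetic inputs for the HDX pipeline.

Everything the analysis consumes can be generated here: the reference
compound panel (shipped as a TSV compound table), pure post-HDX spectra,
two-component isobaric mixtures with known molar composition, internal-
standard calibration series, and a two-group urine-like cohort whose groups
differ in exchange extent for the urea/creatinine marker ions and in a
subset of ion abundances.  Every generator is a pure function of its seed.

The cohort emulates direct-infusion urine profiles: the 12-compound panel
plus 30 deuteration-free decoy ions in m/z 50-300 (where most urinary
metabolites fall), with log-normal biological abundance variation and
multiplicative channel noise.  It does not attempt realistic urinary
metabolome coverage, chromatographic structure, or matrix effects.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_core import ADDUCTS, Adduct, Formula, ion_mz, parse_formula
from .hdx_forward_model import (
    DeuteriumLadder,
    ExchangeSiteSet,
    HDXConditions,
    noiseless_ladder,
)
from .spectrum_io import Spectrum

__all__ = [
    "CompoundFixture",
    "CohortSpec",
    "CohortSample",
    "MixtureSample",
    "fixture_library",
    "fixture_ladder",
    "generate_mixture_samples",
    "generate_calibration_series",
    "generate_cohort",
]

_NO_HDX = HDXConditions(d2o_fraction=0.0, charge_site_exchange=False)


@dataclass(frozen=True)
class CompoundFixture:
    name: str
    formula: Formula
    adduct: Adduct
    site_classes: dict[str, int]
    charge_site_exchange: bool = True
    hdx_attenuation: float = 1.0
    abundance: float = 1.0

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, self.adduct)

    @property
    def site_set(self) -> ExchangeSiteSet:
        return ExchangeSiteSet.from_classes(self.site_classes, self.name)

    def conditions(self, base: HDXConditions | None = None) -> HDXConditions:
        """Per-compound effective conditions: the compound's back-exchange
        attenuation and charge-site availability folded into ``base``."""
        base = base or HDXConditions()
        return replace(
            base,
            back_exchange_factor=base.back_exchange_factor * self.hdx_attenuation,
            charge_site_exchange=base.charge_site_exchange
            and self.charge_site_exchange,
        )


def _parse_sites(text: str) -> dict[str, int]:
    sites: dict[str, int] = {}
    for token in filter(None, (t.strip() for t in text.split(";"))):
        cls, _, n = token.partition(":")
        sites[cls] = sites.get(cls, 0) + (int(n) if n else 1)
    return sites


def fixture_library(table: str | Path | None = None) -> list[CompoundFixture]:
    """The reference compound panel, read from the shipped compound table."""
    if table is None:
        table = importlib.resources.files("microhdx").joinpath("data/compounds.tsv")
    df = pd.read_csv(table, sep="\t", comment="#")
    out = []
    for row in df.to_dict("records"):
        sites = row["exchange_sites"]
        out.append(
            CompoundFixture(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                adduct=ADDUCTS[row["adduct"]],
                site_classes=_parse_sites("" if pd.isna(sites) else str(sites)),
                charge_site_exchange=str(row["charge_site_exchange"]).lower()
                == "true",
                hdx_attenuation=float(row["hdx_attenuation"]),
                abundance=float(row["abundance"]),
            )
        )
    return out


def _by_name(name: str) -> CompoundFixture:
    for fx in fixture_library():
        if fx.name == name:
            return fx
    raise KeyError(f"no fixture compound named {name!r}")


def fixture_ladder(
    name: str, cond: HDXConditions | None = None
) -> DeuteriumLadder:
    """Noise-free post-HDX ladder of a panel compound under ``cond``."""
    fx = _by_name(name)
    return noiseless_ladder(fx.formula, fx.adduct, fx.site_set, fx.conditions(cond))


def _noisy(arr: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return arr.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    return arr * rng.lognormal(-sigma**2 / 2, sigma, size=arr.shape)


def _merge_peaks(mz: np.ndarray, inten: np.ndarray, tol: float = 1e-6) -> Spectrum:
    """Sum coincident peaks (isobaric channels land on identical m/z)."""
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    breaks = np.nonzero(np.diff(mz) > tol)[0] + 1
    out_mz = np.array([g.mean() for g in np.split(mz, breaks)])
    out_in = np.array([g.sum() for g in np.split(inten, breaks)])
    keep = out_in > 0
    return Spectrum(out_mz[keep], out_in[keep])


def _ladder_spectrum(ladders: list[DeuteriumLadder]) -> Spectrum:
    mz = np.concatenate([lad.channel_mz for lad in ladders])
    inten = np.concatenate([lad.intensities for lad in ladders])
    return _merge_peaks(mz, inten)


# ---------------------------------------------------------------------------
# isobaric mixtures


@dataclass(frozen=True)
class MixtureSample:
    ratio: tuple[float, float]
    true_fractions: tuple[float, float]
    observed: DeuteriumLadder
    spectrum: Spectrum


def generate_mixture_samples(
    pair: tuple[str, str] = ("glucose", "inositol"),
    ratios: tuple[tuple[float, float], ...] = ((2, 2), (1, 3), (3, 1)),
    total_conc: float = 100.0,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> tuple[list[MixtureSample], DeuteriumLadder, DeuteriumLadder]:
    """Two-component isobaric mixtures at fixed total molar concentration.

    Per ratio, the absolute mixed pattern is the molar-weighted sum of the
    two per-mole pure patterns with seeded multiplicative channel noise; the
    truth table (true mole fractions) rides along in each sample.  Returns
    (samples, pure_g, pure_i) with the noise-free pure ladders.
    """
    rng = np.random.default_rng(seed)
    g, i = fixture_ladder(pair[0]), fixture_ladder(pair[1])
    n = max(len(g.intensities), len(i.intensities))
    gv = np.pad(g.intensities, (0, n - len(g.intensities)))
    iv = np.pad(i.intensities, (0, n - len(i.intensities)))
    gv, iv = gv / gv.sum(), iv / iv.sum()  # per-mole patterns
    samples = []
    for rg, ri in ratios:
        fg = rg / (rg + ri)
        mixed = total_conc * (fg * gv + (1 - fg) * iv)
        observed = DeuteriumLadder(
            g.precursor_mz, _noisy(mixed, noise_cv, rng), f"{pair[0]}+{pair[1]}"
        )
        samples.append(
            MixtureSample(
                (rg, ri), (fg, 1 - fg), observed, _ladder_spectrum([observed])
            )
        )
    return (
        samples,
        DeuteriumLadder(g.precursor_mz, gv, pair[0]),
        DeuteriumLadder(i.precursor_mz, iv, pair[1]),
    )


# ---------------------------------------------------------------------------
# calibration series


def generate_calibration_series(
    target: str = "codeine",
    interferent: str = "hydrocodone",
    internal_standard: str = "6-acetylmorphine",
    levels: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0, 100.0, 200.0),
    interferent_conc: float = 35.0,
    is_conc: float = 50.0,
    noise_cv: float = 0.005,
    seed: int = 0,
) -> tuple[list[tuple[float, Spectrum]], dict]:
    """Internal-standard calibration series for an isobaric target.

    Each level yields one spectrum containing the isobaric target+interferent
    ladder (channel-wise sum of the two per-mole patterns weighted by molar
    amount — concentrations in ug/mL are divided by molecular weight) plus
    the internal-standard ladder at its own m/z.  Before noise, the target's
    signature-channel deuterium content is strictly proportional to its
    concentration; the interferent populates only its own deuterium channels
    (D0/D1 plus natural tail).
    """
    if len(levels) < 3:
        raise ValueError("a calibration series needs at least 3 levels")
    rng = np.random.default_rng(seed)
    fx_t, fx_i, fx_s = _by_name(target), _by_name(interferent), _by_name(
        internal_standard
    )
    lad_t, lad_i, lad_s = (
        fixture_ladder(target),
        fixture_ladder(interferent),
        fixture_ladder(internal_standard),
    )
    mw = {fx.name: fx.formula.monoisotopic_mass() for fx in (fx_t, fx_i, fx_s)}
    n = max(len(lad_t.intensities), len(lad_i.intensities))
    tv = np.pad(lad_t.intensities, (0, n - len(lad_t.intensities)))
    iv = np.pad(lad_i.intensities, (0, n - len(lad_i.intensities)))
    spectra = []
    for conc in levels:
        iso = (conc / mw[target]) * tv + (interferent_conc / mw[interferent]) * iv
        is_chan = (is_conc / mw[internal_standard]) * lad_s.intensities
        iso_lad = DeuteriumLadder(lad_t.precursor_mz, _noisy(iso, noise_cv, rng))
        is_lad = DeuteriumLadder(lad_s.precursor_mz, _noisy(is_chan, noise_cv, rng))
        spectra.append((conc, _ladder_spectrum([iso_lad, is_lad])))
    meta = {
        "target": target,
        "interferent": interferent,
        "internal_standard": internal_standard,
        "target_mz": lad_t.precursor_mz,
        "is_mz": lad_s.precursor_mz,
        "units": "ug/mL",
    }
    return spectra, meta


# ---------------------------------------------------------------------------
# two-group cohort


@dataclass(frozen=True)
class CohortSpec:
    """Study design of the synthetic two-group urine cohort.

    Cases differ from controls in (a) the back-exchange factor applied to
    the marker ions (urea, creatinine) — controls re-protonate more, i.e.
    exchange less — and (b) a modest abundance multiplier on those markers.
    Abundances additionally vary log-normally between samples (biological
    variation), and each ladder channel carries multiplicative noise.
    """

    n_cases: int = 30
    n_controls: int = 9
    marker_compounds: tuple[str, ...] = ("urea", "creatinine")
    case_back_exchange: float = 1.0
    control_back_exchange: float = 0.6
    marker_abundance_multiplier: float = 1.4
    noise_cv: float = 0.05
    biological_cv: float = 0.4
    n_decoys: int = 30
    decoy_mz_range: tuple[float, float] = (50.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("group sizes must be >= 2")
        if self.marker_abundance_multiplier <= 0:
            raise ValueError("abundance multipliers must be positive")


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    group: str
    pre_hdx: Spectrum
    post_hdx: Spectrum


def generate_cohort(spec: CohortSpec) -> tuple[list[CohortSample], pd.DataFrame]:
    """Generate matched pre-/post-HDX spectra for every cohort sample.

    The pre-HDX spectrum of a sample is its metabolic profile sprayed with
    plain solvent (natural isotope patterns only); the post-HDX spectrum is
    the same profile after microdroplet exchange.  Returns the samples and a
    group table (sample_id, group).
    """
    rng = np.random.default_rng(spec.seed)
    panel = fixture_library()
    decoy_mz = np.sort(
        rng.uniform(*spec.decoy_mz_range, size=spec.n_decoys)
    )
    decoy_base = rng.lognormal(mean=0.0, sigma=0.8, size=spec.n_decoys) * 2.0

    # noise-free per-group ladders, computed once per compound
    group_ladders: dict[str, dict[str, tuple[np.ndarray, float]]] = {}
    for group, beta in (
        ("case", spec.case_back_exchange),
        ("control", spec.control_back_exchange),
    ):
        ladders = {}
        for fx in panel:
            cond = HDXConditions(
                back_exchange_factor=beta
                if fx.name in spec.marker_compounds
                else 1.0
            )
            post = noiseless_ladder(
                fx.formula, fx.adduct, fx.site_set, fx.conditions(cond)
            )
            ladders[fx.name] = (post.intensities, post.precursor_mz)
        group_ladders[group] = ladders
    pre_ladders = {
        fx.name: (
            noiseless_ladder(
                fx.formula, fx.adduct, fx.site_set, fx.conditions(_NO_HDX)
            ).intensities,
            fx.mz,
        )
        for fx in panel
    }

    samples = []
    rows = []
    labels = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    for idx, group in enumerate(labels):
        sid = f"{'BC' if group == 'case' else 'HC'}{idx:03d}"
        spectra = {}
        # per-sample abundances are shared between the pre- and post-HDX scans
        abund = {}
        for fx in panel:
            a = fx.abundance * np.exp(
                rng.normal(0.0, np.sqrt(np.log1p(spec.biological_cv**2)))
            )
            if group == "case" and fx.name in spec.marker_compounds:
                a *= spec.marker_abundance_multiplier
            abund[fx.name] = a
        decoy_now = _noisy(decoy_base, spec.biological_cv, rng)
        for phase, source in (("pre", pre_ladders), ("post", group_ladders[group])):
            mzs, intens = [decoy_mz], [decoy_now]
            for fx in panel:
                chan, mz0 = source[fx.name]
                noisy = _noisy(abund[fx.name] * chan, spec.noise_cv, rng)
                lad = DeuteriumLadder(mz0, noisy)
                mzs.append(lad.channel_mz)
                intens.append(noisy)
            merged = _merge_peaks(np.concatenate(mzs), np.concatenate(intens))
            spectra[phase] = Spectrum(
                merged.mz, merged.intensity, {"sample": sid, "phase": phase}
            )
        samples.append(CohortSample(sid, group, spectra["pre"], spectra["post"]))
        rows.append({"sample_id": sid, "group": group})
    return samples, pd.DataFrame(rows)
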