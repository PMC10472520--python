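"""Monte-Carlo simulator for 20,000-well digital-PCR chips.

Generates the synthetic data every other module is tested on: single
chips, tenfold dilution series and a soil depth-profile fixture (six
samples x three methanotroph types x three replicates) modelled on a
flooded paddy microcosm sliced at 2-mm depth intervals.

Chip model: the number of loaded molecules is Poisson at the requested
mean (aliquot sampling); molecules fall into wells multinomially with
probabilities proportional to per-well volumes (normal law, truncated
at zero, with configurable CV; gamma available behind a flag); each
molecule is detectable with a probability that depends on the
probe-template mismatch count (1.0 at 0-1 mismatches, 0.0 at >= 2 by
default); a well is positive iff it holds at least one detectable
molecule or a false-positive event fires. Fluorescence is two-component
normal noise around well-separated negative/positive means, mirroring
the clear bimodal separation of real chips.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .quant import ChipCounts

__all__ = [
    "SimConfig",
    "ProfileFixtureConfig",
    "ChipSimulation",
    "simulate_chip",
    "simulate_series",
    "simulate_profile",
    "load_profile_fixture",
    "loaded_copies_from_per_gram",
]

DEFAULT_DETECTION = {0: 1.0, 1: 1.0, 2: 0.0}


@dataclass(frozen=True)
class SimConfig:
    """Chip simulation parameters.

    ``detection_by_mismatch`` maps probe-template mismatch counts to
    per-molecule detection probabilities; counts not listed fall back to
    0.0 (the >= 3 mismatch behaviour). Intensity units are arbitrary;
    the defaults keep the two fluorescence components ~14 pooled SDs
    apart so automatic thresholding is unambiguous.
    """

    n_wells: int = 20_000
    mean_well_volume: float = 1.0
    volume_cv: float = 0.10
    detection_by_mismatch: dict = field(default_factory=lambda: dict(DEFAULT_DETECTION))
    false_positive_rate: float = 0.0
    neg_mean: float = 5_000.0
    neg_sd: float = 200.0
    pos_mean: float = 12_000.0
    pos_sd: float = 500.0
    volume_law: str = "truncnorm"  # or "gamma"
    loaded_volume_ul: float = 14.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_wells <= 0:
            raise ValueError("n_wells must be positive")
        if self.volume_cv < 0:
            raise ValueError("volume_cv must be >= 0")
        if not 0 <= self.false_positive_rate <= 1:
            raise ValueError("false_positive_rate must be in [0, 1]")
        for m, p in self.detection_by_mismatch.items():
            if not 0 <= p <= 1:
                raise ValueError(f"detection probability for {m} mismatches not in [0, 1]")
        if self.pos_mean <= self.neg_mean:
            raise ValueError("positive mean must exceed negative mean")
        if self.volume_law not in ("truncnorm", "gamma"):
            raise ValueError("volume_law must be 'truncnorm' or 'gamma'")

    def detection_probability(self, mismatches: int) -> float:
        return float(self.detection_by_mismatch.get(int(mismatches), 0.0))


@dataclass(frozen=True)
class ChipSimulation:
    """One simulated chip with its ground truth."""

    counts: ChipCounts
    intensities: np.ndarray | None
    true_copies_loaded: float  # requested mean
    molecules: int  # realized Poisson draw
    detectable_molecules: int
    probe_mismatch: int


def _well_volumes(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    n, mu, cv = config.n_wells, config.mean_well_volume, config.volume_cv
    if cv == 0:
        return np.full(n, mu)
    if config.volume_law == "gamma":
        shape = 1.0 / cv**2
        return rng.gamma(shape, mu / shape, size=n)
    v = rng.normal(mu, cv * mu, size=n)
    # renormalize the vanishing mass below zero (cv <= 0.33 in practice)
    bad = v <= 0
    while bad.any():
        v[bad] = rng.normal(mu, cv * mu, size=int(bad.sum()))
        bad = v <= 0
    return v


def simulate_chip(
    true_copies_loaded: float,
    probe_mismatch: int = 0,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    return_intensities: bool = True,
) -> ChipSimulation:
    """Simulate one chip at a given mean loaded copy number.

    Fully reproducible for a fixed ``config.seed`` (or supplied ``rng``).
    Set ``return_intensities=False`` to skip the fluorescence draw and
    work at the count level (large simulation studies).
    """
    if true_copies_loaded < 0:
        raise ValueError("true_copies_loaded must be >= 0")
    config = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    volumes = _well_volumes(rng, config)
    molecules = int(rng.poisson(true_copies_loaded))
    if molecules > 0:
        occupancy = rng.multinomial(molecules, volumes / volumes.sum())
    else:
        occupancy = np.zeros(config.n_wells, dtype=np.int64)

    p_det = config.detection_probability(probe_mismatch)
    if p_det == 1.0:
        detectable = occupancy
    elif p_det == 0.0:
        detectable = np.zeros_like(occupancy)
    else:
        detectable = rng.binomial(occupancy, p_det)
    positive = detectable > 0
    if config.false_positive_rate > 0:
        positive |= rng.random(config.n_wells) < config.false_positive_rate

    n_pos = int(positive.sum())
    counts = ChipCounts(
        n_total=config.n_wells,
        n_positive=n_pos,
        loaded_volume_ul=config.loaded_volume_ul,
    )
    intensities = None
    if return_intensities:
        intensities = rng.normal(config.neg_mean, config.neg_sd, size=config.n_wells)
        if n_pos:
            intensities[positive] = rng.normal(
                config.pos_mean, config.pos_sd, size=n_pos
            )
    return ChipSimulation(
        counts=counts,
        intensities=intensities,
        true_copies_loaded=float(true_copies_loaded),
        molecules=molecules,
        detectable_molecules=int(detectable.sum()),
        probe_mismatch=int(probe_mismatch),
    )


def simulate_series(
    levels,
    replicates: int,
    config: SimConfig | None = None,
    *,
    conc_basis: str = "mix",
    probe_mismatch: int = 0,
    rng: np.random.Generator | None = None,
    return_intensities: bool = False,
) -> pd.DataFrame:
    """Simulate a dilution series: independent chips per level x replicate.

    ``levels`` are expected concentrations in copies per uL. With
    ``conc_basis='mix'`` (default) the mean loaded copies are
    concentration x loaded volume (copies per uL of loaded reaction
    mix); ``'template'`` instead scales by the template fraction of the
    reaction before loading. Returns a tidy table consumable by
    :mod:`mobdpcr.validation`.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 dilution levels")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    config = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if conc_basis == "mix":
        scale = config.loaded_volume_ul
    elif conc_basis == "template":
        scale = config.loaded_volume_ul * 1.5 / 15.0
    else:
        raise ValueError("conc_basis must be 'mix' or 'template'")
    rows = []
    for conc in levels:
        expected = conc * scale
        for rep in range(1, replicates + 1):
            sim = simulate_chip(expected, probe_mismatch, config, rng,
                                return_intensities=return_intensities)
            rows.append(
                {
                    "concentration": conc,
                    "replicate": rep,
                    "expected_copies": expected,
                    "n_total": sim.counts.n_total,
                    "n_positive": sim.counts.n_positive,
                    "loaded_volume_ul": sim.counts.loaded_volume_ul,
                    "true_molecules": sim.molecules,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProfileFixtureConfig:
    """Ground truth and design for the soil depth-profile fixture.

    ``truth`` maps (sample, mob_type) to true copies per g dry soil for
    the bulk soil before flooding and five 2-mm layers after 30 days of
    flooded incubation. Replicate microcosms jitter the truth by a
    lognormal factor (``rep_sd_log10`` in log10 units). ``template_dilution``
    per type reflects pre-diluting abundant templates so chips stay in
    the precise occupancy range.
    """

    samples: tuple[str, ...]
    mob_types: tuple[str, ...]
    truth: dict  # (sample, mob_type) -> copies per g dry soil
    replicates: int = 3
    rep_sd_log10: float = 0.05
    elution_volume_ul: float = 100.0
    soil_dry_mass_g: float = 0.5
    template_dilution: dict = field(default_factory=dict)  # mob_type -> factor
    template_volume_ul: float = 1.5
    reaction_volume_ul: float = 15.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        for key, val in self.truth.items():
            if val < 0:
                raise ValueError(f"negative truth for {key}")

    def dilution(self, mob_type: str) -> float:
        return float(self.template_dilution.get(mob_type, 1.0))


def loaded_copies_from_per_gram(
    copies_per_g: float,
    fixture: ProfileFixtureConfig,
    mob_type: str,
    loaded_volume_ul: float = 14.5,
) -> float:
    """Forward conversion: soil abundance -> mean copies loaded on a chip."""
    per_ul_extract = copies_per_g * fixture.soil_dry_mass_g / fixture.elution_volume_ul
    per_ul_template = per_ul_extract / fixture.dilution(mob_type)
    per_ul_mix = per_ul_template * fixture.template_volume_ul / fixture.reaction_volume_ul
    return per_ul_mix * loaded_volume_ul


def simulate_profile(
    fixture: ProfileFixtureConfig,
    config: SimConfig | None = None,
    *,
    return_intensities: bool = True,
) -> tuple[pd.DataFrame, list[ChipSimulation]]:
    """Simulate one chip per (sample, type, replicate) of the fixture.

    Returns a tidy table plus the raw chip simulations (same order); the
    table keys each chip by sample, mob_type and replicate and records
    both the jittered per-replicate truth and the realized well counts.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(fixture.seed)
    rows, chips = [], []
    for sample in fixture.samples:
        for mob_type in fixture.mob_types:
            truth = float(fixture.truth[(sample, mob_type)])
            for rep in range(1, fixture.replicates + 1):
                jitter = 10.0 ** rng.normal(0.0, fixture.rep_sd_log10)
                true_g = truth * jitter
                loaded = loaded_copies_from_per_gram(
                    true_g, fixture, mob_type, config.loaded_volume_ul
                )
                sim = simulate_chip(loaded, 0, config, rng,
                                    return_intensities=return_intensities)
                chips.append(sim)
                rows.append(
                    {
                        "sample": sample,
                        "mob_type": mob_type,
                        "replicate": rep,
                        "true_copies_per_g": true_g,
                        "configured_copies_per_g": truth,
                        "true_copies_loaded": loaded,
                        "template_dilution": fixture.dilution(mob_type),
                        "n_total": sim.counts.n_total,
                        "n_positive": sim.counts.n_positive,
                        "loaded_volume_ul": sim.counts.loaded_volume_ul,
                    }
                )
    return pd.DataFrame(rows), chips


def load_profile_fixture(path=None) -> ProfileFixtureConfig:
    """Load the packaged paddy-soil depth-profile fixture (or a TOML file)."""
    if path is None:
        ref = resources.files("mobdpcr.data").joinpath("soil_profile.toml")
        with ref.open("rb") as fh:
            doc = tomllib.load(fh)
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    design = doc.get("design", {})
    extraction = doc.get("extraction", {})
    truth_doc = doc["truth"]
    samples = tuple(doc["design"]["samples"])
    mob_types = tuple(doc["design"]["mob_types"])
    truth = {}
    for sample in samples:
        for mob_type in mob_types:
            truth[(sample, mob_type)] = float(truth_doc[sample][mob_type])
    return ProfileFixtureConfig(
        samples=samples,
        mob_types=mob_types,
        truth=truth,
        replicates=int(design.get("replicates", 3)),
        rep_sd_log10=float(design.get("rep_sd_log10", 0.05)),
        elution_volume_ul=float(extraction.get("elution_volume_ul", 100.0)),
        soil_dry_mass_g=float(extraction.get("soil_dry_mass_g", 0.5)),
        template_dilution={
            k: float(v) for k, v in extraction.get("template_dilution", {}).items()
        },
        template_volume_ul=float(extraction.get("template_volume_ul", 1.5)),
        reaction_volume_ul=float(extraction.get("reaction_volume_ul", 15.0)),
        seed=int(design.get("seed", 7)),
    )
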