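"""Synthetic screening plates with mechanism-aware phenotype switching.

The simulator produces per-cell feature tables (integrated DNA intensity,
cell area, mitochondrial and TMRE intensities) and per-well bulk readouts
(ATP luminescence, MTS absorbance, membrane-integrity-gated DNA-dye signal)
for 384-well dose-response experiments, together with the generative ground
truth needed to test every downstream analysis stage.

The generative model: each well holds a mixture of cell-cycle phenotype
states (G1, S, G2/M, endoreduplicated, sub-G1).  A compound is described by
one or two Hill transitions — a primary response (e.g. G2/M arrest with cell
enlargement) and an optional higher-concentration switch (e.g. to an
apoptotic sub-G1 phenotype with cell loss).  Bulk metabolic readouts are
sums of per-cell contributions proportional to cell size, so cytostatic
arrest with enlargement inflates ATP/MTS per cell exactly as observed in
size-coupled viability assays, while the DNA-dye signal counts only
membrane-intact (non-sub-G1) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeState",
    "CompoundModel",
    "GrowthModel",
    "NoiseModel",
    "DosePlate",
    "UNTREATED_MIXTURE",
    "REFERENCE_SCALE",
    "BASE_AREA",
    "sample_population",
    "simulate_dose_plate",
    "expected_count",
    "hill_response",
    "builtin_scenarios",
    "Scenario",
]

#: Integrated DNA intensity of a noise-free 2N (G1) nucleus, arbitrary units.
REFERENCE_SCALE = 2.0e5
#: Area of a noise-free untreated G1 cell, pixels.
BASE_AREA = 400.0

# Bulk readout gains (arbitrary instrument units per summed per-cell signal).
ATP_GAIN = 1.25          # RLU per (area x atp_per_size) unit
MTS_GAIN = 1.2e-6        # absorbance per (area x mts_per_size) unit
CYQUANT_GAIN = 100.0     # RFU per unit of DNA content (2N = 1)

_LABELS = ("G1", "S", "G2M", "endoredup", "subG1")


@dataclass(frozen=True)
class PhenotypeState:
    """One cell-cycle phenotype state and its size/metabolism coupling.

    DNA content is drawn per cell according to ``label``: G1 = 1.0 (2N),
    S uniform on (1, 2), G2M = 2.0 (4N), endoreduplicated 4.0 (8N) or 8.0
    (16N; ``endoredup_high_fraction`` selects the higher ploidy), sub-G1
    uniform on (0.2, 0.75).

    ``size_multiplier`` is the fold change in cell area relative to an
    untreated G1 cell; ``mito_per_area`` the mitochondrial stain density per
    unit area; ``atp_per_size`` / ``mts_per_size`` the per-unit-area
    contribution to the bulk ATP and MTS signals; ``tmre_per_mito`` the
    membrane-potential dye signal per unit MitoTracker signal.
    """

    label: str
    size_multiplier: float = 1.0
    mito_per_area: float = 1.0
    atp_per_size: float = 1.0
    mts_per_size: float = 1.0
    tmre_per_mito: float = 1.0
    endoredup_high_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown phenotype label {self.label!r}; expected one of {_LABELS}")
        if self.size_multiplier <= 0:
            raise ValueError("size_multiplier must be > 0")
        if not 0.0 <= self.endoredup_high_fraction <= 1.0:
            raise ValueError("endoredup_high_fraction must be in [0, 1]")

    def sample_dna_content(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` DNA contents (multiples of 2N) for this state."""
        if self.label == "G1":
            return np.full(n, 1.0)
        if self.label == "S":
            return rng.uniform(1.0, 2.0, n)
        if self.label == "G2M":
            return np.full(n, 2.0)
        if self.label == "endoredup":
            return np.where(rng.random(n) < self.endoredup_high_fraction, 8.0, 4.0)
        # subG1: fragmented, sub-diploid
        return rng.uniform(0.2, 0.75, n)


#: (state, weight) pairs; weights must sum to 1.
Mixture = Sequence[tuple[PhenotypeState, float]]

#: Default untreated cycling population of an adherent line: G1-dominant with
#: a small basal apoptotic fraction.  Untreated cycling cells share the unit
#: reference size (size effects are modeled as drug-induced phenotypes);
#: sub-G1 cells shrink to 40 % area.
UNTREATED_MIXTURE: Mixture = (
    (PhenotypeState("G1"), 0.60),
    (PhenotypeState("S"), 0.15),
    (PhenotypeState("G2M"), 0.22),
    (PhenotypeState("subG1", size_multiplier=0.4), 0.03),
)


def _validate_mixture(mixture: Mixture) -> None:
    if len(mixture) == 0:
        raise ValueError("mixture must contain at least one state")
    total = math.fsum(w for _, w in mixture)
    if any(w < 0 for _, w in mixture):
        raise ValueError("mixture weights must be non-negative")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1 (got {total!r})")


def mixture_fractions(mixture: Mixture) -> dict[str, float]:
    """Aggregate mixture weights by phenotype label."""
    out = {lab: 0.0 for lab in _LABELS}
    for state, w in mixture:
        out[state.label] += w
    return out


@dataclass(frozen=True)
class CompoundModel:
    """Concentration-dependent phenotype switching of one compound.

    The primary Hill transition moves the population from the untreated
    cycling mixture to ``primary_phenotype``; an optional second transition
    at higher concentration (``switch_logec50 > primary_logec50``) moves it
    on to ``switch_phenotype`` and removes ``kill_fraction_at_switch`` of
    cells (lysis / detachment), producing biphasic dose responses.
    """

    name: str
    primary_logec50: float
    primary_hill: float
    primary_phenotype: Mixture
    switch_logec50: Optional[float] = None
    switch_hill: Optional[float] = None
    switch_phenotype: Optional[Mixture] = None
    kill_fraction_at_switch: float = 0.0

    def __post_init__(self) -> None:
        if self.primary_hill <= 0:
            raise ValueError("primary_hill must be > 0")
        _validate_mixture(self.primary_phenotype)
        if self.switch_logec50 is not None:
            if self.switch_logec50 <= self.primary_logec50:
                raise ValueError("switch_logec50 must exceed primary_logec50")
            if self.switch_hill is None or self.switch_hill <= 0:
                raise ValueError("switch_hill must be > 0 when switch_logec50 is set")
            if self.switch_phenotype is None:
                raise ValueError("switch_phenotype required when switch_logec50 is set")
            _validate_mixture(self.switch_phenotype)
        if not 0.0 <= self.kill_fraction_at_switch <= 1.0:
            raise ValueError("kill_fraction_at_switch must be in [0, 1]")


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth over the assay window.

    ``arrest_efficacy_max`` is the maximal fractional reduction of the growth
    rate at saturating primary response; it sets the Emax of the cell-count
    curve (full arrest freezes the population at its seeded size).
    """

    doubling_time: float = 24.0   # hours
    seed_count: int = 500         # cells/well at t=0
    duration: float = 48.0        # hours (~2 doublings at default)
    arrest_efficacy_max: float = 1.0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be > 0")
        if self.seed_count < 1:
            raise ValueError("seed_count must be >= 1")
        if not 0.0 <= self.arrest_efficacy_max <= 1.0:
            raise ValueError("arrest_efficacy_max must be in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: lognormal staining CVs, bulk readout CV, background.

    ``background_level`` is expressed as a fraction of the mean control
    signal of each bulk readout (blank wells read this level); it also sets
    the additive offset of rendered images.  All randomness derives from
    ``rng_seed`` through per-well substreams, so well order never changes
    results.
    """

    dna_cv: float = 0.06
    area_cv: float = 0.15
    readout_cv: float = 0.05
    background_level: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dna_cv", "area_cv", "readout_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def sample_population(
    states: Mixture,
    n: int,
    noise: NoiseModel,
    rng: Optional[np.random.Generator] = None,
    well: str = "A01",
    plate: str = "P1",
) -> pd.DataFrame:
    """Draw ``n`` cells from a phenotype mixture.

    Returns a per-cell table with measured features (``dna_int``, ``area``,
    ``mito_int``, ``tmre_int``) and generative truth columns (``true_label``,
    ``true_dna_content``, ``true_size``).  Measured DNA intensity is
    ``REFERENCE_SCALE x dna_content`` with multiplicative lognormal staining
    noise; area is ``BASE_AREA x size_multiplier`` with its own lognormal
    factor; mitochondrial intensity is ``area x mito_per_area``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    _validate_mixture(states)
    if rng is None:
        rng = np.random.default_rng(noise.rng_seed)

    weights = np.asarray([w for _, w in states], dtype=float)
    weights = weights / weights.sum()
    idx = rng.choice(len(states), size=n, p=weights)

    dna_content = np.empty(n)
    size_mult = np.empty(n)
    mito_dens = np.empty(n)
    tmre_ratio = np.empty(n)
    labels = np.empty(n, dtype=object)
    atp_per_size = np.empty(n)
    mts_per_size = np.empty(n)
    for k, (state, _) in enumerate(states):
        mask = idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        dna_content[mask] = state.sample_dna_content(m, rng)
        size_mult[mask] = state.size_multiplier
        mito_dens[mask] = state.mito_per_area
        tmre_ratio[mask] = state.tmre_per_mito
        labels[mask] = state.label
        atp_per_size[mask] = state.atp_per_size
        mts_per_size[mask] = state.mts_per_size

    dna_int = REFERENCE_SCALE * dna_content * _lognormal_factor(rng, noise.dna_cv, n)
    area = BASE_AREA * size_mult * _lognormal_factor(rng, noise.area_cv, n)
    mito_int = area * mito_dens
    tmre_int = mito_int * tmre_ratio

    return pd.DataFrame(
        {
            "plate": plate,
            "well": well,
            "cell_id": np.arange(n),
            "dna_int": dna_int,
            "area": area,
            "mito_int": mito_int,
            "tmre_int": tmre_int,
            "true_label": labels,
            "true_dna_content": dna_content,
            "true_size": size_mult,
            "atp_per_size": atp_per_size,
            "mts_per_size": mts_per_size,
        }
    )


def hill_response(conc: float, logec50: float, hill: float) -> float:
    """Fractional Hill response in [0, 1); 0 at zero concentration."""
    if conc <= 0:
        return 0.0
    return 1.0 / (1.0 + 10.0 ** (hill * (logec50 - math.log10(conc))))


def _mixture_at(compound: CompoundModel, untreated: Mixture, conc: float) -> Mixture:
    """Interpolate phenotype mixtures linearly in Hill-response space."""
    h1 = hill_response(conc, compound.primary_logec50, compound.primary_hill)
    mix: list[tuple[PhenotypeState, float]] = []
    mix += [(s, w * (1.0 - h1)) for s, w in untreated]
    mix += [(s, w * h1) for s, w in compound.primary_phenotype]
    if compound.switch_logec50 is not None:
        h2 = hill_response(conc, compound.switch_logec50, compound.switch_hill)
        mix = [(s, w * (1.0 - h2)) for s, w in mix]
        mix += [(s, w * h2) for s, w in compound.switch_phenotype]
    # drop zero-weight entries for cleanliness
    mix = [(s, w) for s, w in mix if w > 0]
    total = math.fsum(w for _, w in mix)
    return tuple((s, w / total) for s, w in mix)


def expected_count(compound: CompoundModel, growth: GrowthModel, conc: float) -> float:
    """Expected final cell count at one concentration.

    Growth rate is reduced by ``arrest_efficacy_max x h1(conc)``; the switch
    transition removes ``kill_fraction_at_switch x h2(conc)`` of the final
    population (cell loss beyond arrest).
    """
    h1 = hill_response(conc, compound.primary_logec50, compound.primary_hill)
    doublings = growth.duration / growth.doubling_time
    n = growth.seed_count * 2.0 ** (doublings * (1.0 - growth.arrest_efficacy_max * h1))
    if compound.switch_logec50 is not None:
        h2 = hill_response(conc, compound.switch_logec50, compound.switch_hill)
        n *= 1.0 - compound.kill_fraction_at_switch * h2
    return n


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    ids = []
    for i in range(n):
        ids.append(f"{rows[(i // 24) % 16]}{i % 24 + 1:02d}")
    return ids


@dataclass
class DosePlate:
    """A simulated dose-response plate: well table, per-cell table, ground truth."""

    wells: pd.DataFrame
    cells: pd.DataFrame
    truth: dict


def simulate_dose_plate(
    compound: CompoundModel,
    growth: GrowthModel,
    concentrations: Sequence[float],
    wells_per_conc: int,
    noise: NoiseModel,
    untreated: Mixture = UNTREATED_MIXTURE,
    control_wells: int = 8,
    blank_wells: int = 4,
    plate: str = "P1",
) -> DosePlate:
    """Simulate one 384-well dose-response plate.

    Layout: ``control_wells`` DMSO (zero-concentration) wells, then
    ``blank_wells`` medium-only blanks, then ``wells_per_conc`` replicate
    wells per test concentration.  Per-well counts are Poisson around the
    growth-model expectation; bulk readouts are size-weighted sums over the
    well's cells with multiplicative lognormal readout noise.  The DNA-dye
    (CyQuant-like) signal excludes sub-G1 cells, emulating a membrane-
    integrity quencher.  Each well draws from its own seed substream derived
    from ``noise.rng_seed`` and the well index.
    """
    concentrations = list(concentrations)
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be strictly positive")
    if control_wells < 2:
        raise ValueError("at least 2 DMSO control wells are required")
    if wells_per_conc < 1:
        raise ValueError("wells_per_conc must be >= 1")

    plan: list[tuple[str, float]] = []          # (role/compound name, conc)
    plan += [("DMSO", 0.0)] * control_wells
    plan += [("BLANK", float("nan"))] * blank_wells
    for c in sorted(concentrations):
        plan += [(compound.name, c)] * wells_per_conc
    ids = _well_ids(len(plan))

    well_rows = []
    cell_tables = []
    truth_wells: dict[str, dict] = {}
    for widx, ((role, conc), wid) in enumerate(zip(plan, ids)):
        rng = np.random.default_rng(np.random.SeedSequence([int(noise.rng_seed), widx]))
        if role == "BLANK":
            well_rows.append(
                {"plate": plate, "well": wid, "compound": "BLANK", "conc_molar": np.nan,
                 "count_truth": 0, "atp": 0.0, "mts": 0.0, "cyquant": 0.0,
                 "_atp_sig": 0.0, "_mts_sig": 0.0, "_cyq_sig": 0.0}
            )
            continue
        mix = _mixture_at(compound, untreated, conc) if conc > 0 else tuple(untreated)
        n_exp = expected_count(compound, growth, conc)
        count = int(rng.poisson(n_exp))
        cells = sample_population(mix, count, noise, rng=rng, well=wid, plate=plate)

        atp_sig = float((cells["area"] * cells["atp_per_size"]).sum()) * ATP_GAIN
        mts_sig = float((cells["area"] * cells["mts_per_size"]).sum()) * MTS_GAIN
        intact = cells["true_label"] != "subG1"
        cyq_sig = float(cells.loc[intact, "true_dna_content"].sum()) * CYQUANT_GAIN

        f_atp, f_mts, f_cyq = _lognormal_factor(rng, noise.readout_cv, 3)
        well_rows.append(
            {"plate": plate, "well": wid, "compound": role, "conc_molar": conc,
             "count_truth": count,
             "atp": atp_sig * f_atp, "mts": mts_sig * f_mts, "cyquant": cyq_sig * f_cyq,
             "_atp_sig": atp_sig, "_mts_sig": mts_sig, "_cyq_sig": cyq_sig}
        )
        cell_tables.append(cells)
        truth_wells[wid] = {
            "conc_molar": conc,
            "expected_count": n_exp,
            "fractions": mixture_fractions(mix),
            "mean_size_multiplier": float(math.fsum(s.size_multiplier * w for s, w in mix)),
        }

    wells = pd.DataFrame(well_rows)

    # additive background: a fraction of the mean control signal per readout;
    # ATP (no blank-subtraction protocol) gets none.
    ctrl = wells["compound"] == "DMSO"
    blank = wells["compound"] == "BLANK"
    if noise.background_level > 0:
        bg_rng = np.random.default_rng(np.random.SeedSequence([int(noise.rng_seed), len(plan)]))
        for col, sig in (("mts", "_mts_sig"), ("cyquant", "_cyq_sig")):
            bg = noise.background_level * float(wells.loc[ctrl, sig].mean())
            wells[col] = wells[col] + bg * _lognormal_factor(bg_rng, noise.readout_cv, len(wells))
    else:
        # blanks read exactly zero when background is off
        pass
    wells = wells.drop(columns=["_atp_sig", "_mts_sig", "_cyq_sig"])
    wells["is_control"] = ctrl
    wells["is_blank"] = blank

    cells = (
        pd.concat(cell_tables, ignore_index=True)
        if cell_tables
        else sample_population(untreated, 0, noise)
    )
    truth = {
        "compound": compound.name,
        "params": {
            "primary_logec50": compound.primary_logec50,
            "primary_hill": compound.primary_hill,
            "switch_logec50": compound.switch_logec50,
            "switch_hill": compound.switch_hill,
            "kill_fraction_at_switch": compound.kill_fraction_at_switch,
            "arrest_efficacy_max": growth.arrest_efficacy_max,
            "doubling_time": growth.doubling_time,
            "duration": growth.duration,
            "seed_count": growth.seed_count,
            "rng_seed": noise.rng_seed,
        },
        "untreated_fractions": mixture_fractions(untreated),
        "wells": truth_wells,
    }
    return DosePlate(wells=wells, cells=cells, truth=truth)


# ---------------------------------------------------------------------------
# Built-in mechanism scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named simulation setup: compound + growth + dilution series.

    Defaults to four replicate wells per concentration, the standard
    replicate convention for plate-based proliferation assays.
    """

    compound: CompoundModel
    growth: GrowthModel
    concentrations: tuple[float, ...]
    wells_per_conc: int = 4


def _dilutions(top_molar: float, n: int = 20, step: float = 2.0) -> tuple[float, ...]:
    return tuple(top_molar / step**k for k in range(n))


def builtin_scenarios() -> dict[str, Scenario]:
    """Mechanism-of-action presets mirroring classic screening phenotypes.

    ``mitotic_arrest``  — G2/M arrest with ~2x cell enlargement, no death
    (paclitaxel-type: shallow ATP Emax, ratio plateau near 2).
    ``dna_damage_biphasic`` — G2 arrest with enlargement switching to
    sub-G1/apoptosis with 80 % cell loss at higher doses (etoposide-type:
    bell-shaped ATP-per-cell ratio).
    ``s_phase_arrest`` — persistent S-phase arrest with enlargement and no
    convergence (gemcitabine-type in a p53-null line).
    ``endoreduplication_switch`` — 8N endoreduplication switching to 4N +
    sub-G1 (Aurora-B-inhibitor-type multiphasic proxy readouts).
    ``inactive`` — zero-span compound; all wells behave like DMSO.
    """
    growth = GrowthModel()
    g2m_big = (
        (PhenotypeState("G2M", size_multiplier=2.0), 0.9),
        (PhenotypeState("S", size_multiplier=1.6), 0.1),
    )
    g2_damage = (
        (PhenotypeState("G2M", size_multiplier=2.5), 0.85),
        (PhenotypeState("S", size_multiplier=2.0), 0.15),
    )
    apoptotic = (
        (PhenotypeState("subG1", size_multiplier=0.4), 0.7),
        (PhenotypeState("G2M", size_multiplier=1.5), 0.3),
    )
    s_arrest = (
        (PhenotypeState("S", size_multiplier=2.5), 0.9),
        (PhenotypeState("G1", size_multiplier=1.5), 0.1),
    )
    endoredup = (
        (PhenotypeState("endoredup", size_multiplier=3.0, endoredup_high_fraction=0.2), 0.85),
        (PhenotypeState("G2M", size_multiplier=1.8), 0.15),
    )
    late_4n_death = (
        (PhenotypeState("G2M", size_multiplier=1.5), 0.5),
        (PhenotypeState("subG1", size_multiplier=0.4), 0.5),
    )
    return {
        "mitotic_arrest": Scenario(
            CompoundModel("mitotic_arrest", primary_logec50=-8.3, primary_hill=2.0,
                          primary_phenotype=g2m_big),
            replace(growth, arrest_efficacy_max=0.95),
            _dilutions(2e-6),
        ),
        "dna_damage_biphasic": Scenario(
            CompoundModel("dna_damage_biphasic", primary_logec50=-6.8, primary_hill=1.5,
                          primary_phenotype=g2_damage,
                          switch_logec50=-5.3, switch_hill=2.0,
                          switch_phenotype=apoptotic, kill_fraction_at_switch=0.8),
            growth,
            _dilutions(62e-6),
        ),
        "s_phase_arrest": Scenario(
            CompoundModel("s_phase_arrest", primary_logec50=-8.7, primary_hill=1.2,
                          primary_phenotype=s_arrest),
            growth,
            _dilutions(25e-6),
        ),
        "endoreduplication_switch": Scenario(
            CompoundModel("endoreduplication_switch", primary_logec50=-7.5, primary_hill=1.5,
                          primary_phenotype=endoredup,
                          switch_logec50=-5.8, switch_hill=2.0,
                          switch_phenotype=late_4n_death, kill_fraction_at_switch=0.5),
            growth,
            _dilutions(25e-6),
        ),
        "inactive": Scenario(
            CompoundModel("inactive", primary_logec50=-6.0, primary_hill=1.0,
                          primary_phenotype=tuple(UNTREATED_MIXTURE)),
            replace(growth, arrest_efficacy_max=0.0),
            _dilutions(25e-6),
        ),
    }
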