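"""Seeded generators emulating every input surface of the mouse DMPK study.

Three experiment families are simulated: (1) duplicate 8-level calibration
batches with triplicate QCs under multiplicative lognormal noise, (2)
two-compartment IV-bolus concentration-time profiles at the study's
7-point sampling grid for the 5/10/30 mg/kg dose groups, with an optional
saturable-clearance mode that reproduces supra-proportional exposure at
the top dose, and (3) paired control / TiCl3-treated accurate-mass peak
tables plus per-metabolite product-ion spectra generated from a
ground-truth metabolite set (the corrected characterization table shipped
with the package).

All noise is multiplicative lognormal (concentrations and intensities are
positive quantities), parameterized by its coefficient of variation and a
mean of one.  A fixed seed yields bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ElementalFormula, ValidationError, parse_formula
from .metid import (
    DAPORINAD,
    OXYGEN_MASS,
    BiotransformRule,
    FragmentTemplate,
    Peak,
    ProductIonSpectrum,
    TransformationChain,
    default_fragment_template,
    fragment_ion_mz,
    rules_by_name,
)
from .nca import DEFAULT_SAMPLING_GRID, ConcentrationTimeProfile
from .quantcal import (
    DEFAULT_QC_LEVELS,
    CalibrationStandard,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruthMetabolite",
    "CalibrationBatch",
    "PeakTableSet",
    "load_reference_table",
    "reference_metabolites",
    "expected_localization",
    "multiplicative_noise",
    "sim_calibration_batch",
    "sim_qc_runs",
    "sim_pk_profiles",
    "sim_peak_tables",
]

#: Calibration standard levels of the qualified assay (ng/mL).
CALIBRATION_LEVELS = (1.02, 3.05, 9.14, 27.4, 82.3, 247.0, 741.0, 2220.0)


@dataclass(frozen=True)
class GroundTruthMetabolite:
    """One reference metabolite: its chain and where its steps sit."""

    label: str
    transformation: str
    mz: float  # published theoretical [M+H]+ m/z
    formula: ElementalFormula  # corrected elemental composition
    rt: float  # minutes
    steps: Mapping[str, int]  # rule name -> count
    amine_steps: Mapping[str, int]
    acyl_steps: Mapping[str, int]
    n_oxide: str  # yes | no | untested
    presence: Mapping[str, str]  # condition -> "O" | "-"
    note: str = ""

    def chain(
        self,
        parent: ElementalFormula = DAPORINAD,
        rules: Mapping[str, BiotransformRule] | None = None,
    ) -> TransformationChain:
        rules = rules or rules_by_name()
        return TransformationChain.from_steps(
            parent, {rules[name]: count for name, count in self.steps.items()}
        )


def load_reference_table() -> pd.DataFrame:
    """The shipped metabolite characterization table.

    Carries both the published formula column and the corrected one (three
    rows had formulas inconsistent with their own m/z and transformation
    name; the ``note`` column records each correction).
    """
    path = resources.files("dmpkit").joinpath("data/daporinad_metabolites.csv")
    with resources.as_file(path) as file:
        return pd.read_csv(file, keep_default_na=False)


def _parse_steps(text: str) -> dict[str, int]:
    steps: dict[str, int] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        name, _, count = part.partition("=")
        steps[name.strip()] = int(count) if count else 1
    return steps


_PRESENCE_COLUMNS = (
    "mouse_liver_microsome",
    "human_liver_microsome",
    "mouse_plasma",
)


def reference_metabolites() -> tuple[GroundTruthMetabolite, ...]:
    """The corrected reference set parsed into ground-truth records."""
    table = load_reference_table()
    records = []
    for _, row in table.iterrows():
        records.append(
            GroundTruthMetabolite(
                label=row["label"],
                transformation=row["transformation"],
                mz=float(row["mz"]),
                formula=parse_formula(row["formula"]),
                rt=float(row["rt_min"]),
                steps=_parse_steps(row["steps"]),
                amine_steps=_parse_steps(row["amine_steps"]),
                acyl_steps=_parse_steps(row["acyl_steps"]),
                n_oxide=row["n_oxide"],
                presence={col: row[col] for col in _PRESENCE_COLUMNS},
                note=row["note"],
            )
        )
    return tuple(records)


def expected_localization(metabolite: GroundTruthMetabolite) -> str:
    """Moiety pattern the localization engine should recover."""
    if not metabolite.steps or any(
        name.startswith(("amide", "hydrolysis")) for name in metabolite.steps
    ):
        return "unlocalized"
    amine = sum(metabolite.amine_steps.values())
    acyl = sum(metabolite.acyl_steps.values())
    if amine and acyl:
        return "both"
    if amine:
        return "amine_side"
    if acyl:
        return "acyl_side"
    return "unlocalized"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all generators; a fixed seed fixes the output."""

    seed: int = 0
    noise_cv: float = 0.05  # proportional noise on calibration responses
    calibration_levels: tuple[float, ...] = CALIBRATION_LEVELS
    qc_levels: tuple[float, ...] = DEFAULT_QC_LEVELS
    cal_coefficients: tuple[float, float, float] = (-3.0e-7, 3.0e-3, 2.0e-3)
    n_replicates_std: int = 2
    n_replicates_qc: int = 3
    # Two-compartment macro-constants per unit dose (ng/mL per mg/kg) and
    # hybrid rate constants (1/min): c(t)/dose = A e^{-alpha t} + B e^{-beta t}
    pk_coefficients: tuple[float, float] = (900.0, 230.0)
    pk_rates: tuple[float, float] = (0.08, 0.0131)
    sampling_grid: tuple[float, ...] = DEFAULT_SAMPLING_GRID
    pk_noise_cv: float = 0.10
    # clearance saturation above this dose (mg/kg) in saturable mode
    saturation_threshold: float = 10.0
    saturation_exponent: float = 0.7
    ppm_jitter: float = 1.5  # 1-sigma mass accuracy of simulated peaks, ppm
    peak_intensity: float = 1.0e5
    fragment_intensity: float = 1.0e4

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.pk_noise_cv < 0:
            raise ValidationError("noise CV must be >= 0")
        if self.ppm_jitter < 0:
            raise ValidationError("ppm jitter must be >= 0")


def multiplicative_noise(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Mean-one lognormal factors with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class CalibrationBatch:
    standards: tuple[CalibrationStandard, ...]
    qc: tuple[CalibrationStandard, ...]


def sim_calibration_batch(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> CalibrationBatch:
    """Duplicate standards and triplicate QCs from the quadratic forward
    model with proportional lognormal noise."""
    if config.noise_cv >= 0.5:
        raise ValidationError("noise_cv must be < 0.5 for a usable batch")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    a, b, c = config.cal_coefficients

    def forward(x: float) -> float:
        return a * x * x + b * x + c

    standards = []
    for level in config.calibration_levels:
        factors = multiplicative_noise(rng, config.noise_cv, config.n_replicates_std)
        for rep, factor in enumerate(factors, start=1):
            standards.append(
                CalibrationStandard(
                    level_id=f"STD-{level:g}",
                    nominal_conc=float(level),
                    area_ratio=float(forward(level) * factor),
                    replicate=rep,
                )
            )
    qcs = []
    for level in config.qc_levels:
        factors = multiplicative_noise(rng, config.noise_cv, config.n_replicates_qc)
        for rep, factor in enumerate(factors, start=1):
            qcs.append(
                CalibrationStandard(
                    level_id=f"QC-{level:g}",
                    nominal_conc=float(level),
                    area_ratio=float(forward(level) * factor),
                    replicate=rep,
                )
            )
    return CalibrationBatch(standards=tuple(standards), qc=tuple(qcs))


def sim_qc_runs(
    config: GeneratorConfig,
    n_runs: int = 3,
    noise_cv: float = 0.08,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Back-calculated QC concentrations for several qualification runs
    (columns run_id, level_id, nominal, measured)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for run in range(1, n_runs + 1):
        for level in config.qc_levels:
            factors = multiplicative_noise(rng, noise_cv, config.n_replicates_qc)
            for factor in factors:
                rows.append(
                    {
                        "run_id": f"run{run}",
                        "level_id": f"QC-{level:g}",
                        "nominal": float(level),
                        "measured": float(level * factor),
                    }
                )
    return pd.DataFrame(rows)


def sim_pk_profiles(
    config: GeneratorConfig,
    doses: Sequence[float] = (5.0, 10.0, 30.0),
    n_subjects: int = 3,
    saturable: bool = False,
    rng: np.random.Generator | None = None,
) -> list[ConcentrationTimeProfile]:
    """Two-compartment IV-bolus profiles, optionally with saturable
    elimination.

    In saturable mode the terminal rate constant shrinks above the
    saturation threshold (beta * (threshold/dose)^exponent), so
    dose-normalized AUC climbs at the top dose while Cmax stays
    dose-proportional — the signature of a saturating elimination pathway.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coef_a, coef_b = config.pk_coefficients
    alpha, beta = config.pk_rates
    if not (alpha > beta > 0):
        raise ValidationError(
            f"macro rate constants need alpha > beta > 0, got {alpha}, {beta}"
        )
    t = np.asarray(config.sampling_grid, dtype=float)
    profiles = []
    for dose in doses:
        beta_eff = beta
        if saturable and dose > config.saturation_threshold:
            beta_eff = beta * (config.saturation_threshold / dose) ** (
                config.saturation_exponent
            )
        clean = dose * (coef_a * np.exp(-alpha * t) + coef_b * np.exp(-beta_eff * t))
        for subject in range(1, n_subjects + 1):
            noisy = clean * multiplicative_noise(rng, config.pk_noise_cv, t.size)
            profiles.append(
                ConcentrationTimeProfile(
                    subject_id=f"d{dose:g}-s{subject}",
                    dose=float(dose),
                    times=t.copy(),
                    concs=noisy,
                )
            )
    return profiles


@dataclass(frozen=True)
class PeakTableSet:
    """Paired peak tables and MS2 spectra with their generating truth."""

    control: tuple[Peak, ...]
    treated: tuple[Peak, ...]
    spectra: Mapping[str, ProductIonSpectrum]
    ground_truth: tuple[GroundTruthMetabolite, ...]


#: Product ions of the amide-cleavage metabolites, which lose the acyl
#: moiety entirely and so are not described by moiety-shifted templates.
_HYDROLYSIS_FRAGMENTS: dict[str, tuple[str, ...]] = {
    "amide_hydrolysis": ("C9H17N", "C7H4O"),
    "hydrolysis_then_carboxylation": ("C9H15NO2", "C7H4O"),
    "hydrolysis_then_hydroxylation": ("C16H21NO", "C7H4O"),
}

_PARENT_ENTRY = GroundTruthMetabolite(
    label="Parent",
    transformation="Parent",
    mz=392.2333,
    formula=DAPORINAD,
    rt=22.31,
    steps={},
    amine_steps={},
    acyl_steps={},
    n_oxide="untested",
    presence={col: "O" for col in _PRESENCE_COLUMNS},
)


def sim_peak_tables(
    config: GeneratorConfig,
    ground_truth: Sequence[GroundTruthMetabolite] | None = None,
    template: FragmentTemplate | None = None,
    rng: np.random.Generator | None = None,
) -> PeakTableSet:
    """Paired control/TiCl3 peak tables + MS2 spectra from a ground truth.

    Each ground-truth species becomes a peak at its theoretical [M+H]+ m/z
    perturbed by Gaussian ppm jitter, at its reference retention time, with
    a fixed intensity.  MS2 fragments are the parent's diagnostic template
    shifted by the mass of the steps the truth assigns to each moiety.  In
    the treated table every N-oxide loses 95% of its intensity and a
    reduced partner one oxygen lighter appears at the parent's retention
    time (TiCl3 reduction happens in solution before injection; placing the
    regenerated species at the parent's elution position keeps the
    reduced-partner gain observable without inventing new elution times).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    template = template or default_fragment_template()
    rules = rules_by_name()
    entries = list(reference_metabolites() if ground_truth is None else ground_truth)
    if not entries:
        entries = [_PARENT_ENTRY]
    parent_rt = next((e.rt for e in entries if not e.steps), None)

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0.0, config.ppm_jitter) * 1e-6)

    control: list[Peak] = []
    treated: list[Peak] = []
    spectra: dict[str, ProductIonSpectrum] = {}
    for entry in entries:
        chain = entry.chain(rules=rules)
        obs_mz = jitter(chain.theoretical_mz)
        control.append(
            Peak(
                condition="control",
                rt=entry.rt,
                mz=obs_mz,
                intensity=config.peak_intensity,
            )
        )
        hydrolytic = next(
            (name for name in entry.steps if name in _HYDROLYSIS_FRAGMENTS), None
        )
        fragments: list[tuple[float, float]] = []
        if hydrolytic is not None:
            for formula_text in _HYDROLYSIS_FRAGMENTS[hydrolytic]:
                fragments.append(
                    (
                        jitter(fragment_ion_mz(parse_formula(formula_text))),
                        config.fragment_intensity,
                    )
                )
        else:
            amine_mass = sum(
                rules[name].delta_mass * count
                for name, count in entry.amine_steps.items()
            )
            acyl_mass = sum(
                rules[name].delta_mass * count
                for name, count in entry.acyl_steps.items()
            )
            for template_entry in template.entries:
                shift = (
                    amine_mass
                    if template_entry.moiety == "amine_side"
                    else acyl_mass
                )
                fragments.append(
                    (
                        jitter(fragment_ion_mz(template_entry.formula) + shift),
                        config.fragment_intensity,
                    )
                )
        spectra[entry.label] = ProductIonSpectrum(
            precursor_mz=obs_mz, fragments=tuple(fragments)
        )
        if entry.n_oxide == "yes":
            treated.append(
                Peak(
                    condition="ticl3",
                    rt=entry.rt,
                    mz=obs_mz,
                    intensity=config.peak_intensity * 0.05,
                )
            )
            partner_mz = jitter(chain.theoretical_mz - OXYGEN_MASS)
            treated.append(
                Peak(
                    condition="ticl3",
                    rt=parent_rt if parent_rt is not None else entry.rt,
                    mz=partner_mz,
                    intensity=config.peak_intensity * 0.9,
                )
            )
        else:
            treated.append(
                Peak(
                    condition="ticl3",
                    rt=entry.rt,
                    mz=obs_mz,
                    intensity=config.peak_intensity,
                )
            )
    return PeakTableSet(
        control=tuple(control),
        treated=tuple(treated),
        spectra=spectra,
        ground_truth=tuple(entries),
    )
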