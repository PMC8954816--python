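"""Biotransformation-chain enumeration, peak annotation, moiety localization
and the TiCl3 N-oxide differential.

The engine reasons about a parent drug as two diagnostic substructures — for
Daporinad, the 4-butylpiperidine *amine side* and the pyridine-acryloyl
*acyl side* — linked by an amide bond.  Metabolite candidates are generated
as multisets of elemental-composition changes ("chains"), matched to
observed accurate-mass peaks within a ppm tolerance, and localized by
predicting how each diagnostic product ion shifts when the chain's steps
are assigned to one moiety or the other.  N-oxides are called from a paired
control / TiCl3-treated experiment: TiCl3 chemically reduces an N-oxide back
to its parent amine, so the N-oxide peak collapses while a peak one oxygen
lighter gains intensity.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .chem import (
    MONOISOTOPIC_MASSES,
    PROTON_MASS,
    ChainError,
    ElementalFormula,
    ValidationError,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    round_half_up,
)

logger = logging.getLogger("dmpkit.metid")

__all__ = [
    "OXYGEN_MASS",
    "DAPORINAD",
    "RULE_CATEGORIES",
    "BiotransformRule",
    "DEFAULT_RULES",
    "default_rules",
    "rules_by_name",
    "TransformationChain",
    "Peak",
    "ProductIonSpectrum",
    "FragmentTemplateEntry",
    "FragmentTemplate",
    "default_fragment_template",
    "fragment_ion_mz",
    "MetaboliteAnnotation",
    "enumerate_chains",
    "annotate_peaks",
    "localize",
    "detect_n_oxide",
    "build_report",
]

OXYGEN_MASS = MONOISOTOPIC_MASSES["O"]

#: Parent drug scaffold: Daporinad (FK866), C24H29N3O2.
DAPORINAD = parse_formula("C24H29N3O2")

RULE_CATEGORIES = ("hydrolytic", "oxidative", "reductive", "desaturative")

AMINE_SIDE = "amine_side"
ACYL_SIDE = "acyl_side"
BOTH = "both"
UNLOCALIZED = "unlocalized"


@dataclass(frozen=True, eq=False)
class BiotransformRule:
    """One phase-I biotransformation expressed as a signed element delta."""

    name: str
    display: str
    delta: Mapping[str, int]
    max_multiplicity: int = 1
    category: str = "oxidative"

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", dict(self.delta))
        if not any(self.delta.values()):
            raise ValidationError(f"rule {self.name!r} has a zero delta")
        if self.max_multiplicity < 1:
            raise ValidationError(
                f"rule {self.name!r} max_multiplicity must be >= 1"
            )
        if self.category not in RULE_CATEGORIES:
            raise ValidationError(
                f"rule {self.name!r} category must be one of {RULE_CATEGORIES}"
            )

    @property
    def delta_mass(self) -> float:
        """Monoisotopic mass change of one application of this rule (Da)."""
        return sum(n * MONOISOTOPIC_MASSES[el] for el, n in self.delta.items())


def default_rules() -> tuple[BiotransformRule, ...]:
    """The phase-I rule set observed for Daporinad.

    The two composite hydrolysis rules are net transformations of the whole
    scaffold (amide cleavage retaining the amine side, followed by oxidation
    of the freed amine to a carboxylic acid or a hydroxyl).
    """
    return (
        BiotransformRule("oxidation", "Oxidation", {"O": 1}, 3, "oxidative"),
        BiotransformRule(
            "desaturation", "Desaturation", {"H": -2}, 2, "desaturative"
        ),
        BiotransformRule("saturation", "Saturation", {"H": 2}, 1, "reductive"),
        BiotransformRule(
            "amide_hydrolysis",
            "Amide hydrolysis",
            {"C": -8, "H": -5, "N": -1, "O": -1},
            1,
            "hydrolytic",
        ),
        BiotransformRule(
            "hydrolysis_then_carboxylation",
            "Amide hydrolysis followed by carboxylation",
            {"C": -8, "H": -8, "N": -2, "O": 1},
            1,
            "hydrolytic",
        ),
        BiotransformRule(
            "hydrolysis_then_hydroxylation",
            "Amide hydrolysis followed by hydroxylation",
            {"C": -8, "H": -6, "N": -2},
            1,
            "hydrolytic",
        ),
    )


DEFAULT_RULES = default_rules()


def rules_by_name(
    rules: Iterable[BiotransformRule] = DEFAULT_RULES,
) -> dict[str, BiotransformRule]:
    return {rule.name: rule for rule in rules}


_MULT_PREFIX = {1: "", 2: "Di-", 3: "Tri-", 4: "Tetra-"}


@dataclass(frozen=True, eq=False)
class TransformationChain:
    """A multiset of rule applications with its net formula and [M+H]+ m/z."""

    parent: ElementalFormula
    steps: tuple[tuple[BiotransformRule, int], ...]
    net_formula: ElementalFormula
    theoretical_mz: float

    @classmethod
    def from_steps(
        cls,
        parent: ElementalFormula,
        steps: Mapping[BiotransformRule, int],
    ) -> "TransformationChain":
        items = tuple(
            sorted(
                ((rule, int(count)) for rule, count in dict(steps).items() if count),
                key=lambda rc: rc[0].name,
            )
        )
        for rule, count in items:
            if count < 0:
                raise ChainError(f"negative step count for rule {rule.name!r}")
            if count > rule.max_multiplicity:
                raise ChainError(
                    f"rule {rule.name!r} applied {count}x exceeds its "
                    f"multiplicity limit {rule.max_multiplicity}"
                )
        delta: dict[str, int] = {}
        for rule, count in items:
            for element, change in rule.delta.items():
                delta[element] = delta.get(element, 0) + change * count
        from .chem import formula_shift  # local import avoids a cycle at build

        net = formula_shift(parent, delta)
        return cls(parent, items, net, adduct_mz(net))

    @property
    def n_steps(self) -> int:
        return sum(count for _, count in self.steps)

    @property
    def net_delta(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for rule, count in self.steps:
            for element, change in rule.delta.items():
                delta[element] = delta.get(element, 0) + change * count
        return {el: n for el, n in delta.items() if n}

    @property
    def delta_key(self) -> tuple[tuple[str, int], ...]:
        """Hashable net-delta key used to deduplicate equivalent chains."""
        return tuple(sorted(self.net_delta.items()))

    @property
    def name(self) -> str:
        """Table-style transformation name, e.g. ``Desaturation + Oxidation``."""
        if not self.steps:
            return "Parent"
        parts = []
        for rule, count in self.steps:
            if count == 1:
                parts.append(rule.display)
            else:
                prefix = _MULT_PREFIX.get(count, f"{count}x ")
                parts.append(prefix + rule.display[0].lower() + rule.display[1:])
        return " + ".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TransformationChain({self.name!r}, {self.net_formula}, "
            f"m/z {self.theoretical_mz:.4f})"
        )


@dataclass(frozen=True)
class Peak:
    """One centroided chromatographic peak."""

    condition: str
    rt: float
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValidationError(f"retention time must be >= 0, got {self.rt}")
        if self.mz <= 0:
            raise ValidationError(f"m/z must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(
                f"intensity must be >= 0, got {self.intensity}"
            )


@dataclass(frozen=True)
class ProductIonSpectrum:
    """An MS2 spectrum: precursor m/z and (fragment m/z, intensity) pairs."""

    precursor_mz: float
    fragments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fragments", tuple((float(m), float(i)) for m, i in self.fragments)
        )
        for mz, _ in self.fragments:
            if mz >= self.precursor_mz + 0.5:
                raise ValidationError(
                    f"fragment m/z {mz} exceeds precursor {self.precursor_mz}"
                )


@dataclass(frozen=True)
class FragmentTemplateEntry:
    formula: ElementalFormula
    moiety: str  # amine_side | acyl_side
    relation: str  # primary | -NH3 | -CO | -HCN | secondary


@dataclass(frozen=True)
class FragmentTemplate:
    """Diagnostic product ions of the parent, tagged by moiety."""

    entries: tuple[FragmentTemplateEntry, ...]


def fragment_ion_mz(formula: ElementalFormula) -> float:
    """m/z of a singly protonated fragment ion."""
    return monoisotopic_mass(formula) + PROTON_MASS


def default_fragment_template() -> FragmentTemplate:
    """Daporinad's six diagnostic fragments (amide-bond cleavage series).

    Amine side: m/z 261.1961 (primary), 244.1696 (-NH3), 140.1434 (secondary).
    Acyl side: m/z 132.0444 (primary), 105.0335 (-HCN), 104.0495 (-CO).
    """
    return FragmentTemplate(
        entries=(
            FragmentTemplateEntry(parse_formula("C16H24N2O"), AMINE_SIDE, "primary"),
            FragmentTemplateEntry(parse_formula("C16H21NO"), AMINE_SIDE, "-NH3"),
            FragmentTemplateEntry(parse_formula("C9H17N"), AMINE_SIDE, "secondary"),
            FragmentTemplateEntry(parse_formula("C8H5NO"), ACYL_SIDE, "primary"),
            FragmentTemplateEntry(parse_formula("C7H4O"), ACYL_SIDE, "-HCN"),
            FragmentTemplateEntry(parse_formula("C7H5N"), ACYL_SIDE, "-CO"),
        )
    )


@dataclass
class MetaboliteAnnotation:
    """A peak joined to a candidate chain, with localization/N-oxide state."""

    peak: Peak
    chain: TransformationChain
    ppm: float
    rank: int = 0
    localization: str = "untested"
    n_oxide: str = "untested"
    label: str | None = None


def enumerate_chains(
    parent: ElementalFormula,
    rules: Sequence[BiotransformRule] | None = None,
    max_steps: int = 3,
    include_parent: bool = True,
) -> list[TransformationChain]:
    """All valid chains of at most ``max_steps`` rule applications.

    Chains whose net formula would go negative are silently pruned; chains
    with identical net element deltas are deduplicated keeping the fewest
    steps (so e.g. saturation + desaturation collapses onto the parent).
    Result is sorted by theoretical m/z.
    """
    if max_steps < 1:
        raise ValidationError(f"max_steps must be >= 1, got {max_steps}")
    rule_tuple = DEFAULT_RULES if rules is None else tuple(rules)
    if not rule_tuple:
        return []
    ranges = [range(min(r.max_multiplicity, max_steps) + 1) for r in rule_tuple]
    best: dict[tuple, TransformationChain] = {}
    for combo in itertools.product(*ranges):
        total = sum(combo)
        if total > max_steps:
            continue
        if total == 0 and not include_parent:
            continue
        try:
            chain = TransformationChain.from_steps(
                parent, dict(zip(rule_tuple, combo))
            )
        except ChainError:
            continue
        key = chain.delta_key
        prev = best.get(key)
        if prev is None or chain.n_steps < prev.n_steps:
            best[key] = chain
    return sorted(best.values(), key=lambda c: (c.theoretical_mz, c.n_steps))


def annotate_peaks(
    peaks: Sequence[Peak],
    chains: Sequence[TransformationChain],
    tol_ppm: float = 5.0,
) -> tuple[list[MetaboliteAnnotation], list[Peak]]:
    """Match peaks to candidate chains within a ppm window.

    Every chain within tolerance becomes an annotation; candidates for a
    peak are ranked by (fewer total steps, then smaller \\|ppm\\|), rank 0
    being the preferred assignment.  Peaks matching nothing are returned in
    the second list.
    """
    if tol_ppm <= 0:
        raise ValidationError(f"tol_ppm must be > 0, got {tol_ppm}")
    annotations: list[MetaboliteAnnotation] = []
    unmatched: list[Peak] = []
    for peak in peaks:
        candidates = []
        for chain in chains:
            err = ppm_error(peak.mz, chain.theoretical_mz)
            if abs(err) <= tol_ppm:
                candidates.append((chain, err))
        if not candidates:
            unmatched.append(peak)
            continue
        candidates.sort(key=lambda item: (item[0].n_steps, abs(item[1])))
        annotations.extend(
            MetaboliteAnnotation(peak=peak, chain=chain, ppm=err, rank=rank)
            for rank, (chain, err) in enumerate(candidates)
        )
    return annotations, unmatched


def localize(
    annotation: MetaboliteAnnotation,
    spectrum: ProductIonSpectrum | None,
    template: FragmentTemplate | None = None,
    frag_tol_mda: float = 10.0,
) -> str:
    """Assign the chain's steps to moieties from product-ion shifts.

    Brute-forces every partition of the chain's steps between the two
    moieties; for each partition each template fragment's m/z is predicted
    shifted by the mass of the steps assigned to its moiety, and the score
    is the number of predicted fragments observed within ``frag_tol_mda``.
    The best partition's moiety pattern is returned; ties between
    conflicting patterns or a best score below two matched fragments yield
    ``unlocalized``.
    """
    if frag_tol_mda <= 0:
        raise ValidationError(f"frag_tol_mda must be > 0, got {frag_tol_mda}")
    if spectrum is None or not spectrum.fragments:
        logger.warning(
            "empty product-ion spectrum for peak at m/z %.4f; unlocalized",
            annotation.peak.mz,
        )
        annotation.localization = UNLOCALIZED
        return UNLOCALIZED
    template = template or default_fragment_template()
    tol = frag_tol_mda * 1e-3
    observed = [mz for mz, _ in spectrum.fragments]
    rules = [rule for rule, _ in annotation.chain.steps]
    counts = [count for _, count in annotation.chain.steps]
    total = sum(counts)
    best_score = -1
    best_patterns: set[str] = set()
    for amine_counts in itertools.product(*(range(c + 1) for c in counts)):
        amine_mass = sum(
            a * rule.delta_mass for a, rule in zip(amine_counts, rules)
        )
        acyl_mass = sum(
            (c - a) * rule.delta_mass
            for a, c, rule in zip(amine_counts, counts, rules)
        )
        n_amine = sum(amine_counts)
        n_acyl = total - n_amine
        score = 0
        for entry in template.entries:
            shift = amine_mass if entry.moiety == AMINE_SIDE else acyl_mass
            predicted = fragment_ion_mz(entry.formula) + shift
            if any(abs(mz - predicted) <= tol for mz in observed):
                score += 1
        if n_amine and n_acyl:
            pattern = BOTH
        elif n_amine:
            pattern = AMINE_SIDE
        elif n_acyl:
            pattern = ACYL_SIDE
        else:
            pattern = UNLOCALIZED
        if score > best_score:
            best_score = score
            best_patterns = {pattern}
        elif score == best_score:
            best_patterns.add(pattern)
    if best_score < 2 or len(best_patterns) != 1:
        result = UNLOCALIZED
    else:
        result = next(iter(best_patterns))
    annotation.localization = result
    return result


def _peaks_near(
    peaks: Sequence[Peak],
    mz: float,
    rt: float | None,
    mz_tol_ppm: float,
    rt_tol: float,
) -> list[Peak]:
    out = []
    for peak in peaks:
        if abs(ppm_error(peak.mz, mz)) > mz_tol_ppm:
            continue
        if rt is not None and abs(peak.rt - rt) > rt_tol:
            continue
        out.append(peak)
    return out


def detect_n_oxide(
    control: Sequence[Peak],
    treated: Sequence[Peak],
    annotations: Sequence[MetaboliteAnnotation],
    drop_fraction: float = 0.8,
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.2,
    parent_rt: float | None = None,
) -> tuple[list[MetaboliteAnnotation], list[str]]:
    """Flag N-oxides from a paired control / TiCl3-treated experiment.

    An annotation whose chain contains at least one oxidative step is
    flagged ``yes`` iff (a) its peak loses at least ``drop_fraction`` of its
    control intensity under treatment and (b) intensity at one oxygen less
    (m/z - 15.9949) gains under treatment, searched in the annotation's own
    rt neighbourhood and at the parent's rt (TiCl3 reduction regenerates the
    oxygen-free partner).  Non-oxidative annotations are left ``untested``.
    """
    if not 0 < drop_fraction <= 1:
        raise ValidationError(
            f"drop_fraction must be in (0, 1], got {drop_fraction}"
        )
    warnings: list[str] = []
    annotations = list(annotations)
    if parent_rt is None:
        for ann in annotations:
            if ann.chain.n_steps == 0:
                parent_rt = ann.peak.rt
                break
    for ann in annotations:
        oxidative = any(
            rule.category == "oxidative" and count > 0
            for rule, count in ann.chain.steps
        )
        if not oxidative:
            ann.n_oxide = "untested"
            continue
        ctrl_matches = _peaks_near(
            control, ann.peak.mz, ann.peak.rt, mz_tol_ppm, rt_tol
        )
        if not ctrl_matches:
            ann.n_oxide = "untested"
            message = (
                f"annotation at m/z {ann.peak.mz:.4f}, rt {ann.peak.rt:.2f} "
                f"has no matching control peak; N-oxide test skipped"
            )
            warnings.append(message)
            logger.warning(message)
            continue
        ctrl_intensity = sum(p.intensity for p in ctrl_matches)
        trt_intensity = sum(
            p.intensity
            for p in _peaks_near(treated, ann.peak.mz, ann.peak.rt, mz_tol_ppm, rt_tol)
        )
        dropped = trt_intensity <= (1.0 - drop_fraction) * ctrl_intensity
        partner_mz = ann.chain.theoretical_mz - OXYGEN_MASS
        rt_windows = [ann.peak.rt]
        if parent_rt is not None:
            rt_windows.append(parent_rt)
        gained = False
        for rt_ref in rt_windows:
            ctrl_partner = sum(
                p.intensity
                for p in _peaks_near(control, partner_mz, rt_ref, mz_tol_ppm, rt_tol)
            )
            trt_partner = sum(
                p.intensity
                for p in _peaks_near(treated, partner_mz, rt_ref, mz_tol_ppm, rt_tol)
            )
            if trt_partner > ctrl_partner:
                gained = True
                break
        ann.n_oxide = "yes" if (dropped and gained) else "no"
    return annotations, warnings


def build_report(
    annotations: Sequence[MetaboliteAnnotation],
    conditions: Sequence[str] | None = None,
    rt_tol: float = 0.2,
) -> pd.DataFrame:
    """Tabulate rank-0 annotations as a metabolite characterization table.

    Annotations sharing a net transformation and eluting within ``rt_tol``
    minutes collapse onto one row; presence flags (``O`` / ``-``) are emitted
    per condition label.  Rows are sorted by retention time and, when no
    labels were supplied, numbered M1, M2, ... in elution order with the
    unmodified parent labelled ``Parent``.  Duplicate labels are suffixed
    deterministically (``_2``, ``_3``, ...).
    """
    best = sorted(
        (a for a in annotations if a.rank == 0),
        key=lambda a: (a.peak.rt, a.peak.mz),
    )
    clusters: list[dict] = []
    for ann in best:
        for cluster in clusters:
            if (
                cluster["key"] == ann.chain.delta_key
                and abs(ann.peak.rt - cluster["rt"]) <= rt_tol
            ):
                cluster["members"].append(ann)
                break
        else:
            clusters.append(
                {"key": ann.chain.delta_key, "rt": ann.peak.rt, "members": [ann]}
            )
    clusters.sort(key=lambda c: c["rt"])
    if conditions is None:
        seen: list[str] = []
        for cluster in clusters:
            for member in cluster["members"]:
                if member.peak.condition not in seen:
                    seen.append(member.peak.condition)
        conditions = seen
    columns = [
        "label",
        "transformation",
        "mz",
        "formula",
        "rt_min",
        "ppm",
        "localization",
        "n_oxide",
        *conditions,
    ]
    rows = []
    metabolite_counter = 0
    label_counts: dict[str, int] = {}
    for cluster in clusters:
        lead = cluster["members"][0]
        label = next(
            (m.label for m in cluster["members"] if m.label is not None), None
        )
        if label is None:
            if lead.chain.n_steps == 0:
                label = "Parent"
            else:
                metabolite_counter += 1
                label = f"M{metabolite_counter}"
        label_counts[label] = label_counts.get(label, 0) + 1
        if label_counts[label] > 1:
            label = f"{label}_{label_counts[label]}"
        present = {m.peak.condition for m in cluster["members"]}
        row = {
            "label": label,
            "transformation": lead.chain.name,
            "mz": round_half_up(lead.chain.theoretical_mz, 4),
            "formula": lead.chain.net_formula.to_string(),
            "rt_min": cluster["rt"],
            "ppm": lead.ppm,
            "localization": lead.localization,
            "n_oxide": lead.n_oxide,
        }
        for condition in conditions:
            row[condition] = "O" if condition in present else "-"
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
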