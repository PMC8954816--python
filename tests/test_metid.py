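"""Chain enumeration, annotation, localization and the TiCl3 differential."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmpkit import (
    DAPORINAD,
    GeneratorConfig,
    MetaboliteAnnotation,
    Peak,
    ProductIonSpectrum,
    ValidationError,
    annotate_peaks,
    build_report,
    default_fragment_template,
    detect_n_oxide,
    enumerate_chains,
    expected_localization,
    localize,
    parse_formula,
    ppm_error,
    round_half_up,
    rules_by_name,
)
from dmpkit.metid import TransformationChain, fragment_ion_mz
from dmpkit.synth import sim_peak_tables


RULES = rules_by_name()


def make_chain(**steps):
    return TransformationChain.from_steps(
        DAPORINAD, {RULES[name]: count for name, count in steps.items()}
    )


def make_annotation(chain, mz=None, rt=10.0):
    mz = chain.theoretical_mz if mz is None else mz
    peak = Peak("control", rt, mz, 1.0e5)
    return MetaboliteAnnotation(peak=peak, chain=chain, ppm=0.0)


class TestEnumerateChains:
    def test_oxidation_series(self):
        chains = enumerate_chains(
            DAPORINAD, rules=[RULES["oxidation"]], max_steps=3
        )
        mzs = sorted(round_half_up(c.theoretical_mz) for c in chains if c.n_steps)
        assert mzs == [408.2282, 424.2231, 440.2180]

    def test_desaturation_plus_oxidation(self):
        chains = enumerate_chains(
            DAPORINAD,
            rules=[RULES["desaturation"], RULES["oxidation"]],
            max_steps=2,
        )
        by_formula = {c.net_formula.to_string(): c for c in chains}
        assert round_half_up(by_formula["C24H27N3O3"].theoretical_mz) == 406.2125

    def test_invalid_max_steps_and_empty_rules(self):
        with pytest.raises(ValidationError):
            enumerate_chains(DAPORINAD, max_steps=0)
        assert enumerate_chains(DAPORINAD, rules=[], max_steps=3) == []

    def test_cancelling_steps_deduplicate_onto_parent(self):
        chains = enumerate_chains(
            DAPORINAD,
            rules=[RULES["saturation"], RULES["desaturation"]],
            max_steps=2,
        )
        parents = [c for c in chains if not c.net_delta]
        assert len(parents) == 1 and parents[0].n_steps == 0

    def test_sorted_by_mz(self, default_chains):
        mzs = [c.theoretical_mz for c in default_chains]
        assert mzs == sorted(mzs)

    def test_multiplicity_limit_respected(self, default_chains):
        for chain in default_chains:
            for rule, count in chain.steps:
                assert count <= rule.max_multiplicity


class TestAnnotatePeaks:
    def test_parent_peak_matches_parent_chain(self, default_chains):
        peak = Peak("c", 22.31, 392.2333, 1.0)
        annotations, unmatched = annotate_peaks([peak], default_chains)
        assert not unmatched
        best = annotations[0]
        assert best.chain.n_steps == 0
        assert best.ppm == pytest.approx(0.0, abs=0.2)

    def test_mono_oxidation_peak(self, default_chains):
        peak = Peak("c", 11.99, 408.2282, 1.0)
        annotations, _ = annotate_peaks([peak], default_chains)
        assert annotations[0].chain.name == "Oxidation"

    def test_far_peak_unannotated(self, default_chains):
        peak = Peak("c", 1.0, 500.0, 1.0)
        annotations, unmatched = annotate_peaks([peak], default_chains)
        assert annotations == [] and unmatched == [peak]

    def test_empty_input(self, default_chains):
        assert annotate_peaks([], default_chains) == ([], [])

    def test_all_published_metabolites_assigned(
        self, reference, reference_peaks, default_chains
    ):
        annotations, unmatched = annotate_peaks(
            reference_peaks, default_chains, tol_ppm=5.0
        )
        assert not unmatched
        best = {a.peak.rt: a for a in annotations if a.rank == 0}
        for entry in reference:
            assert best[entry.rt].chain.name == entry.transformation, entry.label

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=0.0, max_value=1.0))
    def test_shrinking_tolerance_never_adds_annotations(self, tol, shrink):
        chains = enumerate_chains(DAPORINAD, max_steps=2)
        peaks = [
            Peak("c", 1.0, 392.2333 * (1 + 3e-6), 1.0),
            Peak("c", 2.0, 408.2290, 1.0),
        ]
        wide, _ = annotate_peaks(peaks, chains, tol_ppm=tol)
        narrow, _ = annotate_peaks(peaks, chains, tol_ppm=tol * shrink + 1e-9)
        wide_keys = {(a.peak.rt, a.chain.delta_key) for a in wide}
        narrow_keys = {(a.peak.rt, a.chain.delta_key) for a in narrow}
        assert narrow_keys <= wide_keys


def spectrum_from(mzs, precursor):
    return ProductIonSpectrum(precursor, tuple((m, 100.0) for m in mzs))


class TestLocalize:
    """Fragment-shift patterns published for the Daporinad metabolites."""

    def test_amine_side_pattern(self):
        # desaturation+oxidation with all amine-side fragments shifted +14
        ann = make_annotation(make_chain(desaturation=1, oxidation=1))
        spectrum = spectrum_from(
            [275.18, 258.15, 154.12, 132.04, 105.03, 104.05], 406.21
        )
        assert localize(ann, spectrum) == "amine_side"

    def test_acyl_side_pattern(self):
        # mono-oxidation with acyl-side fragments shifted +16
        ann = make_annotation(make_chain(oxidation=1))
        spectrum = spectrum_from(
            [261.20, 244.17, 140.14, 148.04, 120.04, 105.03], 408.23
        )
        assert localize(ann, spectrum) == "acyl_side"

    def test_both_sides_pattern(self):
        # di-oxidation split across both moieties
        ann = make_annotation(make_chain(oxidation=2))
        spectrum = spectrum_from(
            [277.19, 156.14, 148.04, 120.04, 105.03], 424.22
        )
        assert localize(ann, spectrum) == "both"

    def test_empty_spectrum_unlocalized(self):
        ann = make_annotation(make_chain(oxidation=1))
        assert localize(ann, spectrum_from([], 408.23)) == "unlocalized"
        assert ann.localization == "unlocalized"

    def test_agrees_with_exhaustive_oracle(self, reference):
        """Brute-force oracle: enumerate every per-step moiety assignment
        (not count partitions) and score fragments by simple loops."""
        template = default_fragment_template()

        def oracle(chain, spectrum, tol=0.010):
            unit_steps = []
            for rule, count in chain.steps:
                unit_steps.extend([rule] * count)
            observed = [m for m, _ in spectrum.fragments]
            best_score, best_patterns = -1, set()
            for assignment in itertools.product(
                ["amine_side", "acyl_side"], repeat=len(unit_steps)
            ):
                shifts = {"amine_side": 0.0, "acyl_side": 0.0}
                for rule, side in zip(unit_steps, assignment):
                    shifts[side] += rule.delta_mass
                score = 0
                for entry in template.entries:
                    predicted = fragment_ion_mz(entry.formula) + shifts[entry.moiety]
                    if any(abs(m - predicted) <= tol for m in observed):
                        score += 1
                sides = set(assignment)
                pattern = sides.pop() if len(sides) == 1 else "both"
                if not unit_steps:
                    pattern = "unlocalized"
                if score > best_score:
                    best_score, best_patterns = score, {pattern}
                elif score == best_score:
                    best_patterns.add(pattern)
            if best_score < 2 or len(best_patterns) != 1:
                return "unlocalized"
            return best_patterns.pop()

        tables = sim_peak_tables(GeneratorConfig(seed=5))
        for entry in tables.ground_truth:
            if any(name.startswith(("amide", "hydrolysis")) for name in entry.steps):
                continue
            chain = entry.chain()
            if chain.n_steps == 0 or chain.n_steps > 3:
                continue
            spectrum = tables.spectra[entry.label]
            ann = make_annotation(chain, rt=entry.rt)
            assert localize(ann, spectrum) == oracle(chain, spectrum), entry.label


class TestDetectNOxide:
    def test_synthetic_round_trip_flags_exactly_six(self, config, default_chains):
        tables = sim_peak_tables(config)
        annotations, _ = annotate_peaks(tables.control, default_chains)
        best = [a for a in annotations if a.rank == 0]
        detect_n_oxide(tables.control, tables.treated, best)
        gt = {g.rt: g.label for g in tables.ground_truth}
        flagged = sorted(gt[a.peak.rt] for a in best if a.n_oxide == "yes")
        assert flagged == ["M10", "M11", "M18", "M22", "M25", "M6"]

    def test_identical_lists_give_zero_flags(self, config, default_chains):
        tables = sim_peak_tables(config)
        annotations, _ = annotate_peaks(tables.control, default_chains)
        best = [a for a in annotations if a.rank == 0]
        detect_n_oxide(tables.control, tables.control, best, drop_fraction=0.5)
        assert all(a.n_oxide != "yes" for a in best)

    def test_random_subset_ground_truth_recovered(self, reference, default_chains):
        """A shuffled 20-species subset with known truth round-trips."""
        import numpy as np

        rng = np.random.default_rng(17)
        metabolites = [r for r in reference if r.label != "Parent"]
        subset = [metabolites[i] for i in rng.permutation(len(metabolites))[:19]]
        parent = next(r for r in reference if r.label == "Parent")
        truth = [parent] + subset
        tables = sim_peak_tables(
            GeneratorConfig(seed=23), ground_truth=truth
        )
        annotations, _ = annotate_peaks(tables.control, default_chains)
        best = [a for a in annotations if a.rank == 0]
        detect_n_oxide(tables.control, tables.treated, best, drop_fraction=0.8)
        gt = {g.rt: g for g in tables.ground_truth}
        for ann in best:
            entry = gt[ann.peak.rt]
            if entry.n_oxide in ("yes", "no"):
                oxidative = "oxidation" in entry.steps
                expected = entry.n_oxide if oxidative else "untested"
                assert ann.n_oxide == expected, entry.label

    def test_missing_control_peak_is_untested_with_warning(self, default_chains):
        peak = Peak("control", 11.99, 408.2282, 1.0e5)
        annotations, _ = annotate_peaks([peak], default_chains)
        best = [a for a in annotations if a.rank == 0]
        _, warnings = detect_n_oxide([], [], best)
        assert best[0].n_oxide == "untested"
        assert len(warnings) == 1


class TestBuildReport:
    def test_published_fixture_layout(self, reference_peaks, default_chains):
        annotations, _ = annotate_peaks(reference_peaks, default_chains)
        report = build_report(annotations)
        assert len(report) == 26
        assert list(report["rt_min"]) == sorted(report["rt_min"])
        labels = list(report["label"])
        assert labels.index("M20") < labels.index("Parent") < labels.index("M21")
        assert report.loc[report["label"] == "Parent", "rt_min"].iloc[0] == 22.31
        assert labels == [f"M{i}" for i in range(1, 21)] + ["Parent"] + [
            f"M{i}" for i in range(21, 26)
        ]

    def test_empty_input_gives_header_only(self):
        report = build_report([])
        assert report.empty
        assert list(report.columns)[:2] == ["label", "transformation"]

    def test_duplicate_labels_suffixed_deterministically(self, default_chains):
        peaks = [Peak("c", 11.99, 408.2282, 1.0), Peak("c", 14.00, 408.2282, 1.0)]
        annotations, _ = annotate_peaks(peaks, default_chains)
        for ann in annotations:
            ann.label = "M4"
        report = build_report(annotations)
        assert list(report["label"]) == ["M4", "M4_2"]

    def test_presence_flags_per_condition(self, default_chains):
        peaks = [
            Peak("mouse_liver_microsome", 11.99, 408.2282, 1.0),
            Peak("mouse_plasma", 11.99, 408.2282, 1.0),
        ]
        annotations, _ = annotate_peaks(peaks, default_chains)
        report = build_report(
            annotations,
            conditions=["mouse_liver_microsome", "human_liver_microsome", "mouse_plasma"],
        )
        assert len(report) == 1
        row = report.iloc[0]
        assert row["mouse_liver_microsome"] == "O"
        assert row["human_liver_microsome"] == "-"
        assert row["mouse_plasma"] == "O"


def test_nominal_amide_hydrolysis_loss_is_131():
    """The amide-cleavage metabolite sits a nominal 131 u below the parent."""
    from dmpkit import monoisotopic_mass

    chain = make_chain(amide_hydrolysis=1)
    loss = monoisotopic_mass(DAPORINAD) - monoisotopic_mass(chain.net_formula)
    assert round(loss) == 131
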