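"""Delta-mass inference: localization, refinement, identification, compositions."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from h1ptm.chem_core import (
    MONOISOTOPIC_ELEMENT_MASS,
    PROTON_MASS,
    ElementCounts,
    peptide_monoisotopic_mass,
)
from h1ptm.digestion import PeptideSpan, ProteinRecord
from h1ptm.fragmentation import FragmentIon, ModifiedPeptide, theoretical_fragments
from h1ptm.spectra_match import PeakMatch, Spectrum, match_peaks
from h1ptm.ptm_discovery import (
    CompositionCandidate,
    DeltaObservation,
    FilterConfig,
    classify_site,
    enumerate_compositions,
    estimate_mod_mass,
    localize_shift,
    match_known_ptms,
    precursor_delta,
    suggest_mod_combinations,
)


def span_of(sequence, start=2):
    return PeptideSpan(protein_id="P", start=start,
                       end=start + len(sequence) - 1,
                       sequence=sequence, protease="trypsin")


def spectrum_for(sequence, placements=(), registry=None, charge=2, title="s"):
    """Noiseless spectrum synthesized from the peptide's own ladder."""
    placed = tuple((pos, registry[name]) for pos, name in placements)
    mp = ModifiedPeptide(span=span_of(sequence), placements=placed)
    ions = theoretical_fragments(mp, charges=(1,), include_internal=True,
                                 include_losses=False)
    neutral = mp.neutral_mass()
    return Spectrum(title=title,
                    precursor_mz=(neutral + charge * PROTON_MASS) / charge,
                    precursor_charge=charge,
                    peaks=[(f.mz, 1.0) for f in ions])


class TestPrecursorDelta:
    def test_unmodified_spectrum_gives_zero(self):
        sp = spectrum_for("SAMPLEK")
        assert precursor_delta(sp, span_of("SAMPLEK")) == pytest.approx(
            0.0, abs=1e-6)

    def test_planted_phospho(self, registry):
        sp = spectrum_for("SATAKR", [(1, "phospho")], registry)
        assert precursor_delta(sp, span_of("SATAKR")) == pytest.approx(
            79.96633, abs=1e-4)

    def test_planted_kv_adduct(self, registry):
        sp = spectrum_for("SATAKR", [(5, "KV adduct")], registry)
        assert precursor_delta(sp, span_of("SATAKR")) == pytest.approx(
            227.1634, abs=1e-3)


def bracket_matches(sequence, delta, b_states=None, y_states=None):
    """Hand-built PeakMatch list: states map ladder index -> shifted?"""
    matches = []
    for series, states in (("b", b_states or {}), ("y", y_states or {})):
        for pos, shifted in states.items():
            mz = 100.0 + 10 * pos  # placeholder; localization ignores mz
            shift = delta if shifted else 0.0
            frag = FragmentIon(series=series, pos=pos, charge=1,
                               mz=mz + shift, shift=shift)
            matches.append(PeakMatch(fragment=frag, observed_mz=frag.mz,
                                     error_ppm=0.0, intensity=1.0))
    return matches


class TestLocalizeShift:
    def test_full_ladder_pins_single_site(self):
        # phospho at position 3 of a 6-mer: b1,b2 unshifted; b3.. shifted
        matches = bracket_matches(
            "SATAKR", 79.966,
            b_states={1: False, 2: False, 3: True, 4: True, 5: True},
            y_states={1: False, 2: False, 3: False, 4: True, 5: True})
        loc = localize_shift(79.966, matches, 6)
        assert loc.interval == (3, 3)
        assert loc.site_specific

    def test_only_terminal_ions_leave_wide_interval(self):
        matches = bracket_matches("SATAKR", 79.966,
                                  b_states={1: False}, y_states={1: False})
        loc = localize_shift(79.966, matches, 6)
        assert loc.interval == (2, 5)
        assert not loc.site_specific

    def test_no_informative_ions_returns_full_interval(self):
        loc = localize_shift(79.966, [], 6)
        assert loc.interval == (1, 6)
        assert not loc.site_specific

    def test_contradictory_ladder_flagged_not_raised(self):
        matches = bracket_matches("SATAKR", 79.966, b_states={2: False})
        frag = FragmentIon(series="b", pos=2, charge=1, mz=120.0 + 79.966,
                           shift=79.966)
        matches.append(PeakMatch(fragment=frag, observed_mz=frag.mz,
                                 error_ppm=0.0, intensity=1.0))
        loc = localize_shift(79.966, matches, 6)
        assert loc.ambiguous
        assert loc.contradicted == 1
        assert not loc.site_specific

    def test_smallest_shifted_y_gives_tightest_bound(self):
        # shifted y3 places the site in the last 3 residues even when larger
        # shifted y ions are also present
        matches = bracket_matches(
            "SATAKR", 68.0, y_states={3: True, 5: True, 2: False})
        loc = localize_shift(68.0, matches, 6)
        assert loc.interval == (4, 4)

    def test_terminal_site_accepted_with_one_flank(self):
        # all b ions shifted from b1: site on residue 1, N-terminal bracket
        matches = bracket_matches("SATAKR", 42.0,
                                  b_states={1: True, 2: True},
                                  y_states={1: False})
        loc = localize_shift(42.0, matches, 6)
        assert loc.interval == (1, 1)
        assert loc.site_specific

    def test_internal_ions_shrink_interval(self):
        matches = bracket_matches("SATAKR", 68.0, b_states={1: False})
        frag = FragmentIon(series="internal", pos=(3, 4), charge=1,
                           mz=300.0, shift=68.0)
        matches.append(PeakMatch(fragment=frag, observed_mz=300.0,
                                 error_ppm=0.0, intensity=1.0))
        loc = localize_shift(68.0, matches, 6)
        assert loc.interval == (3, 4)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(3, 20),
        data=st.data(),
    )
    def test_full_singly_charged_ladder_recovers_planted_site(self, n, data):
        site = data.draw(st.integers(1, n))
        b_states = {i: i >= site for i in range(1, n)}
        y_states = {k: k >= n - site + 1 for k in range(1, n)}
        matches = bracket_matches("X" * n, 79.966, b_states, y_states)
        loc = localize_shift(79.966, matches, n)
        assert loc.interval == (site, site)
        assert loc.site_specific


class TestEstimateModMass:
    def make_obs(self, shifts):
        return DeltaObservation(peptide=span_of("SATAKR"), spectrum_title="s",
                                precursor_delta=109.05, ion_shifts=shifts)

    def test_single_ion(self):
        mass, n = estimate_mod_mass(self.make_obs([(300.0, 109.05234)]))
        assert mass == pytest.approx(109.05234, abs=1e-9)
        assert n == 1

    def test_mean_of_identical_shifts(self):
        obs = self.make_obs([(200.0, 42.01), (300.0, 42.01),
                             (400.0, 42.01), (500.0, 42.01)])
        mass, n = estimate_mod_mass(obs)
        assert mass == pytest.approx(42.01)
        assert n == 4

    def test_low_mz_preference_excludes_high_mz_outlier(self):
        obs = self.make_obs([(200.0, 109.0524), (300.0, 109.0524),
                             (400.0, 109.0524), (1500.0, 109.10)])
        mass, n = estimate_mod_mass(obs, mz_cutoff=800.0)
        assert mass == pytest.approx(109.0524, abs=1e-6)
        assert n == 3

    def test_fallback_to_all_ions_when_none_qualify(self):
        obs = self.make_obs([(1200.0, 80.0), (1500.0, 80.2)])
        mass, n = estimate_mod_mass(obs, mz_cutoff=800.0)
        assert mass == pytest.approx(80.1)
        assert n == 2

    def test_permutation_invariance(self):
        shifts = [(200.0, 42.011), (350.0, 42.009), (500.0, 42.010)]
        for perm in itertools.permutations(shifts):
            mass, _ = estimate_mod_mass(self.make_obs(list(perm)))
            assert mass == pytest.approx(42.010, abs=1e-6)

    def test_empty_shifts_error(self):
        with pytest.raises(ValueError, match="ion shifts"):
            estimate_mod_mass(self.make_obs([]))


class TestMatchKnownPtms:
    def test_propionyl_top_hit_within_0003(self, registry):
        hits = match_known_ptms(56.026, registry, "K", tol=0.01)
        assert hits[0][0].name == "propionyl"
        assert hits[0][1] <= 0.0003

    def test_dimethyl_beats_formyl_at_tight_tolerance(self, registry):
        hits = match_known_ptms(28.0313, registry, "K", tol=0.01)
        assert hits[0][0].name == "dimethyl"
        assert "formyl" not in [m.name for m, _ in hits]

    def test_residue_context_filters_targets(self, registry):
        assert match_known_ptms(79.9663, registry, "K", tol=0.01) == []
        hits = match_known_ptms(79.9663, registry, "S", tol=0.01)
        assert hits[0][0].name == "phospho"

    def test_zero_delta_matches_nothing(self, registry):
        assert match_known_ptms(0.0, registry, "K", tol=0.01) == []


def brute_force_compositions(delta, tol, filters):
    """Independent oracle: plain quadruple loop over CHNO."""
    M = MONOISOTOPIC_ELEMENT_MASS
    out = []
    for c in range(0, int((delta + tol) / M["C"]) + 1):
        for h in range(0, int((delta + tol) / M["H"]) + 1):
            for n in range(0, int((delta + tol) / M["N"]) + 1):
                for o in range(0, int((delta + tol) / M["O"]) + 1):
                    mass = c * M["C"] + h * M["H"] + n * M["N"] + o * M["O"]
                    if abs(mass - delta) > tol:
                        continue
                    comp = ElementCounts(c=c, h=h, n=n, o=o)
                    if filters.passes(comp):
                        out.append(comp)
    return sorted(out, key=lambda x: (x.c, x.h, x.n, x.o))


class TestEnumerateCompositions:
    def test_methylpyrroline_unique_within_001(self):
        cands = enumerate_compositions(109.05248, tol=0.01)
        assert [c.comp.hill_formula() for c in cands] == ["C6H7NO"]

    def test_second_hit_at_looser_tolerance(self):
        cands = enumerate_compositions(109.05248, tol=0.02)
        assert [c.comp.hill_formula() for c in cands[:2]] == \
               ["C6H7NO", "C5H7N3"]

    def test_arginine_mass_shift_candidates(self):
        cands = enumerate_compositions(
            156.1016, tol=0.005,
            filters=FilterConfig(allow_radical=True, n_max=4))
        formulas = [c.comp.hill_formula() for c in cands]
        assert "C8H14NO2" in formulas  # the radical top candidate
        assert "C6H12N4O" in formulas  # arginine residue
        arg = next(c for c in cands if c.comp.hill_formula() == "C6H12N4O")
        assert arg.abs_diff <= 0.001

    def test_radicals_excluded_by_default(self):
        cands = enumerate_compositions(156.1016, tol=0.005,
                                       filters=FilterConfig(n_max=4))
        assert all(not c.radical for c in cands)
        assert "C8H14NO2" not in [c.comp.hill_formula() for c in cands]

    def test_sorted_by_abs_diff(self):
        cands = enumerate_compositions(150.0, tol=0.3)
        diffs = [c.abs_diff for c in cands]
        assert diffs == sorted(diffs)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            enumerate_compositions(100.0, tol=0.0)
        with pytest.raises(ValueError):
            enumerate_compositions(-5.0, tol=0.01)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(delta=st.floats(30.0, 300.0), n_max=st.integers(1, 4),
           allow_radical=st.booleans())
    def test_matches_quadruple_loop_oracle(self, delta, n_max, allow_radical):
        filters = FilterConfig(n_max=n_max, allow_radical=allow_radical)
        got = sorted((c.comp for c in
                      enumerate_compositions(delta, 0.02, "CHNO", filters)),
                     key=lambda x: (x.c, x.h, x.n, x.o))
        assert got == brute_force_compositions(delta, 0.02, filters)


class TestSuggestModCombinations:
    def test_single_acetyl(self, registry):
        combos = suggest_mod_combinations(42.011, registry, max_mods=1,
                                          tol=0.01)
        assert combos
        assert [m.name for m in combos[0][0]] == ["acetyl"]

    def test_satellite_190_includes_phospho_crotonyl_acetyl(self, registry):
        combos = suggest_mod_combinations(190.0, registry, max_mods=3, tol=0.5)
        names = [tuple(sorted(m.name for m in combo)) for combo, _ in combos]
        assert ("acetyl", "crotonyl", "phospho") in names

    def test_zero_delta_gives_empty_multiset_only(self, registry):
        combos = suggest_mod_combinations(0.0, registry, max_mods=2, tol=0.01)
        assert len(combos) == 1
        assert combos[0][0] == ()


class TestClassifySite:
    def protein(self):
        return ProteinRecord(
            id="P", sequence="S" + "A" * 70 + "K" * 30, met_removed=True,
            domain_annotations=(("NTD", 2, 55), ("GH1", 56, 90),
                                ("CTD", 91, 102)))

    def test_offset_arithmetic(self):
        loc = localize_shift(42.0, bracket_matches(
            "AAKAA", 42.0, b_states={1: False, 2: False, 3: True, 4: True},
            y_states={1: False, 2: False, 3: True}), 5)
        assert loc.interval == (3, 3)
        pep = PeptideSpan("P", 55, 59, "AAKAA", "trypsin")
        site = classify_site(loc, pep, self.protein(), mod_class="acetyl")
        assert site.position == 57
        assert site.residue == "K"

    def test_mature_nterm_position(self):
        loc = localize_shift(42.0, bracket_matches(
            "SAAAA", 42.0, b_states={1: True, 2: True}, y_states={4: False}), 5)
        pep = PeptideSpan("P", 2, 6, "SAAAA", "trypsin")
        site = classify_site(loc, pep, self.protein(), mod_class="phospho")
        assert site.position == 2
        assert site.domain == "NTD"

    def test_domain_label_attached(self):
        loc = localize_shift(42.0, bracket_matches(
            "AAKAA", 42.0, b_states={1: False, 2: False, 3: True, 4: True},
            y_states={1: False, 2: False, 3: True}), 5)
        pep = PeptideSpan("P", 56, 60, "AAKAA", "trypsin")
        site = classify_site(loc, pep, self.protein(), mod_class="acetyl")
        assert site.domain == "GH1"

    def test_non_site_specific_rejected(self):
        loc = localize_shift(42.0, [], 5)
        pep = PeptideSpan("P", 56, 60, "AAKAA", "trypsin")
        with pytest.raises(ValueError, match="site-specific"):
            classify_site(loc, pep, self.protein())
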