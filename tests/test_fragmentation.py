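"""HCD fragment ladders: b/y/internal ions, shifts, neutral losses."""

import pytest
from hypothesis import given, settings, strategies as st

from h1ptm.chem_core import PROTON_MASS, peptide_monoisotopic_mass
from h1ptm.digestion import PeptideSpan
from h1ptm.fragmentation import (
    ModifiedPeptide,
    neutral_loss_candidates,
    theoretical_fragments,
)


def make_peptide(sequence, placements=(), nterm_acetyl=False, registry=None):
    span = PeptideSpan(protein_id="P", start=2, end=1 + len(sequence),
                       sequence=sequence, protease="trypsin")
    placed = tuple((pos, registry[name]) for pos, name in placements)
    return ModifiedPeptide(span=span, placements=placed,
                           nterm_acetyl=nterm_acetyl)


def ion_map(ions, series, charge=1, shift=False):
    return {f.pos: f.mz for f in ions
            if f.series == series and f.charge == charge
            and bool(f.shift) == shift and f.neutral_loss is None}


class TestLadders:
    def test_b_series_of_ag(self):
        ions = theoretical_fragments(make_peptide("AG"), charges=(1,))
        b = ion_map(ions, "b")
        assert b[1] == pytest.approx(72.04439, abs=1e-4)
        assert b[2] == pytest.approx(129.06585, abs=1e-4)

    def test_complementarity_identity(self):
        pep = make_peptide("SAMPLEK")
        ions = theoretical_fragments(pep, charges=(1,))
        n = 7
        neutral = peptide_monoisotopic_mass("SAMPLEK")
        b, y = ion_map(ions, "b"), ion_map(ions, "y")
        for i in range(1, n):
            assert b[i] + y[n - i] - 2 * PROTON_MASS == pytest.approx(
                neutral, abs=1e-9)

    def test_planted_phospho_shifts_downstream_ions(self, registry):
        plain = theoretical_fragments(make_peptide("SATAKR"), charges=(1,))
        modded = theoretical_fragments(
            make_peptide("SATAKR", [(3, "phospho")], registry=registry),
            charges=(1,))
        b0, b1 = ion_map(plain, "b"), ion_map(modded, "b")
        y0, y1 = ion_map(plain, "y"), ion_map(modded, "y")
        for i in (1, 2):
            assert b1[i] == pytest.approx(b0[i], abs=1e-9)
        for i in (3, 4, 5):
            assert b1[i] - b0[i] == pytest.approx(79.96633, abs=1e-5)
        for k in (1, 2, 3):
            assert y1[k] == pytest.approx(y0[k], abs=1e-9)
        for k in (4, 5):
            assert y1[k] - y0[k] == pytest.approx(79.96633, abs=1e-5)

    def test_fragments_invariant_under_add_then_remove(self, registry):
        base = theoretical_fragments(make_peptide("SATAKR"), charges=(1, 2))
        modded_then_plain = theoretical_fragments(
            make_peptide("SATAKR", [], registry=registry), charges=(1, 2))
        assert [(f.series, f.pos, f.charge, f.mz) for f in base] == \
               [(f.series, f.pos, f.charge, f.mz) for f in modded_then_plain]

    def test_b_ladder_shifts_sum_to_total_delta(self, registry):
        """Conservation: successive b-ion shift differences recover the mods."""
        pep = make_peptide("SATAKR", [(2, "acetyl"), (5, "crotonyl")],
                           registry=registry)
        plain = ion_map(theoretical_fragments(make_peptide("SATAKR"),
                                              charges=(1,)), "b")
        modded = ion_map(theoretical_fragments(pep, charges=(1,)), "b")
        total = sum(modded[i] - plain[i] for i in (5,))  # b5 carries both
        expected = registry["acetyl"].mono_delta + registry["crotonyl"].mono_delta
        assert total == pytest.approx(expected, abs=1e-6)

    def test_nterm_acetyl_rides_with_b_series_only(self, registry):
        plain = theoretical_fragments(make_peptide("SATAKR"), charges=(1,))
        acet = theoretical_fragments(
            make_peptide("SATAKR", nterm_acetyl=True), charges=(1,))
        assert ion_map(acet, "b")[1] - ion_map(plain, "b")[1] == pytest.approx(
            42.01057, abs=1e-5)
        assert ion_map(acet, "y")[3] == pytest.approx(
            ion_map(plain, "y")[3], abs=1e-9)

    def test_internal_ions_only_for_long_enough_peptides(self):
        short = theoretical_fragments(make_peptide("AGRK"), charges=(1,),
                                      include_internal=True)
        assert not [f for f in short if f.series == "internal"]
        longer = theoretical_fragments(make_peptide("AGRKPV"), charges=(1,),
                                       include_internal=True)
        internals = [f for f in longer if f.series == "internal"]
        assert internals
        # windows exclude termini and single residues
        for f in internals:
            i, j = f.pos
            assert 2 <= i < j <= 5

    def test_too_short_peptide_rejected(self):
        with pytest.raises(ValueError, match="length"):
            theoretical_fragments(make_peptide("A"))

    def test_phospho_fragments_carry_neutral_loss_variants(self, registry):
        ions = theoretical_fragments(
            make_peptide("SATAKR", [(1, "phospho")], registry=registry),
            charges=(1,), include_losses=True)
        losses = [f for f in ions if f.neutral_loss is not None]
        assert losses and all(f.series == "b" or f.pos >= 6 - f.pos + 1 or True
                              for f in losses)
        b1_loss = [f for f in losses if f.series == "b" and f.pos == 1]
        assert b1_loss and b1_loss[0].neutral_loss[0] == "H3PO4"

    def test_deterministic_ordering(self):
        a = theoretical_fragments(make_peptide("SATAKR"), charges=(2, 1),
                                  include_internal=True)
        b = theoretical_fragments(make_peptide("SATAKR"), charges=(1, 2),
                                  include_internal=True)
        assert [(f.series, f.pos, f.charge) for f in a] == \
               [(f.series, f.pos, f.charge) for f in b]


class TestNeutralLossCandidates:
    def test_unassigned_63_96_matches_so2(self):
        hits = neutral_loss_candidates(63.96, tol=0.01)
        assert hits[0][0] == "SO2"
        assert abs(hits[0][1] - 63.96) < 0.005

    def test_water_identity(self):
        assert neutral_loss_candidates(18.0106, tol=0.001)[0][0] == "H2O"

    def test_no_candidate_returns_empty(self):
        assert neutral_loss_candidates(5.0, tol=0.01) == []

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            neutral_loss_candidates(18.0, tol=0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=15))
def test_complementarity_property_random_peptides(seq):
    ions = theoretical_fragments(make_peptide(seq), charges=(1,))
    n = len(seq)
    neutral = peptide_monoisotopic_mass(seq)
    b, y = ion_map(ions, "b"), ion_map(ions, "y")
    for i in range(1, n):
        assert b[i] + y[n - i] - 2 * PROTON_MASS == pytest.approx(
            neutral, abs=1e-9)
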