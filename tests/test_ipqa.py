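"""MRM peptide chemistry and impedance trace processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroscreen import synth
from fibroscreen.ipqa import (
    BASELINE_SUBTRACTED,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON_MASS,
    WATER_MASS,
    FIBROSIS_PANEL,
    ImpedanceTrace,
    Peptide,
    PeptideQuant,
    baseline_mean_trace,
    build_mrm_table,
    find_nadir,
    fragment_mz,
    normalize_to_tubulin,
    peptide_mass,
    peptide_mz,
    preprocess_trace,
    trace_response,
)

AA = sorted(MONOISOTOPIC_RESIDUE_MASS)


def oracle_mz(seq: str, charge: int) -> float:
    """Independent residue-sum oracle (written against the public standard
    amino-acid monoisotopic masses, summed digit-by-digit here)."""
    masses = {
        "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
        "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
        "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
        "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
        "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
    }
    total = 18.0105646
    for ch in seq:
        total += masses[ch]
    return (total + charge * 1.007276) / charge


class TestPrecursorMz:
    @pytest.mark.parametrize(
        "seq,charge,expected,dp",
        [
            ("DVNAAIATIK", 2, 508.29, 2),  # tubulin surrogate
            ("GVVGLPGQR", 2, 441.76, 2),  # COL1A1 surrogate (computed value)
            ("G", 1, 76.0393, 4),  # hand sum: 57.02146 + 18.01056 + 1.00728
        ],
    )
    def test_printed_precision(self, seq, charge, expected, dp):
        assert round(peptide_mz(Peptide(seq, charge)), dp) == pytest.approx(expected)

    def test_matches_pyteomics(self):
        mass = pytest.importorskip("pyteomics.mass")
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(AA, 10)) for _ in range(100)]
        seqs += [p.sequence for p, _ in FIBROSIS_PANEL]
        for seq in seqs:
            ours = peptide_mz(Peptide(seq, 2))
            ref = mass.calculate_mass(sequence=seq, charge=2)
            assert abs(ours - ref) < 1e-4

    def test_matches_residue_sum_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            seq = "".join(rng.choice(AA, 10))
            assert peptide_mz(Peptide(seq, 2)) == pytest.approx(
                oracle_mz(seq, 2), abs=1e-4
            )

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            Peptide("GAVBX", 2)
        with pytest.raises(ValueError):
            peptide_mass("GAXR")


class TestFragmentMz:
    @pytest.mark.parametrize(
        "seq,ion,expected,dp",
        [
            ("DVNAAIATIK", "y8", 801.48, 2),
            ("GVVGLPGQR", "y4", 457.3, 1),
        ],
    )
    def test_printed_y_ions(self, seq, ion, expected, dp):
        assert round(fragment_mz(Peptide(seq, 2), ion, 1), dp) == pytest.approx(
            expected
        )

    def test_full_length_y_equals_protonated_precursor(self):
        p = Peptide("GYSFVTTAER", 1)
        yL = fragment_mz(p, f"y{len(p.sequence) - 1}", 1)
        # y_(L-1) plus the N-terminal residue equals the singly charged precursor
        assert yL + MONOISOTOPIC_RESIDUE_MASS["G"] == pytest.approx(
            peptide_mz(p), abs=1e-6
        )

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            fragment_mz(Peptide("GAVR", 2), "y4", 1)
        with pytest.raises(ValueError):
            fragment_mz(Peptide("GAVR", 2), "b0", 1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seq=st.text(alphabet=AA, min_size=2, max_size=15),
        data=st.data(),
    )
    def test_by_complementarity(self, seq, data):
        """b_i + y_(L-i) (both 1+) equals M + 2 protons for every split."""
        i = data.draw(st.integers(1, len(seq) - 1))
        p = Peptide(seq, 2)
        total = fragment_mz(p, f"b{i}", 1) + fragment_mz(p, f"y{len(seq) - i}", 1)
        assert total == pytest.approx(
            peptide_mass(seq) + 2 * PROTON_MASS, abs=1e-4
        )


class TestMrmTable:
    def test_panel_table(self):
        tab = build_mrm_table()
        assert len(tab) == 3
        assert set(tab["protein"]) == {"COL1A1", "ACTA", "TBA1A"}
        row = tab[tab["peptide"] == "DVNAAIATIK"].iloc[0]
        assert row["precursor_mz"] == 508.29 and row["product_mz"] == 801.48

    def test_empty_spec(self):
        assert build_mrm_table([]).empty

    def test_annotation_flags_mismatch(self):
        tab = build_mrm_table(
            annotations={"DVNAAIATIK": (508.29, 801.48), "GVVGLPGQR": (441.73, 457.3)}
        )
        by_pep = tab.set_index("peptide")
        assert bool(by_pep.loc["DVNAAIATIK", "matches_ref"])
        # instrument-tuned precursor 441.73 differs from monoisotopic 441.76
        assert not bool(by_pep.loc["GVVGLPGQR", "matches_ref"])


class TestTubulinNormalization:
    def test_equal_areas_give_unit_ratios(self):
        [q] = normalize_to_tubulin([PeptideQuant("A01", 10, 10, 10)])
        assert q.ratio_col1 == 1.0 and q.ratio_acta == 1.0

    def test_zero_tubulin_flagged(self):
        [q] = normalize_to_tubulin([PeptideQuant("A01", 5, 5, 0)])
        assert q.flagged and q.ratio_acta is None

    def test_normalization_removes_cell_count_variation(self):
        """Tubulin ratio CV is smaller than raw-area CV under cell-count
        jitter, since the shared cell-number factor cancels."""
        rng = np.random.default_rng(0)
        quants = []
        for i in range(200):
            n = int(rng.integers(1000, 8000))
            quants.append(
                synth.simulate_msms_well(5.0, None, 0, n, seed=i, well=f"W{i}")
            )
        normed = normalize_to_tubulin(quants)
        raw = np.array([q.area_acta for q in normed])
        ratio = np.array([q.ratio_acta for q in normed])
        assert ratio.std() / ratio.mean() < raw.std() / raw.mean()

    def test_saturating_dose_gives_threefold_ratio(self):
        sat = normalize_to_tubulin(
            [synth.simulate_msms_well(5.0, None, 0, 4000, s,
                                      synth.MsmsParams(noise_cv=0.0))
             for s in range(4)]
        )
        ctrl = normalize_to_tubulin(
            [synth.simulate_msms_well(0.0, None, 0, 4000, s,
                                      synth.MsmsParams(noise_cv=0.0))
             for s in range(4)]
        )
        fold = np.mean([q.ratio_acta for q in sat]) / np.mean(
            [q.ratio_acta for q in ctrl]
        )
        assert fold == pytest.approx(3.0, rel=0.02)


class TestTracePreprocessing:
    def _raw(self, values, times=None, well="A01"):
        values = np.asarray(values, dtype=float)
        if times is None:
            times = np.arange(values.size, dtype=float)
        return ImpedanceTrace(well, times, values)

    def test_normalized_value_is_one_at_reference(self):
        tr = preprocess_trace(self._raw([2.0, 4.0, 8.0]), t_ref=1.0)
        assert tr.value_at(1.0) == 1.0

    def test_sole_baseline_replicate_subtracts_to_zero(self):
        raw = self._raw([3.0, 4.5, 6.0])
        base = baseline_mean_trace([self._raw([3.0, 4.5, 6.0], well="B01")])
        out = preprocess_trace(raw, 0.0, base)
        assert np.allclose(out.values, 0.0)
        assert out.state == BASELINE_SUBTRACTED

    def test_nonpositive_reference_value_rejected(self):
        with pytest.raises(ValueError):
            preprocess_trace(self._raw([0.0, 1.0, 2.0]), t_ref=0.0)

    def test_normalization_idempotent(self):
        norm = preprocess_trace(self._raw([2.0, 3.0, 5.0]), 0.0)
        again = preprocess_trace(norm, 0.0)
        assert np.array_equal(norm.values, again.values)

    def test_readout_matches_generator_pulse_model(self):
        """Noiseless dose series: baseline-subtracted 20 h value equals the
        generator's amplitude x pulse evaluated directly."""
        kp = synth.KineticParams(noise_sd=0.0)
        base = baseline_mean_trace(
            [preprocess_trace(synth.simulate_impedance_trace(0.0, kp=kp), 0.0)]
        )
        for dose in (0.1, 0.5, 1.0, 5.0):
            raw = synth.simulate_impedance_trace(dose, kp=kp)
            out = preprocess_trace(raw, 0.0, base)
            expected = synth.tgf_amplitude(dose, kp) * float(
                synth.pulse_shape(20.0, kp)
            )
            assert trace_response(out, 20.0) == pytest.approx(expected, abs=1e-9)


class TestTraceReadout:
    def _sub(self, times, values):
        return ImpedanceTrace("A01", times, values, BASELINE_SUBTRACTED, 0.0)

    def test_exact_sample_returned(self):
        tr = self._sub([0.0, 10.0, 20.0], [0.0, 0.5, 0.3])
        assert trace_response(tr, 10.0) == 0.5

    def test_linear_interpolation_midpoint(self):
        tr = self._sub([0.0, 10.0, 20.0], [0.0, 0.2, 0.4])
        assert trace_response(tr, 15.0) == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        tr = self._sub([0.0, 10.0], [0.0, 0.2])
        with pytest.raises(ValueError):
            trace_response(tr, 30.0)

    def test_raw_trace_rejected(self):
        raw = ImpedanceTrace("A01", [0.0, 10.0, 25.0], [1.0, 2.0, 1.5])
        with pytest.raises(ValueError):
            trace_response(raw, 20.0)


class TestNadir:
    def test_flat_trace_depth_zero(self):
        tr = ImpedanceTrace("A01", np.arange(10.0), np.zeros(10),
                            BASELINE_SUBTRACTED, 0.0)
        t, d = find_nadir(tr, (0.0, 9.0))
        assert d == 0.0

    def test_relaxation_nadir_between_two_and_three_hours(self):
        rec = synth.CompoundRecord("R1", True, 100.0, 1.0, 1.0, False, None,
                                   relax_depth=0.3)
        kp = synth.KineticParams(noise_sd=0.0, nadir_tau_h=2.5, amp_max=0.0)
        raw = synth.simulate_impedance_trace(0.0, rec, 10000.0, kp=kp)
        base = baseline_mean_trace(
            [preprocess_trace(synth.simulate_impedance_trace(0.0, kp=kp), 0.0)]
        )
        out = preprocess_trace(raw, 0.0, base)
        t, d = find_nadir(out, (0.5, 10.0))
        assert 2.0 <= t <= 3.0 and d < 0

    def test_tie_resolves_to_earlier_time(self):
        tr = ImpedanceTrace("A01", [0.0, 1.0, 2.0, 3.0], [0.0, -1.0, -1.0, 0.0],
                            BASELINE_SUBTRACTED, 0.0)
        t, _ = find_nadir(tr, (0.0, 3.0))
        assert t == 1.0

    def test_empty_window_rejected(self):
        tr = ImpedanceTrace("A01", [0.0, 1.0], [0.0, 0.0],
                            BASELINE_SUBTRACTED, 0.0)
        with pytest.raises(ValueError):
            find_nadir(tr, (1.0, 1.0))
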