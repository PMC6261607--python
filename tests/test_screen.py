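"""Hit calling, confirmation, Spearman correlation, reversal protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibroscreen import synth
from fibroscreen.doseresponse import CENSOR_ABOVE, DoseResponseFit, fit_3pl
from fibroscreen.screen import (
    ScreenConfig,
    call_primary_hits,
    confirm_hits,
    correlate_readouts,
    hits_frame,
    run_reversal_mode,
    run_synthetic_screen,
    spearman,
)


def frame(rows, cols):
    return pd.DataFrame(rows, columns=cols)


class TestPrimaryHits:
    def _call(self, inhib, viab, **cfg):
        effects = frame([("X", inhib)], ["compound_id", "percent_inhibition"])
        viability = frame([("X", viab)], ["compound_id", "viability_reduction_pct"])
        return call_primary_hits(effects, viability, ScreenConfig(**cfg))[0]

    def test_effective_nontoxic_is_primary(self):
        assert self._call(80.0, 10.0).tier == "primary"

    def test_effective_but_toxic_rejected_with_flag(self):
        hit = self._call(80.0, 60.0)
        assert hit.tier == "rejected"
        assert not hit.viability_pass
        assert hit.viability_reduction_pct == 60.0

    def test_weak_compound_rejected(self):
        assert self._call(30.0, 5.0).tier == "rejected"

    def test_missing_viability_rejected(self):
        effects = frame([("X", 80.0)], ["compound_id", "percent_inhibition"])
        viability = frame([("Y", 5.0)], ["compound_id", "viability_reduction_pct"])
        with pytest.raises(KeyError):
            call_primary_hits(effects, viability)

    def test_threshold_monotonicity(self):
        """Lowering the effect threshold never removes a primary hit."""
        rng = np.random.default_rng(1)
        effects = frame(
            [(f"C{i}", v) for i, v in enumerate(rng.uniform(0, 100, 50))],
            ["compound_id", "percent_inhibition"],
        )
        viability = frame(
            [(f"C{i}", v) for i, v in enumerate(rng.uniform(0, 40, 50))],
            ["compound_id", "viability_reduction_pct"],
        )
        strict = {
            h.compound_id
            for h in call_primary_hits(effects, viability, ScreenConfig())
            if h.tier == "primary"
        }
        loose = {
            h.compound_id
            for h in call_primary_hits(
                effects, viability, ScreenConfig(effect_threshold_pct=30.0)
            )
            if h.tier == "primary"
        }
        assert strict <= loose


class TestConfirmation:
    def _hit(self, cid="X"):
        effects = frame([(cid, 80.0)], ["compound_id", "percent_inhibition"])
        viability = frame([(cid, 5.0)], ["compound_id", "viability_reduction_pct"])
        return call_primary_hits(effects, viability)

    def test_potent_fit_confirms(self):
        fits = {"X": DoseResponseFit(0, 100, np.log10(500.0), "ascending")}
        [hit] = confirm_hits(self._hit(), fits)
        assert hit.tier == "confirmed" and hit.ic50_nM == pytest.approx(500.0)

    def test_censored_fit_not_confirmed(self):
        fits = {"X": DoseResponseFit(0, 100, float("nan"), "ascending", CENSOR_ABOVE)}
        [hit] = confirm_hits(self._hit(), fits)
        assert hit.tier == "primary" and hit.ic50_censored


def oracle_spearman(x, y):
    """Independent average-rank Pearson oracle."""
    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return np.asarray(r)

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float(rx @ ry / denom) if denom else float("nan")


class TestSpearman:
    def test_self_correlation(self):
        r, p = spearman([3, 1, 4, 1, 5], [3, 1, 4, 1, 5])
        assert r == pytest.approx(1.0)

    def test_known_permutation_example(self):
        r, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(oracle_spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert r == pytest.approx(0.8)  # 1 - 6*4/(5*24)

    def test_tied_vectors_perfectly_concordant(self):
        assert oracle_spearman([1, 1, 2], [3, 3, 4]) == pytest.approx(1.0)
        r, _ = spearman([1, 1, 2, 2, 3], [3, 3, 4, 4, 5])
        assert r == pytest.approx(1.0)

    def test_matches_oracle_on_tied_integer_vectors(self):
        """Every 5-element vector over {1,2,3} against a tied reference:
        implementation equals the brute-force oracle and scipy."""
        x = [1, 2, 2, 3, 1]
        for y in itertools.product((1, 2, 3), repeat=5):
            y = list(y)
            if len(set(y)) == 1:
                continue  # constant vector: correlation undefined
            r, _ = spearman(x, y)
            assert r == pytest.approx(oracle_spearman(x, y), abs=1e-12)
            assert r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_permutation_p_matches_t_approx_at_n9(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        _, p_exact = spearman(x, y, exact_n_max=9)
        _, p_t = spearman(x, y, exact_n_max=0)
        assert abs(p_exact - p_t) < 0.02

    def test_correlation_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            r, p = spearman(rng.normal(size=8), rng.normal(size=8))
            assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0


class TestCorrelateReadouts:
    def test_matrix_shape_and_symmetry(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 4, 12)
        pot = pd.DataFrame(
            {
                "hca": 10**base,
                "impedance": 10 ** (base + rng.normal(0, 0.3, 12)),
                "msms": 10 ** (base + rng.normal(0, 0.3, 12)),
            }
        )
        r, p = correlate_readouts(pot)
        assert (r.to_numpy() <= 1.0 + 1e-12).all()
        assert np.allclose(r, r.T)
        assert r.loc["hca", "impedance"] > 0.5

    def test_too_few_pairs_rejected(self):
        pot = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]})
        with pytest.raises(ValueError):
            correlate_readouts(pot)


class TestReversalMode:
    def _plate(self, compounds=()):
        design = synth.PlateDesign(
            neg_control_cols=(1,), pos_control_cols=(12,), mode="reversal",
            compounds=tuple(compounds),
        )
        return synth.generate_plate_layout(8, 12, design)

    def test_prevention_plate_rejected(self):
        plate = synth.generate_plate_layout(8, 12, synth.ipqa_design())
        with pytest.raises(ValueError):
            run_reversal_mode(plate, ScreenConfig(assay_mode="reversal"))

    def test_prevention_config_rejected(self):
        with pytest.raises(ValueError):
            run_reversal_mode(self._plate(), ScreenConfig(assay_mode="prevention"))

    def test_vehicle_wells_persist_differentiated(self):
        eff, _ = run_reversal_mode(
            self._plate(), ScreenConfig(assay_mode="reversal"), seed=1
        )
        vehicle = eff[eff["role"] == "sample"]["percent_effect"]
        assert abs(vehicle.mean()) < 5.0

    def test_full_reverser_restores_baseline_ratio(self):
        table = synth.generate_compound_library(1, 1.0, (100.0, 101.0), 0).table
        table.loc[0, "reverses"] = True
        table.loc[0, "efficacy"] = 1.0
        reg = synth.CompoundRegistry(table)
        cid = table.loc[0, "compound_id"]
        plate = self._plate([(cid, 1e7)])  # saturating concentration
        mp = synth.MsmsParams(noise_cv=0.0)
        eff, quants = run_reversal_mode(
            plate, ScreenConfig(assay_mode="reversal"), reg, seed=2, mp=mp
        )
        by_well = {q.well: q for q in quants}
        pos_wells = plate.wells_of_role("pos_control")["well"]
        comp_wells = eff[eff["compound_id"] == cid]["well"]
        pos_ratio = np.mean([by_well[w].ratio_acta for w in pos_wells])
        comp_ratio = np.mean([by_well[w].ratio_acta for w in comp_wells])
        assert comp_ratio == pytest.approx(pos_ratio, rel=0.02)

    def test_reversal_ic50_round_trip(self):
        """3PL fit of endpoint marker ratios along a reverser dilution
        recovers the programmed reversal potency within 2-fold."""
        rec = synth.CompoundRecord(
            "R1", True, 300.0, 1.0, 1.0, False, None, reverses=True
        )
        concs = np.repeat(30000.0 / 3.0 ** np.arange(9), 2)  # duplicate wells
        ratios = []
        for i, c in enumerate(concs):
            q = synth.simulate_msms_reversal_well(rec, c, 4000, seed=i)
            ratios.append(q.area_acta / q.area_tba1a)
        f = fit_3pl(np.log10(concs), np.array(ratios))
        assert 150.0 <= f.ec50 <= 600.0


@pytest.fixture(scope="module")
def screen_result():
    registry = synth.generate_compound_library(200, 0.1, (30.0, 1000.0), 7)
    return registry, run_synthetic_screen(registry, ScreenConfig(), 7)


class TestEndToEnd:
    def test_recall_and_false_positive_rate(self, screen_result):
        registry, df = screen_result
        hit = df["tier"].isin(["primary", "confirmed"])
        recall = (hit & df["true_active"]).sum() / df["true_active"].sum()
        fpr = (hit & ~df["true_active"]).sum() / (~df["true_active"]).sum()
        assert recall >= 0.9
        assert fpr <= 0.05

    def test_every_confirmed_hit_is_true_active(self, screen_result):
        _, df = screen_result
        confirmed = df[df["tier"] == "confirmed"]
        assert len(confirmed) > 0
        assert confirmed["true_active"].all()

    def test_screen_is_deterministic(self, screen_result):
        registry, df = screen_result
        again = run_synthetic_screen(registry, ScreenConfig(), 7)
        pd.testing.assert_frame_equal(df, again)
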