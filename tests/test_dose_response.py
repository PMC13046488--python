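"""Dose-response surfaces, LD50 interpolation/censoring, AUC, triage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elda.dose_response import (
    DoseResponseSurface,
    auc,
    build_surface,
    ld50,
    triage_panel,
)
from elda.normalization_qc import NormalizedTrace
from elda.plate_model import PlateLayout, WellRole, WellSpec


def make_surface(doses, viability, times_min=None):
    viability = np.asarray(viability, dtype=float)
    if viability.ndim == 1:
        viability = viability[:, None]
    times = (
        np.asarray(times_min, dtype=float)
        if times_min is not None
        else np.arange(viability.shape[1]) * 30.0 + 180.0
    )
    return DoseResponseSurface(
        drug_id="d",
        sample_id="s",
        doses_nM=np.asarray(doses, dtype=float),
        times_min=times,
        viability=viability,
        spread=np.zeros_like(viability),
        n_replicates=np.full(len(doses), 2),
        flags=[],
    )


def layout_with_treatments(doses, n_reps=2):
    wells = [
        WellSpec(row=0, col=i, role=WellRole.vehicle_control, sample_id="s")
        for i in range(2)
    ]
    r = 1
    for rep in range(n_reps):
        for j, d in enumerate(doses):
            wells.append(
                WellSpec(
                    row=r, col=j, role=WellRole.treatment, drug_id="d",
                    concentration_nM=d, replicate=rep + 1, sample_id="s",
                )
            )
        r += 1
    return PlateLayout(wells=wells)


def norm_trace(pct_control):
    pct = np.asarray(pct_control, dtype=float)
    times = np.arange(len(pct)) * 30.0 + 180.0
    return NormalizedTrace(
        times_min=times, raw_area=pct, pct_baseline=pct, pct_control=pct
    )


class TestBuildSurface:
    def test_replicates_averaged_with_spread(self):
        layout = layout_with_treatments([10.0])
        traces = {"B01": norm_trace([60.0]), "C01": norm_trace([80.0])}
        surf = build_surface(traces, layout)
        assert surf.viability[0, 0] == 70.0
        assert surf.spread[0, 0] == 20.0

    def test_full_five_by_two_design(self):
        doses = [8.0, 40.0, 200.0, 1000.0, 5000.0]
        layout = layout_with_treatments(doses)
        traces = {}
        for w in layout.wells_by_role(WellRole.treatment):
            traces[w.address] = norm_trace(np.linspace(100, 50, 4))
        surf = build_surface(traces, layout)
        assert surf.viability.shape == (5, 4)
        assert not surf.flags
        assert np.array_equal(surf.doses_nM, doses)

    def test_vehicle_wells_rejected(self):
        layout = layout_with_treatments([10.0])
        with pytest.raises(ValueError, match="role"):
            build_surface({"A01": norm_trace([100.0])}, layout)

    def test_single_replicate_flagged(self):
        layout = layout_with_treatments([10.0], n_reps=1)
        surf = build_surface({"B01": norm_trace([70.0])}, layout)
        assert any("single_replicate" in f for f in surf.flags)


class TestLD50:
    def test_log_linear_interpolation_matches_closed_form(self):
        surf = make_surface([10.0, 50.0], [[80.0], [20.0]])
        res = ld50(surf)
        expected = 10 ** (1 + 0.5 * (np.log10(50) - np.log10(10)))
        assert res.ld50_nM == pytest.approx(expected, rel=1e-9)  # ~22.36 nM
        assert not res.censored

    def test_resistant_curve_censored_at_twice_max_dose(self):
        surf = make_surface([8, 40, 200, 1000, 5000], [[95], [90], [85], [75], [60]])
        res = ld50(surf)
        assert res.censored
        assert res.ld50_nM == 10000.0

    def test_exact_crossing_returns_tested_dose(self):
        surf = make_surface([10.0, 100.0], [[50.0], [20.0]])
        res = ld50(surf)
        assert res.ld50_nM == 10.0
        assert not res.censored

    def test_below_range_flagged_not_extrapolated(self):
        surf = make_surface([10.0, 100.0], [[30.0], [10.0]])
        res = ld50(surf)
        assert res.below_range
        assert res.ld50_nM == 10.0

    def test_non_monotone_uses_lowest_crossing(self):
        surf = make_surface(
            [1.0, 10.0, 100.0, 1000.0], [[80.0], [40.0], [60.0], [20.0]]
        )
        res = ld50(surf)
        assert res.non_monotone
        assert 1.0 < res.ld50_nM < 10.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_lowering_viability_never_raises_ld50(self, seed):
        rng = np.random.default_rng(seed)
        doses = np.array([8.0, 40.0, 200.0, 1000.0, 5000.0])
        v = np.sort(rng.uniform(0, 120, 5))[::-1]
        drop = rng.uniform(0, 30, 5)
        hi = ld50(make_surface(doses, v)).ld50_nM
        lo = ld50(make_surface(doses, np.clip(v - drop, 0, None))).ld50_nM
        assert lo <= hi + 1e-9

    def test_censoring_flag_consistent_with_value(self):
        surf = make_surface([10.0, 100.0], [[90.0], [70.0]])
        res = ld50(surf)
        assert res.censored == (res.ld50_nM == 2 * 100.0)


class TestAUC:
    def test_no_effect_ceiling(self):
        surf = make_surface([1.0, 10.0], np.full((2, 5), 100.0))
        assert auc(surf) == pytest.approx(1.0)

    def test_instant_kill_floor(self):
        surf = make_surface([1.0, 10.0], np.zeros((2, 5)))
        assert auc(surf) == pytest.approx(0.0)

    def test_linear_decay_gives_half(self):
        v = np.tile(np.linspace(100.0, 0.0, 9), (3, 1))
        surf = make_surface([1.0, 10.0, 100.0], v)
        assert auc(surf) == pytest.approx(0.5)

    def test_single_time_point_rejected(self):
        surf = make_surface([1.0, 10.0], [[50.0], [40.0]])
        with pytest.raises(ValueError):
            auc(surf)

    def test_lowering_viability_never_raises_auc(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(20, 100, (4, 6))
        surf_hi = make_surface([1, 10, 100, 1000], v)
        surf_lo = make_surface([1, 10, 100, 1000], v * 0.7)
        assert auc(surf_lo) <= auc(surf_hi)

    def test_alternative_definition_also_bounded(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 100, (4, 6))
        surf = make_surface([1, 10, 100, 1000], v)
        assert 0.0 <= auc(surf, over="dose_sum") <= 1.0


def brute_force_triage(table: pd.DataFrame, threshold: float):
    inactive, weak, pre = [], [], []
    for drug, row in table.iterrows():
        vals = [v for v in row.to_numpy() if np.isfinite(v)]
        if not vals:
            inactive.append(drug)
        elif min(vals) <= threshold:
            pre.append(drug)
        else:
            weak.append(drug)
    return {
        "discarded_inactive": sorted(inactive),
        "discarded_weak": sorted(weak),
        "preselected": sorted(pre),
    }


class TestTriagePanel:
    def make_library_table(self, n_inactive=57, n_weak=49, n_pre=60, n_samples=8):
        """Library with the stated triage composition (166 drugs)."""
        rng = np.random.default_rng(0)
        rows, names = [], []
        for i in range(n_inactive):
            rows.append([np.nan] * n_samples)
            names.append(f"inactive_{i}")
        for i in range(n_weak):
            row = [np.nan] * n_samples
            row[int(rng.integers(n_samples))] = float(rng.uniform(501, 5000))
            rows.append(row)
            names.append(f"weak_{i}")
        for i in range(n_pre):
            row = [float(rng.uniform(501, 5000))] * n_samples
            row[int(rng.integers(n_samples))] = float(rng.uniform(1, 500))
            rows.append(row)
            names.append(f"pre_{i}")
        return pd.DataFrame(rows, index=names)

    def test_library_composition_reproduced(self):
        table = self.make_library_table()
        assert len(table) == 166
        out = triage_panel(table, preselect_threshold_nM=500.0)
        assert len(out["discarded_inactive"]) == 57
        assert len(out["discarded_weak"]) == 49
        assert len(out["preselected"]) == 60

    def test_all_inactive_gives_empty_preselection(self):
        table = pd.DataFrame([[np.nan, np.nan]] * 3, index=list("abc"))
        out = triage_panel(table)
        assert out["preselected"] == []
        assert out["discarded_inactive"] == ["a", "b", "c"]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_drugs = int(rng.integers(1, 12))
        n_samples = int(rng.integers(1, 5))
        vals = rng.uniform(1, 2000, (n_drugs, n_samples))
        vals[rng.uniform(size=vals.shape) < 0.4] = np.nan
        table = pd.DataFrame(vals, index=[f"d{i}" for i in range(n_drugs)])
        thr = float(rng.uniform(10, 1000))
        assert triage_panel(table, thr) == brute_force_triage(table, thr)

    def test_sets_partition_the_library(self):
        table = self.make_library_table()
        out = triage_panel(table)
        union = (
            set(out["discarded_inactive"])
            | set(out["discarded_weak"])
            | set(out["preselected"])
        )
        assert union == set(table.index)
        assert len(union) == sum(len(v) for v in out.values())

    def test_negative_concentration_rejected(self):
        table = pd.DataFrame([[-5.0]], index=["bad"])
        with pytest.raises(ValueError):
            triage_panel(table)
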