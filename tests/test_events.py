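"""Event-table I/O, gating, PI thresholding, and control subtraction."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoplan import (
    EventTable,
    GateConfig,
    GeneratorConfig,
    derive_pi_threshold,
    estimate_death_fraction,
    gate_events,
    generate_events,
    load_events,
    subtract_controls,
    write_events,
    death_rate_measurements,
)
from photoplan.events import ParseError, SchemaError
from conftest import binom_ci99_halfwidth


def _csv(body: str):
    header = "sample_id,modality,intensity_mw_cm2,duration_min,replicate,control_kind,fsc,ssc,fsc_area,pi\n"
    return io.StringIO(header + textwrap.dedent(body))


def _table(fsc, pi, fsc_area=None, ssc=None, control_kind="none"):
    n = len(fsc)
    return EventTable(
        pd.DataFrame(
            {
                "sample_id": "s1",
                "modality": "PDT",
                "intensity_mw_cm2": 6.0,
                "duration_min": 4.0,
                "replicate": 1,
                "control_kind": control_kind,
                "fsc": fsc,
                "ssc": ssc if ssc is not None else np.full(n, 2e4),
                "fsc_area": fsc_area if fsc_area is not None else np.asarray(fsc, float),
                "pi": pi,
            }
        )
    )


class TestLoadEvents:
    def test_reads_valid_rows(self):
        t = load_events(_csv("""\
            s1,PDT,6,4,1,none,50000,20000,50000,100
            s1,PDT,6,4,1,none,48000,21000,48000,90
            s1,PDT,6,4,1,none,52000,19000,52000,3000
            """))
        assert t.n_events == 3
        assert t.df["pi"].tolist() == [100.0, 90.0, 3000.0]

    def test_missing_column_is_schema_error(self):
        buf = io.StringIO("sample_id,modality\ns1,PDT\n")
        with pytest.raises(SchemaError, match="pi"):
            load_events(buf)

    def test_non_numeric_cell_names_the_row(self):
        with pytest.raises(ParseError, match="row 3.*pi"):
            load_events(_csv("""\
                s1,PDT,6,4,1,none,50000,20000,50000,100
                s1,PDT,6,4,1,none,48000,21000,48000,oops
                """))

    def test_round_trip_preserves_values(self, tmp_path, small_events):
        table, _ = small_events
        path = tmp_path / "events.csv"
        write_events(table, path)
        reread = load_events(path)
        assert reread.n_events == table.n_events
        np.testing.assert_allclose(
            reread.df["pi"].to_numpy(), table.df["pi"].to_numpy(), rtol=1e-12
        )


class TestGating:
    def test_debris_and_cells_separated(self):
        t = _table(fsc=[100, 200] + [50000] * 8, pi=[100] * 10)
        gated = gate_events(t, GateConfig(debris_floor=5000))
        assert len(gated.retained) == 8
        assert (gated.df["gate"] == "debris").sum() == 2

    def test_doublets_removed_by_area_ratio(self):
        fsc = np.full(10, 50000.0)
        area = np.array([50000.0] * 7 + [100000.0] * 3)
        gated = gate_events(_table(fsc=fsc, pi=[100] * 10, fsc_area=area))
        assert len(gated.retained) == 7
        assert (gated.df["gate"] == "doublet").sum() == 3

    def test_clean_table_unchanged(self):
        t = _table(fsc=np.full(20, 50000.0), pi=np.full(20, 100.0))
        gated = gate_events(t)
        assert len(gated.retained) == 20

    def test_idempotent(self, small_events):
        table, _ = small_events
        once = gate_events(table)
        twice = gate_events(once)
        assert (once.df["gate"] == twice.df["gate"]).all()

    def test_all_excluded_flags_invalid(self):
        t = _table(fsc=np.full(5, 10.0), pi=np.full(5, 100.0))
        gated = gate_events(t, GateConfig(debris_floor=1e6))
        assert not gated.valid
        assert len(gated.retained) == 0

    def test_injected_artifact_rates_recovered(self, small_events):
        """Gating recovers the generator's injected debris/doublet fractions."""
        table, ledger = small_events
        gated = gate_events(table)
        n = gated.n_events
        n_debris_true = sum(s["n_debris"] for s in ledger.samples.values())
        n_doublet_true = sum(s["n_doublets"] for s in ledger.samples.values())
        got_debris = (gated.df["gate"] == "debris").sum() / n
        got_doublet = (gated.df["gate"] == "doublet").sum() / n
        assert abs(got_debris - n_debris_true / n) < binom_ci99_halfwidth(0.05, n)
        assert abs(got_doublet - n_doublet_true / n) < binom_ci99_halfwidth(0.03, n) + 0.005


class TestDeathFraction:
    def test_direct_count(self):
        t = _table(fsc=np.full(100, 5e4), pi=np.r_[np.full(30, 2000.0), np.full(70, 100.0)])
        assert estimate_death_fraction(t, pi_threshold=500) == pytest.approx(0.30)

    def test_all_below_threshold(self):
        t = _table(fsc=np.full(10, 5e4), pi=np.full(10, 50.0))
        assert estimate_death_fraction(t, pi_threshold=500) == 0.0

    def test_empty_table_rejected(self):
        t = _table(fsc=np.full(3, 10.0), pi=np.full(3, 50.0))
        gated = gate_events(t)  # everything is debris
        with pytest.raises(ValueError):
            estimate_death_fraction(gated, pi_threshold=500)

    def test_monotone_in_threshold(self, small_events):
        table, _ = small_events
        gated = gate_events(table)
        fracs = [estimate_death_fraction(gated, th) for th in (100, 300, 1000, 3000)]
        assert fracs == sorted(fracs, reverse=True)

    def test_binomial_recovery_of_true_death_probability(self):
        """Estimate at a mid-gap PI threshold recovers the sample's true kill
        probability within a 99% binomial CI at n = 2000."""
        cfg = GeneratorConfig(
            modality="PDT", events_per_sample=2000, debris_rate=0.0, doublet_rate=0.0,
            noise_sd=0.0, control_death=0.0,
        )
        table, ledger = generate_events(cfg, seed=4, conditions=[(5.3, 17.0)])
        sid = "PDT_t5.3_i17_r1"
        sub = [s for s_id, s in gate_events(table).samples() if s_id == sid][0]
        p_true = ledger.samples[sid]["p_dead_raw"]
        est = estimate_death_fraction(sub, pi_threshold=500.0)
        assert abs(est - p_true) < binom_ci99_halfwidth(p_true, cfg.events_per_sample)

    def test_error_shrinks_as_sqrt_n(self):
        """|estimate - truth| stays inside shrinking binomial CIs as n grows."""
        for n in (100, 1000, 10000):
            cfg = GeneratorConfig(
                modality="PDT", events_per_sample=n, debris_rate=0.0, doublet_rate=0.0,
                noise_sd=0.0, control_death=0.0,
            )
            table, ledger = generate_events(cfg, seed=6, conditions=[(5.3, 17.0)])
            for sid, sub in gate_events(table).samples():
                if not sid.startswith("PDT_t5.3"):
                    continue  # controls have p=0; the PI false-positive floor dominates
                p_true = ledger.samples[sid]["p_dead_raw"]
                est = estimate_death_fraction(sub, pi_threshold=500.0)
                assert abs(est - p_true) < binom_ci99_halfwidth(p_true, n) + 0.005


class TestPiThreshold:
    def test_degenerate_distribution(self):
        t = _table(fsc=np.full(200, 5e4), pi=np.full(200, 10.0), control_kind="laser_only")
        assert derive_pi_threshold(t, quantile=0.99) == pytest.approx(10.0)

    def test_median_quantile_on_symmetric_control(self):
        pi = np.r_[np.linspace(50, 150, 201)]
        t = _table(fsc=np.full(201, 5e4), pi=pi, control_kind="np_only")
        assert derive_pi_threshold(t, quantile=0.5) == pytest.approx(100.0)

    def test_treated_samples_rejected(self):
        t = _table(fsc=np.full(10, 5e4), pi=np.full(10, 10.0), control_kind="none")
        with pytest.raises(ValueError):
            derive_pi_threshold(t)

    def test_control_apparent_death_matches_quantile(self, small_events):
        """By construction, ~(1 - q) of pooled control events score above the threshold."""
        table, _ = small_events
        gated = gate_events(table)
        controls = gated.controls()
        for q in (0.95, 0.99):
            th = derive_pi_threshold(controls, quantile=q)
            apparent = estimate_death_fraction(controls, th)
            n = len(controls.retained)
            assert abs(apparent - (1 - q)) < binom_ci99_halfwidth(1 - q, n) + 2 / n

    def test_default_threshold_detects_dead_cells_on_treated_samples(self, small_events):
        """The default quantile clears the control background, so treated-sample
        dead cells are detected nearly in full."""
        table, ledger = small_events
        gated = gate_events(table)
        th = derive_pi_threshold(gated.controls())
        sid = "PDT_t8_i30_r1"  # high-kill sample
        sub = [s for s_id, s in gated.samples() if s_id == sid][0]
        est = estimate_death_fraction(sub, th)
        p_true = ledger.samples[sid]["p_dead_raw"]
        assert est == pytest.approx(p_true, abs=0.06)


class TestSubtractControls:
    @pytest.mark.parametrize(
        "raw,controls,expected",
        [
            (0.34, [0.04, 0.04], 0.30),
            (0.02, [0.04], 0.00),
            (0.99, [0.04], 0.95),
        ],
    )
    def test_arithmetic_and_clipping(self, raw, controls, expected):
        assert subtract_controls(raw, controls) == pytest.approx(expected)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            subtract_controls(0.5, [])

    @given(raw=st.floats(0, 1), c=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_output_in_unit_interval_and_identity_at_zero(self, raw, c):
        out = subtract_controls(raw, [c])
        assert 0.0 <= out <= 1.0
        assert subtract_controls(raw, [0.0, 0.0]) == pytest.approx(raw)


class TestEndToEnd:
    def test_condition_measurements_recover_truth(self, small_events):
        """Gate -> threshold -> subtract recovers the generator's adjusted truths."""
        table, ledger = small_events
        ms = death_rate_measurements(table)
        assert len(ms) == 12
        for m in ms:
            assert 0.0 <= m.adjusted_fraction <= 1.0
            assert m.n_events > 0
            assert len(m.replicate_values) == 2
        # per-condition recovery against the ledger, allowing binomial noise +
        # the control-subtraction offset
        by_cond = {(m.duration, m.intensity): m for m in ms}
        truths = {}
        for sid, info in ledger.samples.items():
            if "true_surface_death" in info:
                parts = sid.split("_")
                tau = float(parts[1][1:])
                i0 = float(parts[2][1:])
                truths.setdefault((tau, i0), []).append(info["true_adjusted_death"])
        for (tau, i0), vals in truths.items():
            m = by_cond[(tau, i0)]
            tol = binom_ci99_halfwidth(np.mean(vals), m.n_events) + 0.03
            assert abs(m.adjusted_fraction - float(np.mean(vals))) < tol
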