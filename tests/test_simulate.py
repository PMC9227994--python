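"""Mechanistic simulator: conservation, convergence, sampling, regimes, determinism."""

import numpy as np
import pytest

from permkit import (Censored, SimulationParams, StudyDesign, TransportRun,
                     TranswellGeometry, TranswellSimulation, analyze_run,
                     apply_noise_and_lloq, apply_sampling, generate_study,
                     is_censored, simulate_deconjugation_assay,
                     simulate_transport)
from permkit.simulate import StepSizeError, params_for_arm, DoseArm

TIMES = [30.0, 60.0, 90.0, 120.0]


def noise_free(**kw):
    kw.setdefault("noise_cv", 0.0)
    return SimulationParams(**kw)


@pytest.fixture
def sink_geometry():
    """Enlarged chambers so that donor depletion and receiver back-flux are
    negligible over 2 h even at the highest permeability."""
    return TranswellGeometry(volume_apical=40.0, volume_basolateral=120.0,
                             aliquot_apical=0.2, aliquot_basolateral=0.2)


class TestDynamics:
    def test_no_transport_when_all_rates_zero(self):
        p = noise_free(papp_parent_ab=0.0, papp_parent_ba=0.0, conj_vmax=0.0)
        st = simulate_transport(p, 3.267, "AB", duration_min=120)
        assert st.mass_receiver_parent == 0.0
        assert st.mass_donor_parent == pytest.approx(3.267 * 0.4)

    def test_analytic_sink_approximation(self):
        # enlarged donor realises the sink regime; receiver mass after 30 min
        # approximates Papp·A·C0·t
        g = TranswellGeometry(volume_apical=4.0, aliquot_apical=0.2)
        p = noise_free(conj_vmax=0.0)
        st = simulate_transport(p, 3.267, "AB", g, duration_min=30)
        expected = 5e-6 * 1.12 * 3.267 * 1800.0
        assert st.mass_receiver_parent == pytest.approx(expected, rel=0.02)

    def test_mass_conservation(self):
        p = noise_free(matrix_factor=3.0, matrix_conj_km_factor=2.0)
        sim = TranswellSimulation(p, 6.535, "AB")
        srun = sim.run_protocol(TIMES)
        initial = 6.535 * 0.4
        assert srun.state.total_mass() == pytest.approx(initial, rel=1e-6)

    def test_step_halving_convergence(self):
        kw = dict(matrix_factor=3.0, matrix_conj_km_factor=2.0)
        a = apply_sampling(noise_free(**kw), 6.535, "AB", TIMES)
        b = apply_sampling(noise_free(dt=0.25, **kw), 6.535, "AB", TIMES)
        for (_, pa, ca), (_, pb, cb) in zip(a.record, b.record):
            assert pa == pytest.approx(pb, rel=1e-3)
            assert ca == pytest.approx(cb, rel=1e-3)

    def test_unstable_step_raises(self):
        # a step far beyond the fastest cell-compartment timescale
        p = noise_free(papp_parent_ab=5e-5, papp_parent_ba=5e-5,
                       cell_volume=1e-6, dt=60.0)
        with pytest.raises(StepSizeError):
            simulate_transport(p, 3.267, "AB", duration_min=30)


class TestSampling:
    def test_aliquot_dilution_arithmetic(self):
        # withdrawing S from V and refilling scales concentration by (V−S)/V
        p = noise_free(conj_vmax=0.0, papp_parent_ab=50e-6, papp_parent_ba=50e-6)
        sim = TranswellSimulation(p, 10.0, "AB")
        srun = sim.run_protocol([30.0])
        c_before = srun.record[0][1]
        resident_after = srun.state.mass_receiver_parent / 1.2
        assert resident_after == pytest.approx(c_before * (1.2 - 0.6) / 1.2)

    def test_ledger_tracks_withdrawn_mass(self):
        p = noise_free()
        srun = TranswellSimulation(p, 3.267, "AB").run_protocol(TIMES)
        # each withdrawal removes S·C of each species
        parent_removed = [m for _, side, sp, m in srun.state.removed_ledger
                          if sp == "parent"]
        assert len(parent_removed) == len(TIMES)
        assert parent_removed[0] == pytest.approx(srun.record[0][1] * 0.6)

    def test_eq3_reconstruction_equals_ledger_truth(self):
        p = noise_free(matrix_factor=3.0, matrix_conj_km_factor=2.0)
        srun = TranswellSimulation(p, 3.2675, "AB").run_protocol(TIMES)
        run = TransportRun("r", "AB", 3.2675,
                           list(zip(TIMES, srun.parent_concentrations())))
        from permkit import cumulative_amount
        q, _ = cumulative_amount(run)
        for (_, q_est), q_true in zip(q, srun.true_q_parent):
            assert q_est == pytest.approx(q_true, rel=1e-12, abs=1e-15)


class TestNoiseAndCensoring:
    def test_zero_noise_identity_except_censoring(self):
        vals = [0.5, 0.02, 1.0]
        out = apply_noise_and_lloq(vals, 0.0, 0.025, rng=1)
        assert out[0] == 0.5 and out[2] == 1.0
        assert isinstance(out[1], Censored)

    def test_all_below_lloq_fully_censored(self):
        out = apply_noise_and_lloq([0.01, 0.02, 0.005], 0.05, 0.025, rng=1)
        assert all(is_censored(v) for v in out)

    def test_seed_determinism(self):
        vals = [0.5, 0.8, 1.0]
        a = apply_noise_and_lloq(vals, 0.1, 0.025, rng=42)
        b = apply_noise_and_lloq(vals, 0.1, 0.025, rng=42)
        assert a == b

    def test_noise_is_mean_preserving(self):
        rng = np.random.default_rng(0)
        out = apply_noise_and_lloq([1.0] * 20000, 0.1, 0.0, rng=rng)
        assert np.mean(out) == pytest.approx(1.0, rel=0.01)


class TestDeconjugationAssay:
    def test_zero_conjugate_equals_parent_record(self):
        p = noise_free(conj_vmax=0.0)
        srun = TranswellSimulation(p, 3.267, "AB").run_protocol(TIMES)
        total = simulate_deconjugation_assay(srun, 0.0, 0.0, rng=1,
                                             enzyme_dilution=False)
        assert total == pytest.approx(srun.parent_concentrations())

    def test_conjugated_regime_before_censored_after_quantifiable(self):
        # defaults: pure-compound arm conjugates nearly all parent
        p = noise_free()
        srun = TranswellSimulation(p, 3.267, "AB").run_protocol(TIMES)
        before = apply_noise_and_lloq(srun.parent_concentrations(), 0.0,
                                      p.lloq, rng=1)
        after = simulate_deconjugation_assay(srun, 0.0, p.lloq, rng=1)
        assert all(is_censored(v) for v in before)
        assert all(not is_censored(v) for v in after)

    def test_enzyme_dilution_round_trip(self):
        p = noise_free()
        srun = TranswellSimulation(p, 3.267, "AB").run_protocol(TIMES)
        diluted = simulate_deconjugation_assay(srun, 0.0, 0.0, rng=1)
        assert [v * 21.0 / 20.0 for v in diluted] == \
            pytest.approx(srun.total_concentrations())


class TestRegimes:
    def test_passive_symmetry_er_is_one(self):
        sym = TranswellGeometry(volume_apical=10.0, volume_basolateral=10.0,
                                aliquot_apical=0.2, aliquot_basolateral=0.2)
        p = noise_free(conj_vmax=0.0)
        papps = {}
        for d in ("AB", "BA"):
            srun = TranswellSimulation(p, 3.267, d, sym).run_protocol(TIMES)
            run = TransportRun("r", d, 3.267,
                               list(zip(TIMES, srun.parent_concentrations())),
                               geometry=sym)
            papps[d] = analyze_run(run).papp
        assert papps["BA"] / papps["AB"] == pytest.approx(1.0, abs=1e-9)

    def test_saturation_dose_disproportionality(self):
        # with saturable conjugation, doubling the dose less than doubles the
        # total transported amount
        p = noise_free(matrix_factor=3.0, matrix_conj_km_factor=2.0)
        q = {}
        for c0 in (3.2675, 6.535):
            srun = TranswellSimulation(p, c0, "AB").run_protocol(TIMES)
            q[c0] = srun.true_q_total[-1]
        assert q[6.535] < 2.0 * q[3.2675]

    def test_parameter_recovery_sink_regime(self, sink_geometry):
        for papp_true in (1e-6, 5e-6, 1e-5, 5e-5):
            p = noise_free(papp_parent_ab=papp_true, papp_parent_ba=papp_true,
                           conj_vmax=0.0)
            srun = TranswellSimulation(p, 3.267, "AB",
                                       sink_geometry).run_protocol(TIMES)
            run = TransportRun("r", "AB", 3.267,
                               list(zip(TIMES, srun.parent_concentrations())),
                               geometry=sink_geometry)
            res = analyze_run(run)
            assert res.sink_ok
            assert res.papp == pytest.approx(papp_true, rel=0.02)


class TestGenerateStudy:
    def test_schema_and_layout(self, tmp_path):
        out = generate_study(StudyDesign(replicates=2), seed=3,
                             out_dir=tmp_path)
        df = out["transport"]
        assert set(df.columns) == {"run_id", "dose_label", "direction",
                                   "deconjugated", "c0_ug_per_ml", "time_min",
                                   "conc_ug_per_ml", "replicate"}
        # 4 doses × 2 directions × 2 arms × 2 replicates × 4 timepoints
        assert len(df) == 4 * 2 * 2 * 2 * 4
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "teer.csv").exists()

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        generate_study(seed=11, out_dir=a_dir)
        generate_study(seed=11, out_dir=b_dir)
        assert (a_dir / "transport.csv").read_bytes() == \
            (b_dir / "transport.csv").read_bytes()
        assert (a_dir / "truth.json").read_bytes() == \
            (b_dir / "truth.json").read_bytes()

    def test_noise_free_round_trip_matches_truth(self):
        out = generate_study(StudyDesign(replicates=1),
                             SimulationParams(noise_cv=0.0), seed=5)
        truth = out["truth"]
        from permkit import TransportStudy
        results = TransportStudy(out["transport"]).fit()
        t = results.run_table
        for key, tr in truth.items():
            dose, direction = key.split(":")
            sel = t[(t["dose_label"] == dose) & (t["direction"] == direction)
                    & (t["deconjugated"])]
            est = sel["papp_cm_per_s"].iloc[0]
            assert est == pytest.approx(tr["papp_total_true"], rel=0.02)

    def test_extract_arm_params(self):
        base = SimulationParams()
        ext = params_for_arm(base, DoseArm.extract(250.0))
        pure = params_for_arm(base, DoseArm.pure(3.267))
        assert ext.matrix_factor > 1.0 and ext.matrix_conj_km_factor > 1.0
        assert pure.matrix_factor == 1.0 and pure.matrix_conj_km_factor == 1.0

    def test_extract_dose_conversion(self):
        arm = DoseArm.extract(250.0)
        assert arm.c0 == pytest.approx(250.0 * 13.07 / 1000.0)
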