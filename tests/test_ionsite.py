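import numpy as np
import pytest

from iontraj.errors import (
    InsufficientDataError,
    ParameterError,
    SelectionError,
)
from iontraj.geomcore import pair_distance_series
from iontraj.ionsite import (
    BONDING_THRESHOLDS,
    COULOMB_KCAL_A,
    CoordinationSeries,
    NonbondedParams,
    coordination_population,
    coordination_series,
    detect_binding_event,
    gateway_contact_order,
    interaction_energy,
    ligand_distance_table,
)
from iontraj.synthgen import (
    MG_SITE_PRESET,
    gen_binding_approach,
    gen_gateway_path,
    gen_ion_site,
)

from .conftest import make_topology, make_trajectory


@pytest.fixture(scope="module")
def mg_preset_run():
    return gen_ion_site(MG_SITE_PRESET, seed=3)


class TestCoordinationSeries:
    def test_perfect_octahedron(self, octahedron_mg_trajectory):
        series = coordination_series(octahedron_mg_trajectory, 0, cutoff=0.21)
        assert list(series.counts) == [6, 6, 6]

    def test_cutoff_is_strict(self, octahedron_mg_trajectory):
        traj = octahedron_mg_trajectory
        expanded = make_trajectory(traj.topology, traj.coords * 1.1)  # 0.22 nm
        series = coordination_series(expanded, 0, cutoff=0.21)
        assert list(series.counts) == [0, 0, 0]

    def test_exactly_at_cutoff_excluded(self, octahedron_mg_trajectory):
        # strict inequality: a cutoff equal to the actual distance counts 0
        traj = octahedron_mg_trajectory
        distance = float(np.linalg.norm(traj.coords[0, 1] - traj.coords[0, 0]))
        series = coordination_series(traj, 0, cutoff=distance)
        assert list(series.counts) == [0, 0, 0]

    def test_non_ion_index_rejected(self, octahedron_mg_trajectory):
        with pytest.raises(SelectionError):
            coordination_series(octahedron_mg_trajectory, 1, cutoff=0.21)

    def test_stride(self, octahedron_mg_trajectory):
        series = coordination_series(octahedron_mg_trajectory, 0, 0.21, stride=2)
        assert len(series.counts) == 2

    def test_monotone_in_cutoff(self, mg_preset_run):
        traj, _ = mg_preset_run
        cutoffs = [0.15, 0.21, 0.25, 0.35]
        previous = None
        for cutoff in cutoffs:
            counts = coordination_series(traj, 0, cutoff).counts
            if previous is not None:
                assert np.all(counts >= previous)
            previous = counts

    def test_markov_preset_histogram_matches_stationary(self, mg_preset_run):
        traj, manifest = mg_preset_run
        series = coordination_series(traj, 0, MG_SITE_PRESET.cutoff)
        pop = coordination_population(series).percentages
        for cn_str, prob in manifest.expectations["cn_stationary"].items():
            assert pop.get(int(cn_str), 0.0) == pytest.approx(100 * prob, abs=3.0)

    def test_stationary_total_variation(self, mg_preset_run):
        traj, manifest = mg_preset_run
        series = coordination_series(traj, 0, MG_SITE_PRESET.cutoff)
        pop = coordination_population(series).percentages
        expected = {int(k): 100 * v
                    for k, v in manifest.expectations["cn_stationary"].items()}
        keys = set(pop) | set(expected)
        tv = 0.5 * sum(abs(pop.get(k, 0) - expected.get(k, 0)) for k in keys) / 100
        assert tv < 0.03


class TestCoordinationPopulation:
    def test_constant_count(self):
        series = CoordinationSeries(ion=0, species="MG", cutoff=0.21,
                                    times=np.arange(5.0), counts=[6] * 5)
        assert coordination_population(series).percentages == {6: 100.0}

    def test_alternating(self):
        series = CoordinationSeries(ion=0, species="MG", cutoff=0.21,
                                    times=np.arange(6.0),
                                    counts=[5, 6, 5, 6, 5, 6])
        pop = coordination_population(series).percentages
        assert pop == {5: 50.0, 6: 50.0}

    def test_empty_series_rejected(self):
        series = CoordinationSeries(ion=0, species="MG", cutoff=0.21,
                                    times=np.array([]), counts=np.array([], dtype=int))
        with pytest.raises(InsufficientDataError):
            coordination_population(series)

    def test_mg_preset_cn6_near_80(self, mg_preset_run):
        traj, _ = mg_preset_run
        series = coordination_series(traj, 0, MG_SITE_PRESET.cutoff)
        pop = coordination_population(series).percentages
        assert pop[6] == pytest.approx(80.0, abs=3.0)


class TestLigandDistanceTable:
    def test_static_bonded_row(self, octahedron_mg_trajectory):
        table = ligand_distance_table(octahedron_mg_trajectory, 0,
                                      "element O", "MG")
        row = table.rows[table.rows["atom_name"] == "OE1"].iloc[0]
        assert row["mean_nm"] == pytest.approx(0.20)
        assert row["sd_nm"] == pytest.approx(0.0, abs=1e-12)
        assert bool(row["bonded"]) is True

    def test_nonbonded_filtered(self):
        top = make_topology([("MG", "MG", "MG", 1001), ("OE1", "O", "GLU", 771)])
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 0.25
        traj = make_trajectory(top, coords)
        table = ligand_distance_table(traj, 0, "element O", "MG")
        assert not bool(table.rows.iloc[0]["bonded"])
        assert len(table.bonded_only()) == 0

    def test_threshold_table_values(self):
        assert BONDING_THRESHOLDS == {"MG": 0.21, "K": 0.30, "CA": 0.25}

    def test_unknown_species(self, octahedron_mg_trajectory):
        with pytest.raises(ParameterError):
            ligand_distance_table(octahedron_mg_trajectory, 0, "element O", "NA")

    def test_preset_mean_recovery(self, mg_preset_run):
        traj, manifest = mg_preset_run
        table = ligand_distance_table(traj, 0, "element O", "MG")
        expected = manifest.expectations["expected_ligand_means_nm"]
        for _, row in table.rows.iterrows():
            key = f"{row['residue']}:{row['atom_name']}"
            assert row["mean_nm"] == pytest.approx(expected[key], abs=0.005)

    def test_target_distance_recovery_within_5_thousandths(self, mg_preset_run):
        # ligands present in (almost) every frame recover their targets
        traj, _ = mg_preset_run
        table = ligand_distance_table(traj, 0, "element O", "MG")
        oe1 = table.rows[(table.rows["resid"] == 771)
                         & (table.rows["atom_name"] == "OE1")].iloc[0]
        assert oe1["mean_nm"] == pytest.approx(0.20, abs=0.005)
        assert bool(oe1["bonded"]) is True

    def test_sorted_by_resid(self, mg_preset_run):
        traj, _ = mg_preset_run
        table = ligand_distance_table(traj, 0, "element O", "MG")
        assert list(table.rows["resid"]) == sorted(table.rows["resid"])

    def test_means_match_pair_distance_series(self, octahedron_mg_trajectory):
        # cross-module consistency with geomcore
        traj = octahedron_mg_trajectory
        table = ligand_distance_table(traj, 0, "element O", "MG")
        series = pair_distance_series(traj, "resname MG",
                                      "resid 771 and name OE2")
        row = table.rows[table.rows["atom_name"] == "OE2"].iloc[0]
        assert row["mean_nm"] == pytest.approx(series.mean, abs=1e-12)


class TestBindingEvent:
    def test_inside_from_start(self):
        traj = gen_binding_approach(entry_frame=0, frames=50)
        event = detect_binding_event(traj, 1, "name OD1", cutoff=0.30, dwell=5)
        assert event is not None
        assert event.t_on == traj.times[0]

    def test_never_inside(self):
        traj = gen_binding_approach(entry_frame=0, frames=50)
        event = detect_binding_event(traj, 1, "name OD1", cutoff=0.01, dwell=5)
        assert event is None

    def test_scripted_entry_frame_70(self):
        traj = gen_binding_approach(entry_frame=70, frames=1000, frame_dt=0.001)
        event = detect_binding_event(traj, 1, "name OD1", cutoff=0.30, dwell=10)
        assert event is not None
        assert event.t_on == pytest.approx(0.07, abs=1e-12)
        assert event.sustained

    def test_empty_site_selection(self):
        traj = gen_binding_approach(entry_frame=0, frames=10)
        with pytest.raises(SelectionError):
            detect_binding_event(traj, 1, "resid 12345", cutoff=0.3, dwell=1)

    def test_dwell_filters_short_visits(self):
        top = make_topology([("OD1", "O", "ASP", 800), ("K", "K", "POT", 2001)])
        coords = np.zeros((20, 2, 3))
        coords[:, 1, 0] = 1.0
        coords[5, 1, 0] = 0.1  # single-frame visit
        coords[10:, 1, 0] = 0.1  # sustained from frame 10
        traj = make_trajectory(top, coords, frame_dt=0.001)
        event = detect_binding_event(traj, 1, "name OD1", cutoff=0.3, dwell=3)
        assert event.t_on == pytest.approx(0.010)


class TestGatewayContacts:
    def test_scripted_order(self):
        traj = gen_gateway_path(gateway_resids=(55, 58, 59, 109))
        ion = traj.n_atoms - 1
        contacts = gateway_contact_order(traj, ion, [55, 58, 59, 109],
                                         contact_cutoff=0.3)
        assert [resid for resid, _ in contacts] == [55, 58, 59, 109]
        times = [t for _, t in contacts]
        assert times == sorted(times)
        assert len(set(times)) == len(times)

    def test_far_ion_empty(self):
        traj = gen_gateway_path(gateway_resids=(55, 58))
        ion = traj.n_atoms - 1
        contacts = gateway_contact_order(traj, ion, [55, 58],
                                         contact_cutoff=0.0001)
        assert contacts == []

    def test_shuffled_input_order_sorted_by_time(self):
        traj = gen_gateway_path(gateway_resids=(55, 58, 59, 109))
        ion = traj.n_atoms - 1
        contacts = gateway_contact_order(traj, ion, [109, 55, 59, 58],
                                         contact_cutoff=0.3)
        assert [resid for resid, _ in contacts] == [55, 58, 59, 109]


class TestInteractionEnergy:
    def _two_atom_traj(self, distance_nm):
        top = make_topology([("MG", "MG", "MG", 1001), ("OE1", "O", "GLU", 771)])
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = distance_nm
        return make_trajectory(top, coords)

    def test_zero_charge_far_partner(self):
        traj = self._two_atom_traj(2.5)
        params = NonbondedParams(charges={0: 0.0, 1: -1.0})
        mean, _ = interaction_energy(traj, 0, "name OE1", params, include_lj=False)
        assert abs(mean) < 0.01

    def test_coulomb_closed_form(self):
        # q1=+2, q2=-1 at 0.30 nm (3 A), dielectric 1, LJ off:
        # E = 332.0636 * 2 * (-1) / 3 = -221.37573... kcal/mol
        traj = self._two_atom_traj(0.30)
        params = NonbondedParams(charges={0: 2.0, 1: -1.0})
        mean, series = interaction_energy(traj, 0, "name OE1", params,
                                          include_lj=False)
        assert mean == pytest.approx(COULOMB_KCAL_A * 2 * -1 / 3.0, rel=1e-12)
        assert len(series) == 3

    def test_dielectric_scales(self):
        traj = self._two_atom_traj(0.30)
        p1 = NonbondedParams(charges={0: 2.0, 1: -1.0}, dielectric=1.0)
        p4 = NonbondedParams(charges={0: 2.0, 1: -1.0}, dielectric=4.0)
        e1, _ = interaction_energy(traj, 0, "name OE1", p1, include_lj=False)
        e4, _ = interaction_energy(traj, 0, "name OE1", p4, include_lj=False)
        assert e4 == pytest.approx(e1 / 4)

    def test_symmetric_pair_additivity(self):
        top = make_topology([
            ("MG", "MG", "MG", 1001),
            ("OE1", "O", "GLU", 771),
            ("OE2", "O", "GLU", 771),
        ])
        coords = np.zeros((2, 3, 3))
        coords[:, 1, 0] = 0.30
        coords[:, 2, 0] = -0.30
        traj = make_trajectory(top, coords)
        params = NonbondedParams(charges={0: 2.0, 1: -1.0, 2: -1.0})
        both, _ = interaction_energy(traj, 0, "element O", params, include_lj=False)
        one, _ = interaction_energy(traj, 0, "name OE1", params, include_lj=False)
        assert both == pytest.approx(2 * one, rel=1e-12)

    def test_additive_over_disjoint_selections(self):
        traj, _ = gen_ion_site(MG_SITE_PRESET, seed=9)
        charges = {i: -0.8 for i in range(traj.n_atoms)}
        charges[0] = 2.0
        params = NonbondedParams(charges=charges)
        total, _ = interaction_energy(traj, 0, "element O", params, include_lj=False)
        part_a, _ = interaction_energy(traj, 0, "element O and resid 771",
                                       params, include_lj=False)
        part_b, _ = interaction_energy(traj, 0, "element O and not resid 771",
                                       params, include_lj=False)
        assert total == pytest.approx(part_a + part_b, rel=1e-9)

    def test_linear_in_ion_charge(self):
        traj = self._two_atom_traj(0.30)
        e1, _ = interaction_energy(traj, 0, "name OE1",
                                   NonbondedParams(charges={0: 1.0, 1: -1.0}),
                                   include_lj=False)
        e3, _ = interaction_energy(traj, 0, "name OE1",
                                   NonbondedParams(charges={0: 3.0, 1: -1.0}),
                                   include_lj=False)
        assert e3 == pytest.approx(3 * e1, rel=1e-12)

    def test_lj_minimum_at_rmin(self):
        # at r = rmin_ij the LJ term equals -eps_ij
        traj = self._two_atom_traj(0.30)
        params = NonbondedParams(charges={0: 0.0, 1: 0.0},
                                 epsilon={0: 0.1, 1: 0.4},
                                 rmin={0: 0.3, 1: 0.3})
        mean, _ = interaction_energy(traj, 0, "name OE1", params)
        assert mean == pytest.approx(-np.sqrt(0.1 * 0.4), rel=1e-9)

    def test_missing_parameter_names_atom(self):
        traj = self._two_atom_traj(0.30)
        params = NonbondedParams(charges={0: 2.0})
        with pytest.raises(ParameterError) as err:
            interaction_energy(traj, 0, "name OE1", params)
        assert "GLU771 OE1" in str(err.value)

    def test_params_from_table(self, tmp_path):
        traj = self._two_atom_traj(0.30)
        path = tmp_path / "params.tsv"
        path.write_text(
            "# selection\tcharge\teps\trmin\n"
            "resname MG\t2.0\t0.0015\t0.1185\n"
            "element O\t-1.0\t0.12\t0.17\n"
        )
        params = NonbondedParams.from_table(path, traj.topology)
        assert params.charges[0] == 2.0
        assert params.charges[1] == -1.0
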