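import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frenetmap as fm
from frenetmap.frames import FrenetFrame, SphericalDirection, build_frenet_frames
from frenetmap.maps_stats import StratumKey
from frenetmap.reconstruction import (
    PlacementEntry,
    PlacementLibrary,
    build_placement_library,
    decode_atom,
    encode_atom,
    reconstruct_chain,
)


def _frame():
    return FrenetFrame(
        origin=np.array([1.0, -2.0, 0.5]),
        t=np.array([0.0, 0.0, 1.0]),
        n=np.array([1.0, 0.0, 0.0]),
        b=np.array([0.0, 1.0, 0.0]),
    )


class TestEncodeDecode:
    def test_axis_points(self):
        f = _frame()
        d, r = encode_atom(f, f.origin + 2.0 * f.t)
        assert (d.latitude, r) == pytest.approx((0.0, 2.0))
        assert np.allclose(decode_atom(f, SphericalDirection(0.0, 0.0), 2.0),
                           f.origin + 2.0 * f.t, atol=1e-12)
        assert np.allclose(decode_atom(f, SphericalDirection(math.pi / 2, 0.0), 1.5),
                           f.origin + 1.5 * f.n, atol=1e-12)

    @given(
        st.floats(0.01, math.pi - 0.01),
        st.floats(-math.pi + 1e-6, math.pi),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bijection_property(self, lat, lon, radius):
        f = _frame()
        coord = decode_atom(f, SphericalDirection(lat, lon), radius)
        d, r = encode_atom(f, coord)
        assert r == pytest.approx(radius, abs=1e-9)
        assert d.latitude == pytest.approx(lat, abs=1e-9)
        assert d.longitude == pytest.approx(lon, abs=1e-9)

    def test_round_trip_on_real_atoms(self, helix_chain):
        frames = fm.chain_frenet_frames(helix_chain)
        for res, f in zip(helix_chain.residues, frames):
            if f is None:
                continue
            for atom in res.atoms:
                if atom.name == "CA":
                    continue
                d, r = encode_atom(f, atom.coord)
                assert np.allclose(decode_atom(f, d, r), atom.coord, atol=1e-9)

    def test_next_ca_radius_is_virtual_bond(self, helix_trace):
        frames = build_frenet_frames(helix_trace)
        _, r = encode_atom(frames[1], helix_trace[2])
        assert r == pytest.approx(3.804, abs=0.01)

    def test_zero_radius_rejected(self):
        f = _frame()
        with pytest.raises(ValueError):
            decode_atom(f, SphericalDirection(1.0, 0.0), 0.0)
        with pytest.raises(ValueError):
            encode_atom(f, f.origin)


class TestPlacementLibrary:
    def test_unreachable_support_raises(self, training_chains):
        with pytest.raises(ValueError, match="min_support"):
            build_placement_library(
                training_chains, levels=("beta",), n_lat=30, n_lon=60, min_support=10**6
            )

    def test_small_stratum_absent(self, training_chains):
        lib = build_placement_library(
            training_chains, levels=("beta",), n_lat=30, n_lon=60, min_support=20
        )
        sizes = [e.n for e in lib.entries.values()]
        assert min(sizes) >= 20

    def test_mode_recovery_within_one_cell(self, training_chains):
        """Library modes recover the generating directions within a grid cell."""
        n_lat, n_lon = 60, 120
        lib = build_placement_library(
            training_chains,
            levels=("backbone-N", "backbone-C", "backbone-O", "beta", "gamma"),
            n_lat=n_lat, n_lon=n_lon, min_support=20,
        )
        # generating directions measured on a noise-free chain
        clean = fm.generate_ideal_backbone(
            fm.generate_trace(fm.HelixParams(n_residues=30)),
            resnames="LEU", chi1_deg=-60.0, chi2_deg=175.0, ss_label="helix",
        )
        obs = fm.collect_observations([clean], "beta")
        true_lat = obs["latitude"].median()
        true_lon = obs["longitude"].median()
        entry, depth = lib.lookup(
            StratumKey(atom_level="beta", atom_name="CB", residue_class="LEU", ss="helix")
        )
        assert entry is not None and depth == 0
        cell_lat = 2.5 * math.pi / n_lat  # generous: a couple of cells
        assert abs(entry.modal_direction.latitude - true_lat) < cell_lat
        assert abs(entry.modal_direction.longitude - true_lon) < 2.5 * 2 * math.pi / n_lon

    def test_helix_and_strand_O_modes_differ(self, training_chains):
        """Backbone O placement depends strongly on secondary structure."""
        lib = build_placement_library(
            training_chains, levels=("backbone-O",), n_lat=45, n_lon=90, min_support=20
        )
        e_h, _ = lib.lookup(StratumKey(atom_level="backbone-O", atom_name="O",
                                       residue_class="LEU", ss="helix"))
        e_s, _ = lib.lookup(StratumKey(atom_level="backbone-O", atom_name="O",
                                       residue_class="LEU", ss="strand"))
        v1, v2 = e_h.modal_direction.as_vector(), e_s.modal_direction.as_vector()
        assert math.degrees(math.acos(np.clip(v1 @ v2, -1, 1))) > 15

    def test_fallback_order(self):
        lib = PlacementLibrary()
        generic = PlacementEntry(
            StratumKey(atom_level="gamma", atom_name="CG", residue_class="LEU"),
            SphericalDirection(1.0, 1.0), 1.5, 0.9, 100,
        )
        lib.add(generic)
        key = StratumKey(atom_level="gamma", atom_name="CG", residue_class="LEU",
                         ss="helix", rotamer="t")
        entry, depth = lib.lookup(key)
        assert entry is generic and depth == 3  # dropped rotamer, context, ss
        missing, depth = lib.lookup(StratumKey(atom_level="eta", atom_name="NH2"))
        assert missing is None and depth == -1

    def test_json_round_trip(self, training_chains, tmp_path):
        lib = build_placement_library(training_chains, levels=("beta",),
                                      n_lat=20, n_lon=40, min_support=20)
        p = tmp_path / "lib.json"
        lib.save(p)
        again = PlacementLibrary.load(p)
        assert set(again.entries) == set(lib.entries)
        k = next(iter(lib.entries))
        assert again.entries[k].mean_radius == pytest.approx(lib.entries[k].mean_radius)


@pytest.fixture(scope="module")
def library(training_chains):
    return build_placement_library(
        training_chains,
        levels=("backbone-N", "backbone-C", "backbone-O", "beta", "gamma", "delta"),
        n_lat=60, n_lon=120, min_support=20,
    )


class TestReconstruction:

    def test_self_consistency_rmsd(self, library):
        tr = fm.generate_trace(fm.HelixParams(n_residues=30))
        truth = fm.generate_ideal_backbone(tr, resnames="LEU", chi1_deg=-60.0,
                                           chi2_deg=175.0, ss_label="helix")
        res = reconstruct_chain(tr, ["LEU"] * 30, ["helix"] * 30, library, truth=truth)
        assert res.rmsd_by_atom
        for atom, rmsd in res.rmsd_by_atom.items():
            assert rmsd < 0.35, (atom, rmsd)

    def test_rmsd_decreases_with_grid_refinement(self, training_chains):
        tr = fm.generate_trace(fm.HelixParams(n_residues=30))
        truth = fm.generate_ideal_backbone(tr, resnames="LEU", chi1_deg=-60.0,
                                           chi2_deg=175.0, ss_label="helix")
        rmsds = []
        for n_lat in (12, 24, 48):
            lib = build_placement_library(
                training_chains, levels=("backbone-N", "backbone-C", "backbone-O", "beta"),
                n_lat=n_lat, n_lon=2 * n_lat, min_support=20,
            )
            r = reconstruct_chain(tr, ["LEU"] * 30, ["helix"] * 30, lib, truth=truth)
            rmsds.append(np.mean(list(r.rmsd_by_atom.values())))
        assert rmsds[2] < rmsds[0] + 0.02  # non-increasing within noise
        assert rmsds[2] < 0.3

    def test_equivariance_under_rigid_motion(self, library):
        tr = fm.generate_trace(fm.HelixParams(n_residues=20))
        res1 = reconstruct_chain(tr, ["LEU"] * 20, ["helix"] * 20, library)
        rng = np.random.default_rng(5)
        from frenetmap.geometry import random_rotation

        R, tvec = random_rotation(rng), rng.normal(size=3) * 8
        tr2 = tr @ R.T + tvec
        res2 = reconstruct_chain(tr2, ["LEU"] * 20, ["helix"] * 20, library)
        for r1, r2 in zip(res1.chain.residues, res2.chain.residues):
            for a1 in r1.atoms:
                a2 = r2.atom(a1.name)
                assert a2 is not None
                assert np.allclose(R @ a1.coord + tvec, a2.coord, atol=1e-9)

    def test_gly_gets_no_cb(self, library):
        tr = fm.generate_trace(fm.HelixParams(n_residues=10))
        res = reconstruct_chain(tr, ["GLY"] * 10, ["helix"] * 10, library)
        for r in res.chain.residues:
            assert r.atom("CB") is None

    def test_placed_radii_equal_library_means(self, library):
        tr = fm.generate_trace(fm.HelixParams(n_residues=10))
        res = reconstruct_chain(tr, ["LEU"] * 10, ["helix"] * 10, library)
        frames = build_frenet_frames(tr)
        for r, f in zip(res.chain.residues, frames):
            if f is None:
                continue
            cb = r.atom("CB")
            if cb is None:
                continue
            entry, _ = library.lookup(
                StratumKey(atom_level="beta", atom_name="CB",
                           residue_class="LEU", ss="helix")
            )
            assert np.linalg.norm(cb.coord - f.origin) == pytest.approx(
                entry.mean_radius, abs=1e-9
            )

    def test_provenance_and_termini(self, library):
        tr = fm.generate_trace(fm.HelixParams(n_residues=10))
        res = reconstruct_chain(tr, ["LEU"] * 10, ["helix"] * 10, library)
        assert len(res.chain.residues[0].atoms) == 1  # terminal: CA only
        assert all("stratum" in p and "fallback_depth" in p for p in res.provenance)

    def test_short_trace_rejected(self, library):
        with pytest.raises(ValueError):
            reconstruct_chain(np.zeros((2, 3)), ["ALA"] * 2, ["loop"] * 2, library)
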