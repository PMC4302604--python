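import math

import numpy as np
import pytest

import frenetmap as fm
from frenetmap.frames import (
    SphericalDirection,
    backbone_kappa_tau,
    build_frenet_frames,
    build_side_chain_frame,
    chain_frenet_frames,
    chi1_frame,
    chi_dihedral,
    dihedral_angle,
    direction_in_frame,
    ramachandran,
    zx_frame,
)
from frenetmap.geometry import random_rotation, unit
from frenetmap.synthetic import apply_rigid_transform, reflect_coords

SQUARE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)


def oracle_frames_kappa_tau(points):
    """Independent brute-force evaluation of the frame and angle definitions
    on raw points (kept free of the library code paths)."""
    points = np.asarray(points, float)
    t = [None] * len(points)
    b = [None] * len(points)
    for i in range(len(points) - 1):
        d = points[i + 1] - points[i]
        t[i] = d / np.linalg.norm(d)
    for i in range(1, len(points) - 1):
        c = np.cross(t[i - 1], t[i])
        b[i] = c / np.linalg.norm(c)
    kappa, tau = {}, {}
    for i in range(2, len(points) - 1):
        kappa[i] = math.acos(np.clip(t[i - 1] @ t[i], -1, 1))
        mag = math.acos(np.clip(b[i - 1] @ b[i], -1, 1))
        s = np.cross(b[i - 1], b[i]) @ t[i - 1]
        tau[i] = math.copysign(mag, s) if s != 0 else mag
    return t, b, kappa, tau


class TestFrenetFrames:
    def test_square_trace_hand_values(self):
        frames = build_frenet_frames(SQUARE)
        f = frames[1]
        assert np.allclose(f.t, [0, 1, 0], atol=1e-12)
        assert np.allclose(f.b, [0, 0, 1], atol=1e-12)
        assert np.allclose(f.n, [-1, 0, 0], atol=1e-12)
        ang = backbone_kappa_tau(frames)
        assert ang.kappa[2] == pytest.approx(math.pi / 2, abs=1e-12)
        assert ang.tau[2] == pytest.approx(0.0, abs=1e-12)

    def test_every_frame_right_handed_orthonormal(self, helix_trace):
        rng = np.random.default_rng(2)
        traces = [helix_trace] + [rng.normal(size=(12, 3)) * 3 for _ in range(10)]
        for tr in traces:
            for f in build_frenet_frames(tr):
                if f is None:
                    continue
                M = f.axes()
                assert np.allclose(M @ M.T, np.eye(3), atol=1e-9)
                assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-9)

    def test_helix_matches_brute_force_oracle(self, helix_trace):
        _, _, k_or, t_or = oracle_frames_kappa_tau(helix_trace)
        ang = backbone_kappa_tau(build_frenet_frames(helix_trace))
        for i, v in k_or.items():
            assert ang.kappa[i] == pytest.approx(v, abs=1e-12)
        for i, v in t_or.items():
            assert ang.tau[i] == pytest.approx(v, abs=1e-12)

    def test_helix_kappa_tau_constant_and_in_alpha_annulus(self, helix_trace):
        ang = backbone_kappa_tau(build_frenet_frames(helix_trace))
        k = ang.kappa[~np.isnan(ang.kappa)]
        t = ang.tau[~np.isnan(ang.tau)]
        assert k.std() < 1e-9 and t.std() < 1e-9
        # the backbone map annulus: kappa roughly between 1 and 3/2
        assert 0.9 < k.mean() < 1.65
        assert 0.5 < t.mean() < 1.2  # right-handed alpha region

    def test_too_short_or_coincident_raise(self):
        with pytest.raises(ValueError, match="too short"):
            build_frenet_frames(SQUARE[:2])
        bad = SQUARE.copy()
        bad[1] = bad[0]
        with pytest.raises(ValueError):
            build_frenet_frames(bad)

    def test_collinear_trace_flagged_with_transported_binormal(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        frames = build_frenet_frames(line)
        inner = [f for f in frames if f is not None]
        assert inner and all(f.flagged for f in inner)
        for f in inner:
            M = f.axes()
            assert np.allclose(M @ M.T, np.eye(3), atol=1e-9)
        ang = backbone_kappa_tau(frames)
        assert np.all(np.isnan(ang.tau[2:-1]))  # tau undefined when flagged


class TestDirectionInFrame:
    def setup_method(self):
        self.frame = fm.FrenetFrame(
            origin=np.zeros(3),
            t=np.array([0.0, 0.0, 1.0]),
            n=np.array([1.0, 0.0, 0.0]),
            b=np.array([0.0, 1.0, 0.0]),
        )

    def test_north_pole_and_axes(self):
        d = direction_in_frame(self.frame, np.array([0, 0, 2.0]))
        assert d.latitude == pytest.approx(0.0, abs=1e-12)
        d = direction_in_frame(self.frame, np.array([1.0, 0, 0]))
        assert (d.latitude, d.longitude) == pytest.approx((math.pi / 2, 0.0))
        d = direction_in_frame(self.frame, np.array([0, 1.0, 0]))
        assert d.longitude == pytest.approx(math.pi / 2)  # counter-clockwise about t

    def test_translate_keeps_axes_fixed(self):
        d = direction_in_frame(
            self.frame, np.array([5.0, 1.0, 0.0]), translate_to=np.array([4.0, 1.0, 0.0])
        )
        assert (d.latitude, d.longitude) == pytest.approx((math.pi / 2, 0.0))

    def test_zero_direction_raises(self):
        with pytest.raises(ValueError):
            direction_in_frame(self.frame, np.zeros(3))

    def test_ca_map_direction_equals_kappa_tau(self, helix_trace):
        # translating the observer to the next CA and sighting t_{i+1}
        # reproduces (kappa_{i+1}, tau_{i+1}) of the backbone map
        frames = build_frenet_frames(helix_trace)
        ang = backbone_kappa_tau(frames)
        for i in range(1, len(helix_trace) - 2):
            if frames[i] is None or frames[i + 1] is None:
                continue
            d = direction_in_frame(
                frames[i], helix_trace[i + 2], translate_to=helix_trace[i + 1]
            )
            assert d.latitude == pytest.approx(ang.kappa[i + 1], abs=1e-9)
            assert d.longitude == pytest.approx(ang.tau[i + 1], abs=1e-9)


class TestSideChainFrames:
    def test_chi1_longitude_equals_dihedral_oracle(self, helix_chain):
        for res in helix_chain.residues:
            f = build_side_chain_frame(res, "chi1")
            cg = res.coord("CG")
            if f is None or cg is None:
                continue
            lon = direction_in_frame(f, cg).longitude
            assert lon == pytest.approx(chi_dihedral(res, 1), abs=1e-9)

    def test_chi1_longitude_equals_dihedral_on_random_geometry(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, ca, cb, cg = rng.normal(size=(4, 3)) * 2
            try:
                f = chi1_frame(n, ca, cb)
                lon = direction_in_frame(f, cg).longitude
                want = dihedral_angle(n, ca, cb, cg)
            except ValueError:
                continue
            assert lon == pytest.approx(want, abs=1e-9)

    def test_planar_anti_gamma_longitude_is_pi(self):
        n = np.array([0.0, 1.0, 0.0])
        ca = np.zeros(3)
        cb = np.array([1.5, 0.0, 0.0])
        cg = cb + np.array([0.5, -1.0, 0.0])  # anti to N across the CA-CB axis
        f = chi1_frame(n, ca, cb)
        assert abs(direction_in_frame(f, cg).longitude) == pytest.approx(math.pi)

    def test_zx_frame_degenerate_when_parallel(self):
        t_a = np.array([0.0, 0.0, 1.0])
        assert zx_frame(np.zeros(3), np.array([0, 0, 1.5]), t_a) is None

    def test_delta_frame_uses_gamma_bonded_to_delta(self, helix_chain):
        # LEU path: CB -> CG -> CD1; the delta frame is anchored on CB->CG
        res = helix_chain.residues[5]
        bb = chain_frenet_frames(helix_chain)[5]
        f = build_side_chain_frame(res, "delta", backbone_tangent=bb.t)
        assert f is not None
        assert np.allclose(f.origin, res.coord("CG"))
        assert np.allclose(f.t, unit(res.coord("CG") - res.coord("CB")))


class TestInvarianceProperties:
    def test_rigid_motion_invariance(self, helix_chain):
        """kappa, tau, spherical directions, phi/psi and chi longitudes are
        unchanged by any proper rigid motion of all coordinates."""
        chain2 = _transform_chain(helix_chain, seed=42)
        a1 = fm.chain_kappa_tau(helix_chain)
        a2 = fm.chain_kappa_tau(chain2)
        assert np.allclose(a1.kappa, a2.kappa, atol=1e-9, equal_nan=True)
        assert np.allclose(a1.tau, a2.tau, atol=1e-9, equal_nan=True)
        p1, s1 = ramachandran(helix_chain)
        p2, s2 = ramachandran(chain2)
        assert _circ_close(p1, p2)
        assert _circ_close(s1, s2)
        o1 = fm.collect_observations([helix_chain], "beta")
        o2 = fm.collect_observations([chain2], "beta")
        assert np.allclose(o1["latitude"], o2["latitude"], atol=1e-9)
        assert np.allclose(o1["longitude"], o2["longitude"], atol=1e-9)

    def test_reflection_negates_tau_and_longitudes(self, helix_chain):
        chain2 = _reflect_chain(helix_chain)
        a1 = fm.chain_kappa_tau(helix_chain)
        a2 = fm.chain_kappa_tau(chain2)
        assert np.allclose(a1.kappa, a2.kappa, atol=1e-9, equal_nan=True)
        assert np.allclose(a1.tau, -a2.tau, atol=1e-9, equal_nan=True)
        o1 = fm.collect_observations([helix_chain], "beta")
        o2 = fm.collect_observations([chain2], "beta")
        assert np.allclose(o1["latitude"], o2["latitude"], atol=1e-9)
        assert np.allclose(o1["longitude"], -o2["longitude"], atol=1e-9)

    def test_opposite_handedness_helices_have_opposite_tau(self):
        right = fm.generate_trace(fm.HelixParams(n_residues=12, handedness=1))
        left = fm.generate_trace(fm.HelixParams(n_residues=12, handedness=-1))
        ar = backbone_kappa_tau(build_frenet_frames(right))
        al = backbone_kappa_tau(build_frenet_frames(left))
        assert np.allclose(ar.kappa, al.kappa, atol=1e-9, equal_nan=True)
        assert np.allclose(ar.tau, -al.tau, atol=1e-9, equal_nan=True)


class TestRamachandran:
    def test_termini_undefined(self, helix_chain):
        phi, psi = ramachandran(helix_chain)
        assert math.isnan(phi[0]) and math.isnan(psi[-1])

    def test_extended_geometry_is_180_180(self):
        chain = fm.backbone_from_dihedrals([180.0] * 6, 180.0, 180.0)
        phi, psi = ramachandran(chain)
        for i in range(1, 5):
            assert abs(math.degrees(phi[i])) == pytest.approx(180.0, abs=1e-6)
            assert abs(math.degrees(psi[i])) == pytest.approx(180.0, abs=1e-6)

    def test_ideal_helix_backbone_in_alpha_region(self, helix_chain):
        phi, psi = ramachandran(helix_chain)
        phi = np.degrees(phi[2:-2])
        psi = np.degrees(psi[2:-2])
        assert np.all((phi > -120) & (phi < -20))
        assert np.all((psi > -90) & (psi < 10))


def _circ_close(a, b, atol=1e-9):
    """Angular arrays equal modulo 2 pi (NaNs must coincide)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(np.isnan(a), np.isnan(b)):
        return False
    d = np.angle(np.exp(1j * (a - b)))
    return bool(np.all(np.abs(d[~np.isnan(d)]) < atol))


def _transform_chain(chain, seed):
    import copy

    out = copy.deepcopy(chain)
    rng = np.random.default_rng(seed)
    R = random_rotation(rng)
    tvec = rng.normal(size=3) * 5
    for res in out.residues:
        for a in res.atoms:
            a.coord = R @ a.coord + tvec
    return out


def _reflect_chain(chain):
    import copy

    out = copy.deepcopy(chain)
    for res in out.residues:
        for a in res.atoms:
            a.coord = reflect_coords(a.coord)
    return out
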