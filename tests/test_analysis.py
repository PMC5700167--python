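"""Density profiles, order parameters, Voronoi areas, cholesterol metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from conftest import bare_frame
from memcurve.analysis import (
    EmptyGroupError,
    ExplicitHydrogensError,
    _voronoi_cell_area,
    aggregate_apl,
    areas_per_lipid,
    cholesterol_metrics,
    default_groups,
    density_profiles,
    order_parameters,
)
from memcurve.config import Config, SpeciesMap, default_config
from memcurve.fixtures import FixtureSpec, make_membrane_fixture
from memcurve.geometry import SectorSpec, make_surface, sector_mask
from memcurve.system import Composition, NamingConventionError


# ------------------------------------------------------------------ density


class TestDensityProfiles:
    def test_uniform_slab_is_flat(self):
        rng = np.random.default_rng(0)
        n = 40000
        pos = np.column_stack([
            rng.uniform(-5, 5, n), rng.uniform(-5, 5, n), rng.uniform(-2, 2, n)])
        frame = bare_frame(pos)
        surf = make_surface(0.0)
        bw = 0.2
        prof = density_profiles([frame], surf, {"all": np.ones(n, bool)},
                                bin_width=bw, weighting="number",
                                split_leaflets=False)
        dens = prof.profiles[("all", "all")]
        core = dens[2:-2]  # edge bins may be partially filled by binning snap
        expected = 1.0 / 4.0
        per_bin = n * expected * bw
        sigma = np.sqrt(per_bin) / (n * bw)
        assert np.all(np.abs(core - expected) < 3.5 * sigma)

    def test_cylindrical_shell_peaks_at_its_depth(self):
        rng = np.random.default_rng(1)
        surf = make_surface(0.2)
        n = 5000
        ang = rng.uniform(-1.0, 1.0, n)
        r = surf.radius + 1.75
        cx, cz = surf.center
        pos = np.column_stack([
            cx + r * np.sin(ang), rng.uniform(-3, 3, n), cz + r * np.cos(ang)])
        frame = bare_frame(pos)
        prof = density_profiles([frame], surf, {"shell": np.ones(n, bool)},
                                bin_width=0.05, split_leaflets=False)
        assert prof.peak_depth(("shell", "all")) == pytest.approx(1.75, abs=0.05)

    def test_unit_integral(self):
        spec = FixtureSpec(seed=4, composition=Composition(
            {"PC": (30, 30), "CHOL": (10, 10)}), n_rows=5)
        frame, _ = make_membrane_fixture(spec)
        surf = make_surface(0.0)
        prof = density_profiles([frame], surf, default_groups(frame),
                                bin_width=0.05)
        for key in prof.profiles:
            assert prof.integral(key) == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_rejected(self):
        frame = bare_frame([[0, 0, 0]])
        with pytest.raises(EmptyGroupError):
            density_profiles([frame], make_surface(0.0),
                             {"none": np.zeros(1, bool)})


# --------------------------------------------------------- order parameters


def ch_frame(vectors, normal_axis=2):
    """One-carbon pseudo-lipids with prescribed C-H unit vectors."""
    n = len(vectors)
    names, resnames, resids, elements, leaflet, pos = [], [], [], [], [], []
    for k, v in enumerate(vectors):
        base = np.array([(k % 200) * 0.5, (k // 200) * 0.5, 1.0])
        for nm, el, p in [("P", "P", base + [0, 0, 0.5]),
                          ("C2A", "C", base),
                          ("H2A1", "H", base + 0.109 * np.asarray(v)),
                          ("H2A2", "H", base - 0.109 * np.asarray(v))]:
            names.append(nm)
            resnames.append("PC")
            resids.append(k + 1)
            elements.append(el)
            leaflet.append("outer")
            pos.append(p)
    return bare_frame(pos, names=names, resnames=resnames, resids=resids,
                      elements=elements, leaflet=leaflet)


@pytest.fixture
def short_chain_config():
    cfg = default_config()
    cfg.species = {"PC": SpeciesMap(last_carbon=2)}
    return cfg


class TestOrderParameters:
    def test_all_trans_aligned_chain(self):
        """C-H perpendicular to the normal at every carbon -> S_CD = -0.5."""
        spec = FixtureSpec(seed=0, scd_default=-0.5, composition=Composition(
            {"PC": (20, 20), "CHOL": (0, 0)}), n_rows=4)
        frame, _ = make_membrane_fixture(spec)
        prof = order_parameters([frame], "PC", "outer", make_surface(0.0))
        assert np.allclose(prof.mean, -0.5, atol=1e-9)

    def test_magic_angle_is_zero(self):
        ang = np.radians(54.7356103172)
        v = np.array([np.sin(ang), 0.0, np.cos(ang)])
        frame = ch_frame([v] * 10)
        cfg = default_config()
        cfg.species = {"PC": SpeciesMap(last_carbon=2)}
        prof = order_parameters([frame], "PC", "outer", make_surface(0.0),
                                config=cfg)
        assert abs(prof.mean[0]) < 1e-9

    def test_isotropic_vectors_average_to_zero(self, short_chain_config):
        rng = np.random.default_rng(5)
        n = 50000  # two H per molecule -> 1e5 samples
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        frame = ch_frame(v)
        prof = order_parameters([frame], "PC", "outer", make_surface(0.0),
                                config=short_chain_config)
        assert prof.n_samples[0] == 2 * n
        assert abs(prof.mean[0]) < 0.01

    def test_scd_bounds(self, short_chain_config):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(500, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        frame = ch_frame(v)
        prof = order_parameters([frame], "PC", "outer", make_surface(0.0),
                                config=short_chain_config)
        assert np.all(prof.mean >= -0.5) and np.all(prof.mean <= 1.0)

    def test_missing_hydrogens_rejected(self, short_chain_config):
        frame = bare_frame(
            [[0, 0, 1], [0, 0, 0.5]],
            names=["P", "C2A"], resnames=["PC", "PC"], resids=[1, 1],
            elements=["P", "C"], leaflet=["outer", "outer"])
        with pytest.raises(ExplicitHydrogensError):
            order_parameters([frame], "PC", "outer", make_surface(0.0),
                             config=short_chain_config)

    def test_unknown_species_rejected(self):
        frame = bare_frame([[0, 0, 1]])
        with pytest.raises(EmptyGroupError):
            order_parameters([frame], "DOPG", "outer", make_surface(0.0))


# ------------------------------------------------------------ area per lipid


def lattice_frame(points_xy, z=2.0, leaflet="outer"):
    pos = np.column_stack([
        points_xy[:, 0], points_xy[:, 1], np.full(len(points_xy), z)])
    return bare_frame(pos, names=["P"] * len(pos), leaflet=[leaflet] * len(pos))


def pixel_cell_area(points2d, target=0, pixel=1e-3, margin=1.2):
    """Brute-force nearest-site pixel integration of one Voronoi cell."""
    p0 = points2d[target]
    xs = np.arange(p0[0] - margin, p0[0] + margin, pixel)
    ys = np.arange(p0[1] - margin, p0[1] + margin, pixel)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pix = np.column_stack([xx.ravel(), yy.ravel()])
    _, owner = cKDTree(points2d).query(pix, workers=1)
    return np.count_nonzero(owner == target) * pixel * pixel


class TestAreasPerLipid:
    def test_square_lattice_interior_cells(self):
        a = 0.8
        xs, ys = np.meshgrid(np.arange(7) * a, np.arange(7) * a, indexing="ij")
        frame = lattice_frame(np.column_stack([xs.ravel(), ys.ravel()]))
        df = areas_per_lipid(frame, make_surface(0.0), cutoff=1.5)
        interior = df[df.bounded]
        assert len(interior) >= 25
        assert np.allclose(interior.area, a * a, atol=1e-6)

    def test_hexagonal_lattice_interior_cells(self):
        a = 0.8
        pts = []
        for j in range(7):
            for i in range(7):
                pts.append([i * a + (j % 2) * a / 2, j * a * np.sqrt(3) / 2])
        frame = lattice_frame(np.asarray(pts))
        df = areas_per_lipid(frame, make_surface(0.0), cutoff=1.5)
        interior = df[df.bounded &
                      (np.abs(df.area - np.sqrt(3) / 2 * a * a) < 1e-6)]
        # every fully-coordinated site carries the closed-form hexagon area
        assert len(interior) >= 25

    def test_voronoi_matches_pixel_oracle_small_patch(self):
        """<= 12-lipid patch: cell areas vs nearest-site pixel integration."""
        rng = np.random.default_rng(8)
        base = np.array([[i, j] for i in range(4) for j in range(3)], float) * 0.8
        pts = base + rng.uniform(-0.08, 0.08, base.shape)
        for target in (4, 7):  # interior sites of the 4x3 patch
            order = [target] + [k for k in range(len(pts)) if k != target]
            analytic = _voronoi_cell_area(pts[order])
            brute = pixel_cell_area(pts, target=target)
            assert analytic == pytest.approx(brute, rel=0.01)

    def test_cylindrical_leaflet_area_ratio(self):
        """Equal counts on arcs at R +- t: mean area ratio = (R+t)/(R-t)."""
        comp = Composition({"PC": (60, 60), "CHOL": (0, 0)})
        spec = FixtureSpec(curvature=0.2, seed=3, composition=comp,
                           spacing_reference="mid")
        frame, _ = make_membrane_fixture(spec)
        df = areas_per_lipid(frame, make_surface(0.2), cutoff=1.5)
        b = df[df.bounded]
        ratio = (b[b.leaflet == "outer"].area.mean()
                 / b[b.leaflet == "inner"].area.mean())
        R, t = 5.0, spec.head_offset
        assert ratio == pytest.approx((R + t) / (R - t), rel=0.02)

    def test_curvature_monotonicity(self):
        """APL(convex) > APL(flat) > APL(concave) at fixed loading."""
        comp = Composition({"PC": (60, 60), "CHOL": (0, 0)})
        means = {}
        for c in (0.2, 0.0):
            spec = FixtureSpec(curvature=c, seed=3, composition=comp,
                               spacing_reference="mid")
            frame, _ = make_membrane_fixture(spec)
            df = areas_per_lipid(frame, make_surface(c), cutoff=2.0)
            b = df[df.bounded]
            for lf in ("outer", "inner"):
                means[(c, lf)] = b[b.leaflet == lf].area.mean()
        convex, flat, concave = means[(0.2, "outer")], means[(0.0, "outer")], \
            means[(0.2, "inner")]
        assert convex > flat > concave

    def test_too_few_lipids_rejected(self):
        frame = lattice_frame(np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(EmptyGroupError):
            areas_per_lipid(frame, make_surface(0.0))


class TestAggregateApl:
    @staticmethod
    def df(areas, species="PC", leaflet="outer"):
        return pd.DataFrame({
            "resid": np.arange(len(areas)), "species": species,
            "leaflet": leaflet, "area": areas,
            "bounded": np.isfinite(areas)})

    def test_single_frame_mean(self):
        rep = aggregate_apl([self.df(np.array([0.5, 0.7]))])
        assert rep.mean("PC", "outer") == pytest.approx(0.6)

    def test_identical_frames_zero_sd(self):
        frames = [self.df(np.array([0.6, 0.6]))] * 2
        rep = aggregate_apl(frames)
        assert rep.table.std_nm2.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_sampling_mean(self):
        rng = np.random.default_rng(9)
        rep = aggregate_apl([self.df(rng.normal(0.6, 0.05, 10000))])
        assert rep.mean("PC", "outer") == pytest.approx(0.6, abs=0.002)

    def test_unbounded_cells_excluded(self):
        areas = np.array([0.6, np.nan, 0.6])
        rep = aggregate_apl([self.df(areas)])
        assert rep.table.n.iloc[0] == 2


# -------------------------------------------------------------- cholesterol


def chol_frame(entries):
    """entries: (oh_position, axis_unit_vector) per molecule."""
    names, resnames, resids, elements, leaflet, pos = [], [], [], [], [], []
    for k, (oh, axis) in enumerate(entries):
        oh = np.asarray(oh, float)
        for nm, el, p in [("O3", "O", oh),
                          ("C17", "C", oh - 0.9 * np.asarray(axis, float))]:
            names.append(nm)
            resnames.append("CHOL")
            resids.append(k + 1)
            elements.append(el)
            leaflet.append("none")
            pos.append(p)
    return bare_frame(pos, names=names, resnames=resnames, resids=resids,
                      elements=elements, leaflet=leaflet)


class TestCholesterolMetrics:
    def test_axis_parallel_to_normal_zero_inclination(self):
        frame = chol_frame([((0, 0, 1.5), (0, 0, 1))] * 5)
        rep = cholesterol_metrics([frame], make_surface(0.0),
                                  head_depths={"outer": 2.0, "inner": -2.0})
        assert rep.angle_peak_deg["outer"] == pytest.approx(0.0, abs=2.0)
        assert rep.minor_fraction_percent == 0.0

    def test_horizontal_mid_membrane_is_minor_at_90deg(self):
        frame = chol_frame([((0, 0, 0.0), (0, 1, 0))] * 4)
        rep = cholesterol_metrics([frame], make_surface(0.0),
                                  head_depths={"outer": 2.0, "inner": -2.0})
        assert rep.n_central == 4
        assert rep.angle_peak_deg["central"] == pytest.approx(90.0, abs=2.0)

    def test_constructed_minor_fraction_exact(self):
        entries = [((0, 0, 1.5), (0, 0, 1))] * 39 + \
                  [((0, 0, -1.5), (0, 0, -1))] * 39 + \
                  [((0, 0, 0.0), (0, 1, 0))] * 2
        rep = cholesterol_metrics([chol_frame(entries)], make_surface(0.0),
                                  head_depths={"outer": 2.0, "inner": -2.0})
        assert rep.n_total == 80
        assert rep.minor_fraction_percent == pytest.approx(2.5, abs=1e-12)

    def test_depth_measured_from_head_surface(self):
        frame = chol_frame([((0, 0, 1.5), (0, 0, 1))] * 5)
        rep = cholesterol_metrics([frame], make_surface(0.0),
                                  head_depths={"outer": 2.0, "inner": -2.0})
        assert rep.depth_peak_nm["outer"] == pytest.approx(0.5, abs=0.05)

    def test_histogram_masses_sum_to_one(self):
        entries = [((0, 0, 1.5), (0, 0, 1))] * 6 + [((0, 0, 0.0), (0, 1, 0))] * 2
        rep = cholesterol_metrics([chol_frame(entries)], make_surface(0.0),
                                  head_depths={"outer": 2.0, "inner": -2.0})
        for h in rep.angle_hist.values():
            assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_defining_atom_rejected(self):
        frame = bare_frame([[0, 0, 1.5]], names=["O3"], resnames=["CHOL"],
                           resids=[1], elements=["O"], leaflet=["none"])
        with pytest.raises(NamingConventionError):
            cholesterol_metrics([frame], make_surface(0.0))


# ------------------------------------------------------------------ sectors


def test_analyses_invariant_outside_sector():
    """Arbitrary changes to atoms outside the sector leave results unchanged."""
    comp = Composition({"PC": (60, 60), "CHOL": (10, 10)})
    spec = FixtureSpec(curvature=0.2, seed=11, composition=comp,
                       minor_fraction_percent=10.0)
    frame, _ = make_membrane_fixture(spec)
    surf = make_surface(0.2)
    sector = SectorSpec("arc", half_angle_deg=20.0)

    # modify everything beyond the sector plus a neighbour-cutoff guard band,
    # shifting along Y so arc angles (and hence sector membership) are kept
    guard = SectorSpec("arc", half_angle_deg=45.0)
    outside = ~sector_mask(surf, frame.positions, guard)
    rng = np.random.default_rng(12)
    moved = frame.positions.copy()
    moved[outside, 1] += rng.uniform(1.0, 5.0, outside.sum())
    frame2 = frame.with_positions(moved)

    prof1 = density_profiles([frame], surf, default_groups(frame),
                             bin_width=0.05, sector=sector)
    prof2 = density_profiles([frame2], surf, default_groups(frame2),
                             bin_width=0.05, sector=sector)
    for key in prof1.profiles:
        assert np.array_equal(prof1.profiles[key], prof2.profiles[key])

    df1 = areas_per_lipid(frame, surf, sector=sector)
    df2 = areas_per_lipid(frame2, surf, sector=sector)
    pd.testing.assert_frame_equal(df1, df2)
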