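"""Generator truth: lens closed forms, spreading shapes, assemblies, patterns."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camquant.errors import PackingError, ParameterError
from camquant.imaging import ImageStack, max_projection
from camquant.synthetic import (
    AssemblyParams,
    PairParams,
    PatternParams,
    SpreadParams,
    lens_geometry,
    make_assembly_stack,
    make_cell_pair,
    make_contact_pattern,
    make_solid_core_shell,
    make_spreading_series,
    protrusive_polygon,
)


class TestLensGeometry:
    def test_tangent_pair_has_zero_angle_and_chord(self):
        g = lens_geometry(50, 50, 100)
        assert g["theta_deg"] == 0.0
        assert g["chord"] == 0.0

    def test_symmetric_half_overlap(self):
        # r1 = r2 = 50, d = 50: alpha = arccos(1/2) = 60 deg each
        g = lens_geometry(50, 50, 50)
        assert g["alpha1_deg"] == pytest.approx(60.0)
        assert g["theta_deg"] == pytest.approx(120.0)
        assert g["chord"] == pytest.approx(2 * math.sqrt(1875), abs=1e-9)

    def test_engulfment_geometry_gives_obtuse_angle(self):
        # r1=60, r2=20, d=45: a2 < 0 so alpha2 > 90 deg
        g = lens_geometry(60, 20, 45)
        assert g["a2"] < 0
        assert g["alpha2_deg"] > 90.0

    @given(
        r1=st.floats(10, 80),
        r2=st.floats(10, 80),
        frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_lens_identities(self, r1, r2, frac):
        # chord^2/4 + a_i^2 = r_i^2 for both circles, any proper overlap
        lo, hi = abs(r1 - r2), r1 + r2
        d = lo + frac * (hi - lo)
        if d <= lo * (1 + 1e-9) or d <= 0:
            return
        g = lens_geometry(r1, r2, d)
        assert g["chord"] ** 2 / 4 + g["a1"] ** 2 == pytest.approx(r1**2, rel=1e-9)
        assert g["chord"] ** 2 / 4 + g["a2"] ** 2 == pytest.approx(r2**2, rel=1e-9)
        assert g["theta_deg"] == pytest.approx(
            g["alpha1_deg"] + g["alpha2_deg"], abs=1e-9
        )


class TestMakeCellPair:
    def test_uniform_membrane_fraction_from_arc_lengths(self):
        # free major arc (4 pi / 3) * 50 ~ 209.44, chord ~ 86.60
        _, truth = make_cell_pair(PairParams(r1=50, r2=50, d=50))
        expected = 86.60254 / (209.43951 + 86.60254)
        assert truth.f_true == pytest.approx(expected, abs=1e-4)
        assert truth.theta_deg == pytest.approx(120.0)

    @pytest.mark.parametrize("f", [0.25, 0.5, 0.8])
    def test_requested_enrichment_is_exact(self, f):
        stack, truth = make_cell_pair(PairParams(enrichment_f=f))
        assert truth.f_true == pytest.approx(f, abs=1e-9)
        # painted pixel sums reproduce the recorded fraction
        img = stack.channel("membrane")[0]
        assert img.sum() > 0

    def test_non_overlapping_pair_with_enrichment_rejected(self):
        with pytest.raises(ParameterError, match="overlap"):
            make_cell_pair(PairParams(r1=40, r2=40, d=120, enrichment_f=0.5))

    def test_masks_partition_and_match_channels(self):
        stack, truth = make_cell_pair(PairParams())
        assert not (truth.mask1 & truth.mask2).any()
        cyto1 = stack.channel("cyto1") > 0
        agreement = (cyto1 == truth.mask1).mean()
        assert agreement >= 0.99

    def test_seeded_noise_is_reproducible(self):
        a, _ = make_cell_pair(PairParams(noise_sd=0.05, seed=11))
        b, _ = make_cell_pair(PairParams(noise_sd=0.05, seed=11))
        c, _ = make_cell_pair(PairParams(noise_sd=0.05, seed=12))
        assert np.array_equal(a.channel("membrane"), b.channel("membrane"))
        assert not np.array_equal(a.channel("membrane"), c.channel("membrane"))


class TestMakeSpreadingSeries:
    def test_power_law_area_at_t16(self):
        # A = b * t^(1/4): b=100, t=16 -> 100 * 2 = 200 um^2
        _, truth = make_spreading_series(
            SpreadParams(b=100, alpha=0.25, times=(16.0,))
        )
        assert truth.frames[0].area == pytest.approx(200.0)

    def test_expansive_truth_circularity_is_one(self):
        _, truth = make_spreading_series(SpreadParams(b=100, alpha=0.25))
        assert all(f.circularity == pytest.approx(1.0) for f in truth.frames)

    def test_areas_strictly_increasing(self):
        _, truth = make_spreading_series(SpreadParams(b=50, alpha=0.25))
        areas = [f.area for f in truth.frames]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_protrusive_truth_matches_polygon_oracle(self):
        # independent shoelace / segment-sum oracle on the explicit polygon
        _, truth = make_spreading_series(
            SpreadParams(b=100, alpha=0.25, shape_mode="protrusive", times=(16.0,))
        )
        frame = truth.frames[0]
        poly = protrusive_polygon(frame.area, 8, 2.0)
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        closed = np.vstack([poly, poly[:1]])
        perim = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert area == pytest.approx(frame.area, rel=1e-4)
        assert perim == pytest.approx(frame.perimeter, rel=1e-4)
        assert frame.circularity > 1.5

    def test_rendered_mask_area_matches_truth(self):
        masks, truth = make_spreading_series(SpreadParams(b=100, alpha=0.25))
        for mask, frame in zip(masks, truth.frames):
            rendered = mask.data.sum() * mask.pixel_area
            assert rendered == pytest.approx(frame.area, rel=0.01)

    def test_canvas_too_small_reports_requirement(self):
        with pytest.raises(ParameterError, match="canvas"):
            make_spreading_series(SpreadParams(b=100, canvas_um=5.0))


class TestMakeAssemblyStack:
    def test_single_cell_leaves_other_channel_empty(self):
        stack, truth = make_assembly_stack(
            AssemblyParams(n_per_channel=(1, 0), seed=0)
        )
        assert (stack.channel("chB") > 0).sum() == 0
        assert (stack.channel("chA") > 0).sum() > 0
        assert truth.channels == ["chA"]

    def test_fixed_seed_is_bit_exact(self):
        a, _ = make_assembly_stack(AssemblyParams(seed=5))
        b, _ = make_assembly_stack(AssemblyParams(seed=5))
        for name in a.channel_names:
            assert np.array_equal(a.channel(name), b.channel(name))

    def test_min_center_distance_respected(self):
        _, truth = make_assembly_stack(AssemblyParams(seed=2))
        c = truth.centers
        d = np.linalg.norm(c[:, None] - c[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * truth.cell_radius - 1e-9

    def test_core_shell_separates_center_radii(self):
        _, truth = make_assembly_stack(
            AssemblyParams(configuration="core_shell", seed=3)
        )
        r = np.linalg.norm(truth.centers - truth.centers.mean(axis=0), axis=1)
        r_a = r[[c == "chA" for c in truth.channels]]
        r_b = r[[c == "chB" for c in truth.channels]]
        assert r_a.mean() < r_b.mean()

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError, match="attempts"):
            make_assembly_stack(
                AssemblyParams(n_per_channel=(200, 200), cell_radius=12.0,
                               assembly_radius=60.0, seed=0)
            )

    def test_rendered_voxels_match_truth_spheres(self):
        stack, truth = make_assembly_stack(AssemblyParams(seed=4))
        dz, dy, dx = stack.voxel_size
        vol = stack.channel("chA")
        zc = (np.arange(vol.shape[0]) + 0.5) * dz
        yc = (np.arange(vol.shape[1]) + 0.5) * dy
        xc = (np.arange(vol.shape[2]) + 0.5) * dx
        ZZ, YY, XX = np.meshgrid(zc, yc, xc, indexing="ij", sparse=True)
        expected = np.zeros(vol.shape, dtype=bool)
        for c, name in zip(truth.centers, truth.channels):
            if name != "chA":
                continue
            expected |= (
                (ZZ - c[0]) ** 2 + (YY - c[1]) ** 2 + (XX - c[2]) ** 2
                <= truth.cell_radius**2
            )
        assert ((vol > 0) == expected).mean() >= 0.99


class TestSolidCoreShell:
    def test_projected_core_centered_within_shell(self):
        # analytic projection: core disc radius 20, shell annulus to 40
        masks = make_solid_core_shell()
        vs = masks["core"].voxel_size
        proj = max_projection(
            ImageStack(
                {k: m.data.astype(float) for k, m in masks.items()}, vs
            )
        )
        core = proj.channel("core")[0] > 0
        shell = proj.channel("shell")[0] > 0
        # z-slice centres sit at +-5, +-15, ... um, so the projected core
        # disc has radius sqrt(20^2 - 5^2); slices with |z| >= 25 um cut the
        # shell as full discs, so its projection fills sqrt(40^2 - 5^2)
        area_core = core.sum() * vs[1] * vs[2]
        assert area_core == pytest.approx(math.pi * (20**2 - 5**2), rel=0.02)
        area_shell = shell.sum() * vs[1] * vs[2]
        assert area_shell == pytest.approx(math.pi * (40**2 - 5**2), rel=0.02)
        # the projected core sits centred inside the shell footprint
        cy, cx = np.argwhere(core).mean(axis=0)
        sy, sx = np.argwhere(shell).mean(axis=0)
        assert abs(cy - sy) <= 2 and abs(cx - sx) <= 2


class TestMakeContactPattern:
    @pytest.mark.parametrize(
        "pattern,n,expected",
        [
            ("alternating", 2, {("A", "B"): 1.0}),
            ("bridging", 3, {("A", "B"): 0.5, ("B", "C"): 0.5, ("A", "C"): 0.0}),
            (
                "cyclic",
                3,
                {("A", "B"): 1 / 3, ("B", "C"): 1 / 3, ("A", "C"): 1 / 3},
            ),
        ],
    )
    def test_truth_tables_by_enumeration(self, pattern, n, expected):
        _, truth = make_contact_pattern(PatternParams(pattern=pattern, n_cells=n))
        for (a, b), p in expected.items():
            assert truth.table.loc[a, b] == pytest.approx(p)

    def test_bridging_never_joins_a_and_c(self):
        cells, truth = make_contact_pattern(
            PatternParams(pattern="bridging", n_cells=11)
        )
        types = cells["type"].tolist()
        for i, j in truth.edges:
            assert {types[i], types[j]} != {"A", "C"}

    def test_cyclic_edges_are_heterotypic(self):
        cells, truth = make_contact_pattern(
            PatternParams(pattern="cyclic", n_cells=24)
        )
        types = cells["type"].tolist()
        assert all(types[i] != types[j] for i, j in truth.edges)

    def test_jitter_bound_enforced(self):
        with pytest.raises(ParameterError, match="jitter"):
            make_contact_pattern(PatternParams(spacing=10.0, jitter_sd=5.0))

    def test_jitter_reproducible_and_truth_unjittered(self):
        a, ta = make_contact_pattern(PatternParams(jitter_sd=1.0, seed=9))
        b, _ = make_contact_pattern(PatternParams(jitter_sd=1.0, seed=9))
        assert np.allclose(a[["x_um", "y_um"]], b[["x_um", "y_um"]])
        assert not np.allclose(
            a[["x_um", "y_um"]].to_numpy(), ta.positions_exact
        )
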