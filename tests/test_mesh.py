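import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dotbench.mesh import (
    CONTAINMENT_MARGIN,
    DEFAULT_PARTITION,
    DEFAULT_RANGES,
    Inclusion,
    ParameterRanges,
    Phantom,
    allocate_partition,
    build_disk_mesh,
    circular_mask,
    nodal_coefficients,
    rasterize_truth,
    sample_phantom,
    sample_phantom_batch,
)


class TestBuildDiskMesh:
    def test_reference_configuration_counts(self):
        mesh = build_disk_mesh(32, 100.0)
        assert mesh.n_nodes == 3169
        assert mesh.n_elements == 6144

    @pytest.mark.parametrize("n,nodes,elements", [(1, 7, 6), (2, 19, 24)])
    def test_small_counts_by_hand(self, n, nodes, elements):
        mesh = build_disk_mesh(n, 100.0)
        assert mesh.n_nodes == nodes
        assert mesh.n_elements == elements

    @given(n=st.integers(min_value=1, max_value=40))
    @settings(max_examples=15, deadline=None)
    def test_ring_count_formulas(self, n):
        mesh = build_disk_mesh(n, 50.0)
        assert mesh.n_nodes == 3 * n**2 + 3 * n + 1
        assert mesh.n_elements == 6 * n**2

    def test_positive_orientation_and_area(self):
        mesh = build_disk_mesh(32, 100.0)
        areas = mesh.element_areas()
        assert np.all(areas > 0)
        assert abs(areas.sum() - np.pi * 50.0**2) / (np.pi * 50.0**2) < 0.01

    def test_boundary_nodes_on_circle(self):
        d = 123.0
        mesh = build_disk_mesh(10, d)
        r = np.linalg.norm(mesh.node_coords[mesh.boundary_nodes], axis=1)
        assert np.all(np.abs(r - d / 2.0) < 1e-9 * d)
        assert len(mesh.boundary_nodes) == 60

    @pytest.mark.parametrize("bad", [0, -1])
    def test_invalid_rings(self, bad):
        with pytest.raises(ValueError):
            build_disk_mesh(bad, 100.0)

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            build_disk_mesh(4, -5.0)


class TestAllocatePartition:
    def test_default_partition_exact(self):
        counts = allocate_partition(10_000, DEFAULT_PARTITION)
        assert counts == [100, 4400, 5500]

    def test_sums_to_n(self):
        assert sum(allocate_partition(997, (0.33, 0.33, 0.34))) == 997

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            allocate_partition(10, (0.5, 0.6))


class TestSamplePhantom:
    def test_deterministic(self):
        a = sample_phantom(rng=np.random.default_rng(42))
        b = sample_phantom(rng=np.random.default_rng(42))
        assert a == b

    def test_forced_zero_inclusions(self):
        ph = sample_phantom(partition=(1.0, 0.0, 0.0), rng=np.random.default_rng(0))
        assert ph.inclusions == ()

    def test_ranges_and_containment(self):
        rng = np.random.default_rng(7)
        r = DEFAULT_RANGES
        for _ in range(300):
            ph = sample_phantom(rng=rng)
            assert r.diameter_mm[0] <= ph.diameter_mm <= r.diameter_mm[1]
            assert r.frequency_MHz[0] <= ph.frequency_MHz <= r.frequency_MHz[1]
            assert r.mu_a0[0] <= ph.mu_a0 <= r.mu_a0[1]
            assert r.mu_s0[0] <= ph.mu_s0 <= r.mu_s0[1]
            for inc in ph.inclusions:
                assert r.contrast[0] <= inc.contrast_a <= r.contrast[1]
                assert r.contrast[0] <= inc.contrast_s <= r.contrast[1]
                assert (
                    inc.off_center_mm + inc.radius_mm
                    <= CONTAINMENT_MARGIN * ph.diameter_mm / 2 + 1e-9
                )

    def test_two_inclusions_disjoint(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ph = sample_phantom(rng=rng, n_inclusions=2)
            (a, b) = ph.inclusions
            dist = np.hypot(
                a.center_mm[0] - b.center_mm[0], a.center_mm[1] - b.center_mm[1]
            )
            assert dist > a.radius_mm + b.radius_mm

    def test_marginal_coverage(self):
        # uniformity sanity check: draws should span >95% of each range
        rng = np.random.default_rng(11)
        ds = [sample_phantom(rng=rng).diameter_mm for _ in range(2000)]
        lo, hi = DEFAULT_RANGES.diameter_mm
        assert (max(ds) - min(ds)) / (hi - lo) > 0.95


class TestSamplePhantomBatch:
    def test_exact_stratification(self):
        phantoms = sample_phantom_batch(1000, rng=np.random.default_rng(0))
        counts = np.bincount([len(p.inclusions) for p in phantoms], minlength=3)
        assert counts.tolist() == [10, 440, 550]


class TestNodalCoefficients:
    def test_homogeneous(self, homogeneous_phantom, mesh16):
        co = nodal_coefficients(homogeneous_phantom, mesh16)
        assert np.all(co.mu_a == 0.01)
        assert np.all(co.mu_s == 1.0)

    def test_contrast_applied(self, single_inclusion_phantom, mesh16):
        co = nodal_coefficients(single_inclusion_phantom, mesh16)
        inc = single_inclusion_phantom.inclusions[0]
        cx, cy = inc.center_mm
        inside = (
            (mesh16.node_coords[:, 0] - cx) ** 2 + (mesh16.node_coords[:, 1] - cy) ** 2
        ) <= inc.radius_mm**2
        assert np.allclose(co.mu_a[inside], 0.01 * inc.contrast_a)
        assert np.allclose(co.mu_a[~inside], 0.01)

    def test_inside_count_matches_brute_force(self, mesh16):
        ph = Phantom(
            100.0, 50.0, 0.01, 1.0,
            (Inclusion(100 / 8, 100 / 4, 30.0, 2.0, 2.0),),
        )
        co = nodal_coefficients(ph, mesh16)
        inc = ph.inclusions[0]
        cx, cy = inc.center_mm
        brute = int(
            np.sum(
                (mesh16.node_coords[:, 0] - cx) ** 2
                + (mesh16.node_coords[:, 1] - cy) ** 2
                <= inc.radius_mm**2
            )
        )
        assert int(np.sum(co.mu_a > 0.01)) == brute

    def test_diameter_mismatch(self, single_inclusion_phantom, mesh8):
        with pytest.raises(ValueError):
            nodal_coefficients(single_inclusion_phantom, mesh8)


class TestRasterizeTruth:
    def test_homogeneous_constant(self, homogeneous_phantom):
        img = rasterize_truth(homogeneous_phantom, 64)
        assert np.allclose(img.mu_a_grid[img.mask], 0.01)
        assert np.all(img.mu_a_grid[~img.mask] == 0)

    def test_centered_inclusion_pixel_count(self):
        ph = Phantom(
            100.0, 50.0, 0.01, 1.0, (Inclusion(25.0, 0.0, 0.0, 2.0, 2.0),)
        )
        img = rasterize_truth(ph, 64)
        # brute-force: pixel centers within 16-pixel radius of grid center
        u = (np.arange(64) + 0.5) / 64 - 0.5
        xx, yy = np.meshgrid(u, u)
        brute = int(np.sum(xx**2 + yy**2 <= 0.25**2))
        assert int(np.sum(img.mu_a_grid > 0.015)) == brute

    def test_mask_independent_of_diameter(self):
        m1 = rasterize_truth(Phantom(60.0, 0.0, 0.01, 1.0), 64).mask
        m2 = rasterize_truth(Phantom(150.0, 0.0, 0.01, 1.0), 64).mask
        assert np.array_equal(m1, m2)
        assert np.array_equal(m1, circular_mask(64))

    def test_diameter_covariance(self):
        # same relative geometry => identical pixel footprint at any diameter
        footprints = []
        for d in (60.0, 120.0):
            ph = Phantom(d, 0.0, 0.01, 1.0, (Inclusion(d / 8, d / 4, 90.0, 2.0, 2.0),))
            img = rasterize_truth(ph, 64)
            footprints.append(img.mu_a_grid > ph.mu_a0)
        assert np.array_equal(footprints[0], footprints[1])

    def test_contrast_kind_bounds(self, single_inclusion_phantom):
        img = rasterize_truth(single_inclusion_phantom, 64, kind="contrast")
        assert img.kind == "contrast"
        assert img.mu_a_grid.min() >= 0.0
        assert img.mu_a_grid.max() <= 1.0

    def test_bad_grid(self, homogeneous_phantom):
        with pytest.raises(ValueError):
            rasterize_truth(homogeneous_phantom, 1)


class TestMeshExport:
    def test_text_tables_roundtrip(self, tmp_path, mesh8):
        from dotbench.mesh import save_mesh_text

        prefix = str(tmp_path / "m")
        save_mesh_text(mesh8, prefix)
        nodes = np.loadtxt(f"{prefix}_nodes.csv", delimiter=",", skiprows=1)
        elements = np.loadtxt(f"{prefix}_elements.csv", delimiter=",", skiprows=1)
        assert nodes.shape == (mesh8.n_nodes, 2)
        assert elements.shape == (mesh8.n_elements, 3)
        assert np.allclose(nodes, mesh8.node_coords)

    def test_gmsh_export_counts(self, tmp_path, mesh8):
        from dotbench.mesh import save_mesh_gmsh

        path = tmp_path / "m.msh"
        save_mesh_gmsh(mesh8, str(path))
        text = path.read_text()
        assert "$MeshFormat" in text
        assert f"\n{mesh8.n_nodes}\n" in text
        assert f"\n{mesh8.n_elements}\n" in text


class TestInvariants:
    def test_inclusion_validation(self):
        with pytest.raises(ValueError):
            Inclusion(-1.0, 0.0, 0.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            Inclusion(5.0, 0.0, 0.0, 0.5, 2.0)

    def test_phantom_validation(self):
        with pytest.raises(ValueError):
            Phantom(100.0, 0.0, 0.01, 1.0, (Inclusion(20.0, 40.0, 0.0, 2.0, 2.0),))
        with pytest.raises(ValueError):
            Phantom(-1.0, 0.0, 0.01, 1.0)
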