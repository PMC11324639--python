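"""Territory assignment: geodesic labeling vs brute-force oracle, partitioning."""

import numpy as np
import pytest

from svperf.core import MyocardiumSample, tissue_mass
from svperf.errors import EmptySegmentationError, InvalidParameterError
from svperf.territory import (
    Centerline,
    assign_territories,
    read_centerlines_csv,
    regional_perfusion,
    write_centerlines_csv,
)

VSZ = (1.0, 1.0, 1.0)


def straight_line(artery, p0, p1, n=5):
    pts = np.linspace(p0, p1, n)
    return Centerline(artery=artery, points_mm=pts)


def oracle_assign(mask, centerlines, vsz, order):
    """Independent labeling: networkx single-source-per-artery Dijkstra.

    Replicates the operation's contract (resample to half a voxel, snap to
    voxels, 26-connected metric graph over mask+seeds, Euclidean fallback
    for unreachable voxels) with an independent graph implementation.
    """
    import networkx as nx

    vsz = np.asarray(vsz, float)
    shape = np.asarray(mask.shape)
    spacing = 0.5 * vsz.min()
    seeds, dense_pts = {}, {}
    for c in centerlines:
        pts = [c.points_mm[0]]
        for a, b in zip(c.points_mm[:-1], c.points_mm[1:]):
            n = max(int(np.ceil(np.linalg.norm(b - a) / spacing)), 1)
            pts.extend(a + (b - a) * k / n for k in range(1, n + 1))
        pts = np.asarray(pts)
        dense_pts[c.artery] = pts
        idx = np.clip(np.rint(pts / vsz).astype(int), 0, shape - 1)
        seeds[c.artery] = set(map(tuple, idx))
    domain = set(zip(*np.nonzero(mask)))
    for s in seeds.values():
        domain |= s
    G = nx.Graph()
    G.add_nodes_from(domain)
    for (z, y, x) in domain:
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    nb = (z + dz, y + dy, x + dx)
                    if nb in domain:
                        w = float(np.linalg.norm(np.array([dz, dy, dx]) * vsz))
                        G.add_edge((z, y, x), nb, weight=w)
    dist = {a: nx.multi_source_dijkstra_path_length(G, s, weight="weight")
            for a, s in seeds.items()}
    labels = np.zeros(mask.shape, dtype=np.int16)
    for v in zip(*np.nonzero(mask)):
        d = np.array([dist[a].get(v, np.inf) for a in order])
        if not np.isfinite(d).any():
            world = np.array(v) * vsz
            d = np.array([np.linalg.norm(dense_pts[a] - world, axis=1).min()
                          for a in order])
        labels[v] = int(np.argmin(d)) + 1
    return labels


def random_case(rng, n=18):
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.random((n, n, n)), sigma=2.0)
    mask = field > np.quantile(field, 0.72)
    extent = (n - 1) * np.ones(3)
    lines = [Centerline(artery=a,
                        points_mm=rng.uniform(0, 1, (4, 3)) * extent)
             for a in ("LAD", "LCx", "RCA")]
    return mask, lines


class TestAssignTerritories:
    def test_single_centerline_labels_everything(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        line = straight_line("LAD", (0, 3, 3), (7, 3, 3))
        tmap = assign_territories(mask, [line], VSZ)
        assert np.array_equal(tmap.mask_for("LAD"), mask)

    def test_two_parallel_lines_split_at_bisector(self):
        """Convex slab, straight lines at x=0 and x=11: boundary at x=5.5."""
        mask = np.zeros((6, 6, 12), dtype=bool)
        mask[1:5, 1:5, :] = True
        left = straight_line("LAD", (0, 2.5, 0.0), (5, 2.5, 0.0))
        right = straight_line("LCx", (0, 2.5, 11.0), (5, 2.5, 11.0))
        tmap = assign_territories(mask, [left, right], VSZ)
        xs = np.nonzero(mask)[2]
        labs = tmap.labels[mask]
        assert np.all(labs[xs <= 5] == tmap.arteries["LAD"])
        assert np.all(labs[xs >= 6] == tmap.arteries["LCx"])

    def test_geodesic_matches_euclidean_on_convex_mask(self):
        mask = np.zeros((6, 6, 12), dtype=bool)
        mask[1:5, 1:5, :] = True
        lines = [straight_line("LAD", (0, 2.5, 0.0), (5, 2.5, 0.0)),
                 straight_line("RCA", (0, 2.5, 11.0), (5, 2.5, 11.0))]
        geo = assign_territories(mask, lines, VSZ, metric="geodesic")
        eu = assign_territories(mask, lines, VSZ, metric="euclidean")
        assert np.array_equal(geo.labels, eu.labels)

    @pytest.mark.parametrize("seed", range(6))
    def test_geodesic_matches_networkx_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        mask, lines = random_case(rng)
        vsz = (0.9, 1.0, 1.1)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tmap = assign_territories(mask, lines, vsz)
        expected = oracle_assign(mask, lines, vsz, ("LAD", "LCx", "RCA"))
        assert np.array_equal(tmap.labels, expected)

    def test_partition_property(self, small_study):
        tmap = small_study.truth_territories
        union = np.zeros(tmap.labels.shape, dtype=int)
        for artery in tmap.arteries:
            union += tmap.mask_for(artery).astype(int)
        assert np.array_equal(union == 1, small_study.myo_mask)
        assert not (union > 1).any()

    def test_input_order_irrelevant_off_ties(self):
        rng = np.random.default_rng(77)
        mask, lines = random_case(rng)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = assign_territories(mask, lines, VSZ)
            b = assign_territories(mask, lines[::-1], VSZ)
        assert np.array_equal(a.labels, b.labels)
        assert a.arteries == b.arteries

    def test_validation(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(InvalidParameterError):
            assign_territories(mask, [], VSZ)
        with pytest.raises(EmptySegmentationError):
            assign_territories(np.zeros((4, 4, 4), dtype=bool),
                               [straight_line("LAD", (0, 0, 0), (3, 0, 0))], VSZ)
        with pytest.raises(InvalidParameterError):
            Centerline("LAD", np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))


class TestRegionalPerfusion:
    def test_uniform_map_gives_uniform_means(self, small_study):
        s = small_study
        vmap = np.where(s.myo_mask, 1.2, 0.0)
        sample = MyocardiumSample(s.myo_mask, s.config.voxel_volume_ml)
        table = regional_perfusion(vmap, s.truth_territories, sample)
        assert np.allclose(table["mean_perfusion_ml_min_g"], 1.2)

    def test_masses_partition_total(self, small_study):
        s = small_study
        sample = MyocardiumSample(s.myo_mask, s.config.voxel_volume_ml)
        table = regional_perfusion(np.where(s.myo_mask, 1.0, 0.0),
                                   s.truth_territories, sample)
        assert table["mass_g"].sum() == pytest.approx(tissue_mass(sample), rel=1e-12)

    def test_mass_weighted_mean_equals_global(self, small_study, rng):
        s = small_study
        vmap = np.where(s.myo_mask, rng.uniform(0.5, 2.0, s.myo_mask.shape), 0.0)
        sample = MyocardiumSample(s.myo_mask, s.config.voxel_volume_ml)
        table = regional_perfusion(vmap, s.truth_territories, sample)
        weighted = (table["mean_perfusion_ml_min_g"] * table["mass_g"]).sum() / table["mass_g"].sum()
        assert weighted == pytest.approx(vmap[s.myo_mask].mean(), rel=1e-9)

    def test_empty_territory_warns_and_is_omitted(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        near = straight_line("LAD", (1, 1, 1), (2, 2, 2))
        far = straight_line("RCA", (5, 5, 5), (5, 5, 4), n=2)
        tmap = assign_territories(mask, [near, far], VSZ, metric="euclidean")
        sample = MyocardiumSample(mask, 1e-4)
        if (tmap.labels == tmap.arteries["RCA"]).sum() == 0:
            with pytest.warns(RuntimeWarning):
                table = regional_perfusion(np.where(mask, 1.0, 0.0), tmap, sample)
            assert "RCA" not in table.index


def test_centerline_csv_roundtrip(tmp_path):
    lines = [straight_line("LAD", (0, 1, 2), (5, 1, 2)),
             straight_line("LCx", (0, 3, 4), (5, 3, 4), n=3)]
    path = tmp_path / "centerlines.csv"
    write_centerlines_csv(lines, path)
    back = read_centerlines_csv(path)
    assert [c.artery for c in back] == ["LAD", "LCx"]
    for a, b in zip(lines, back):
        np.testing.assert_allclose(a.points_mm, b.points_mm)
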