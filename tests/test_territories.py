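"""Minimum-cost-path territory assignment against brute-force oracles."""

import numpy as np
import pytest

from fpact.territories import (
    Centerline,
    TerritoryLabelMap,
    assign_territories,
    partition_distal,
    territory_cfr,
    territory_stats,
)
from fpact.volume import BinaryMask


def slab(shape=(20, 12, 6), spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.ones(shape, dtype=bool), spacing)


def straight_line(label, x, z, y0=0.5, y1=11.5, sten=None):
    pts = np.array([[x, y0, z], [x, y1, z]])
    return Centerline(label, pts, stenosis_arclength_mm=sten)


def nx_oracle_labels(mask: BinaryMask, centerlines):
    """Independent multi-source Dijkstra (networkx) on the same voxel graph.

    Sources are the rasterized centerline voxels; the domain is the mask
    plus source voxels; ties resolve in the given centerline order.
    """
    import networkx as nx

    from fpact.territories import _order_key, rasterize_centerline

    lines = sorted(centerlines, key=lambda c: _order_key(c.label))
    spacing = np.asarray(mask.spacing_mm)
    domain = mask.data.copy()
    sources = []
    for cl in lines:
        vox = rasterize_centerline(cl.points_mm, mask.shape, mask.spacing_mm)
        domain[tuple(vox.T)] = True
        sources.append([tuple(v) for v in vox])

    G = nx.Graph()
    coords = [tuple(c) for c in np.argwhere(domain)]
    G.add_nodes_from(coords)
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    cs = set(coords)
    for c in coords:
        for off in offs:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if nb in cs:
                w = float(np.linalg.norm(np.asarray(off) * spacing))
                G.add_edge(c, nb, weight=w)

    dists = []
    for srcs in sources:
        d = nx.multi_source_dijkstra_path_length(G, srcs)
        dists.append({c: d.get(c, np.inf) for c in coords})

    labels = np.zeros(mask.shape, dtype=np.uint8)
    for c in coords:
        if not mask.data[c]:
            continue
        best = int(np.argmin([d[c] for d in dists]))
        labels[c] = best + 1
    return labels, {k + 1: cl.label for k, cl in enumerate(lines)}


class TestAssignTerritories:
    def test_single_centerline_labels_everything(self):
        mask = slab()
        lm = assign_territories(mask, [straight_line("LAD", 0.5, 0.5)])
        assert np.array_equal(lm.labels > 0, mask.data)
        assert np.all(lm.labels[mask.data] == 1)

    def test_two_parallel_lines_split_at_midplane(self):
        """Equidistant midplane split, boundary voxels to LAD by tie order."""
        mask = slab((21, 12, 6))
        lad = straight_line("LAD", 0.5, 0.5)
        lcx = straight_line("LCx", 20.5, 0.5)
        lm = assign_territories(mask, [lad, lcx])
        oracle, _ = nx_oracle_labels(mask, [lad, lcx])
        np.testing.assert_array_equal(lm.labels, oracle)
        # the centre column x=10 is equidistant: tie goes to LAD (label 1)
        assert np.all(lm.labels[10][mask.data[10]] == 1)
        assert np.all(lm.labels[:10][mask.data[:10]] == 1)
        assert np.all(lm.labels[11:][mask.data[11:]] == 2)

    def test_matches_bruteforce_dijkstra_on_irregular_mask(self):
        rng = np.random.default_rng(5)
        arr = np.ones((16, 10, 6), dtype=bool)
        # carve irregular holes so geodesic paths must bend
        arr[4:8, 3:7, :] = False
        arr[12, :5, :] = False
        mask = BinaryMask(arr, (1.0, 0.8, 1.2))
        lines = [
            straight_line("LAD", 0.5, 0.5, y1=7.5),
            straight_line("LCx", 15.5, 0.5, y1=7.5),
            Centerline("RCA", np.array([[8.0, 9.5, 0.5], [8.0, 9.5, 5.5]])),
        ]
        lm = assign_territories(mask, lines)
        oracle, legend = nx_oracle_labels(mask, lines)
        assert lm.legend == legend
        np.testing.assert_array_equal(lm.labels, oracle)

    def test_partition_covers_myocardium_exactly(self, small_truth):
        labels = small_truth.labelmap.labels
        assert np.array_equal(labels > 0, small_truth.myo.data)

    def test_translation_invariance(self):
        mask_a = BinaryMask(np.pad(np.ones((10, 8, 4), dtype=bool), ((0, 6), (0, 0), (0, 0))), (1, 1, 1))
        mask_b = BinaryMask(np.pad(np.ones((10, 8, 4), dtype=bool), ((6, 0), (0, 0), (0, 0))), (1, 1, 1))
        lines_a = [straight_line("LAD", 0.5, 0.5, y1=7.5),
                   straight_line("LCx", 9.5, 0.5, y1=7.5)]
        lines_b = [
            Centerline(c.label, c.points_mm + np.array([6.0, 0, 0])) for c in lines_a
        ]
        la = assign_territories(mask_a, lines_a)
        lb = assign_territories(mask_b, lines_b)
        np.testing.assert_array_equal(la.labels[:10], lb.labels[6:])

    def test_far_centerline_rejected(self):
        mask = slab((10, 10, 4))
        far = Centerline("LAD", np.array([[200.0, 0.0, 0.0], [200.0, 10.0, 0.0]]))
        with pytest.raises(ValueError, match="from the myocardium"):
            assign_territories(mask, [far], max_gap_mm=10.0)

    def test_moving_a_line_closer_does_not_steal_voxels(self):
        """Voxels labelled LAD stay LAD when the rival moves farther away."""
        mask = slab((21, 12, 6))
        lad = straight_line("LAD", 0.5, 0.5)
        near = assign_territories(mask, [lad, straight_line("LCx", 14.5, 0.5)])
        far = assign_territories(mask, [lad, straight_line("LCx", 20.5, 0.5)])
        lad_near = near.labels == 1
        assert np.all(far.labels[lad_near] == 1)


class TestPartitionDistal:
    def test_straight_line_splits_at_marker_bisector(self):
        mask = slab((8, 20, 4))
        # vessel runs along +y; stenosis at half arc-length (y = 10.5 of 0.5..19.5)
        line = Centerline(
            "LAD",
            np.array([[0.5, 0.5, 0.5], [0.5, 19.5, 0.5]]),
            stenosis_arclength_mm=9.5,
        )
        lm = assign_territories(mask, [line])
        out = partition_distal(lm, line, mask)
        names = set(out.legend.values())
        assert names == {"LAD-proximal", "LAD-distal"}
        prox = out.mask_for("LAD-proximal")
        dist = out.mask_for("LAD-distal")
        # brute-force: nearer source subset by Euclidean distance along y
        ys = (np.arange(20) + 0.5)
        boundary = 0.5 + 9.5  # marker position along the line
        for j, y in enumerate(ys):
            col_label = dist[0, j, 0]
            assert col_label == (y > boundary) or abs(y - boundary) < 1.0
        assert prox.sum() + dist.sum() == mask.n_voxels

    def test_degenerate_marker_rejected(self):
        mask = slab((8, 20, 4))
        line = Centerline(
            "LAD",
            np.array([[0.5, 0.5, 0.5], [0.5, 19.5, 0.5]]),
            stenosis_arclength_mm=19.0,
        )
        lm = assign_territories(mask, [line])
        bad = Centerline("LAD", line.points_mm, stenosis_arclength_mm=0.0)
        with pytest.raises(ValueError, match="degenerate|empty"):
            partition_distal(lm, bad, mask)

    def test_no_marker_rejected(self, small_truth):
        lad = small_truth.centerlines[0]
        with pytest.raises(ValueError, match="no stenosis marker"):
            partition_distal(small_truth.labelmap, lad, small_truth.myo)

    def test_phantom_distal_subterritory_dice(self):
        """Recovered distal mask overlaps the phantom truth (Dice > 0.95)."""
        import dataclasses

        from fpact.phantom import build_ground_truth, default_swine_spec

        spec = default_swine_spec(with_stenosis=True)
        spec = dataclasses.replace(
            spec,
            grid_shape=(48, 48, 48),
            spacing_mm=(0.9, 0.9, 1.0),
            center_mm=(21.6, 21.6, 36.0),
            aorta_center_mm=(21.6, 21.6, 42.0),
        )
        truth = build_ground_truth(spec)
        lad = next(c for c in truth.centerlines if c.label == "LAD")
        lm = assign_territories(truth.myo, truth.centerlines)
        lm = partition_distal(lm, lad, truth.myo)
        a = lm.mask_for("LAD-distal")
        b = truth.labelmap.mask_for("LAD-distal")
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice > 0.95


class TestTerritoryStats:
    def test_uniform_map(self, small_truth):
        vals = np.where(small_truth.myo.data, 1.7, np.nan)
        df = territory_stats(vals, small_truth.labelmap)
        assert np.allclose(df["mean"], 1.7)
        assert np.allclose(df["sd"], 0.0, atol=1e-9)

    def test_three_voxel_enumeration(self):
        labels = np.zeros((3, 1, 1), dtype=np.uint8)
        labels[:, 0, 0] = [1, 2, 2]
        lm = TerritoryLabelMap(labels, {1: "LAD", 2: "LCx"}, (1.0, 1.0, 1.0))
        vals = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        df = territory_stats(vals, lm)
        assert df.loc["LAD", "mean"] == 1.0
        assert df.loc["LCx", "mean"] == 2.5
        assert df.loc["LCx", "n_voxels"] == 2
        assert df.loc["LAD", "mass_g"] == pytest.approx(1.055e-3)

    def test_empty_territory_warns(self):
        labels = np.ones((2, 2, 2), dtype=np.uint8)
        lm = TerritoryLabelMap(labels, {1: "LAD", 2: "LCx"}, (1.0, 1.0, 1.0))
        vals = np.ones((2, 2, 2))
        with pytest.warns(UserWarning, match="no defined voxels"):
            df = territory_stats(vals, lm)
        assert np.isnan(df.loc["LCx", "mean"])

    def test_regional_cfr_is_ratio_of_means(self):
        labels = np.zeros((4, 1, 1), dtype=np.uint8)
        labels[:, 0, 0] = [1, 1, 2, 2]
        lm = TerritoryLabelMap(labels, {1: "LAD", 2: "LCx"}, (1.0, 1.0, 1.0))
        stress = np.array([2.0, 4.0, 3.0, 3.0]).reshape(4, 1, 1)
        rest = np.array([1.0, 2.0, 1.0, 2.0]).reshape(4, 1, 1)
        df = territory_cfr(stress, rest, lm)
        assert df.loc["LAD", "cfr"] == pytest.approx(3.0 / 1.5)
        assert df.loc["LCx", "cfr"] == pytest.approx(3.0 / 1.5)
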