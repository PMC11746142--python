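"""Vesicle morphometrics: skeleton traces, perimeters, nesting, thickness."""

import numpy as np
import pytest

from pspatools import morphometrics as mm
from pspatools import synthetic
from pspatools.morphometrics import MembraneTrace

PX = 7.0


def annulus_mask(shape, center, radius, half_width=2.5):
    rr, cc = np.indices(shape)
    d = np.hypot(rr - center[0], cc - center[1])
    return (np.abs(d - radius) <= half_width).astype(np.uint8)


def square_trace(pixel_size=10.0):
    pts = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
    return MembraneTrace(pts, closed=True, pixel_size=pixel_size)


class TestSkeletonize:
    def test_empty_mask(self):
        assert mm.skeletonize(np.zeros((64, 64), np.uint8), PX) == []

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mm.skeletonize(np.full((16, 16), 3, np.uint8), PX)

    def test_single_annulus_one_closed_trace(self):
        mask = annulus_mask((160, 160), (80, 80), 50)
        traces = mm.skeletonize(mask, PX)
        assert len(traces) == 1
        assert traces[0].closed

    def test_two_disjoint_annuli(self):
        mask = annulus_mask((160, 320), (80, 80), 40)
        mask |= annulus_mask((160, 320), (80, 240), 55)
        assert len(mm.skeletonize(mask, PX)) == 2

    def test_open_arc_is_open(self):
        rr, cc = np.indices((160, 160))
        d = np.hypot(rr - 80.0, cc - 80.0)
        mask = ((np.abs(d - 50) <= 2.5) & (cc >= 80)).astype(np.uint8)
        traces = mm.skeletonize(mask, PX)
        assert len(traces) == 1
        assert not traces[0].closed
        assert mm.select_closed(traces) == []

    def test_branched_component_discarded(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[10:54, 30:33] = 1  # vertical bar
        mask[30:33, 10:54] = 1  # crossing horizontal bar -> X junction
        assert mm.skeletonize(mask, PX) == []


class TestPerimeter:
    def test_unit_square_hand_value(self):
        assert mm.perimeter(square_trace(10.0)) == pytest.approx(4.0)

    def test_open_trace_rejected(self):
        t = MembraneTrace(np.array([[0, 0], [0, 1], [0, 2], [0, 3]], float), False, PX)
        with pytest.raises(ValueError):
            mm.perimeter(t)

    def test_rasterized_circle_within_5pct(self):
        mask = annulus_mask((260, 260), (130, 130), 100)
        (trace,) = mm.skeletonize(mask, PX)
        expected = 2 * np.pi * 100 * PX / 10.0  # 439.8 nm
        assert mm.perimeter(trace) == pytest.approx(expected, rel=0.05)

    def test_translation_invariance_exact(self):
        mask = annulus_mask((300, 300), (90, 90), 45)
        shifted = np.roll(np.roll(mask, 60, axis=0), 85, axis=1)
        (t1,) = mm.skeletonize(mask, PX)
        (t2,) = mm.skeletonize(shifted, PX)
        assert mm.perimeter(t1) == pytest.approx(mm.perimeter(t2), abs=1e-9)

    def test_rot90_invariance_exact(self):
        mask = annulus_mask((300, 300), (100, 140), 52)
        (t1,) = mm.skeletonize(mask, PX)
        (t2,) = mm.skeletonize(np.rot90(mask).copy(), PX)
        assert mm.perimeter(t1) == pytest.approx(mm.perimeter(t2), abs=1e-9)

    @pytest.mark.parametrize("angle", [17.0, 33.0])
    def test_arbitrary_rotation_within_2pct(self, angle):
        from scipy.ndimage import rotate

        mask = annulus_mask((300, 300), (150, 150), 70)
        rotated = (rotate(mask.astype(float), angle, reshape=False, order=1) > 0.5).astype(np.uint8)
        (t1,) = mm.skeletonize(mask, PX)
        (t2,) = mm.skeletonize(rotated, PX)
        assert mm.perimeter(t2) == pytest.approx(mm.perimeter(t1), rel=0.02)


class TestNesting:
    def _traces(self, radii, centers):
        shape = (400, 400)
        traces = []
        for r, c in zip(radii, centers):
            (t,) = mm.skeletonize(annulus_mask(shape, c, r), PX)
            traces.append(t)
        return traces

    def test_disjoint_circles_no_relation(self):
        traces = self._traces([40, 40], [(100, 100), (100, 300)])
        rel = mm.detect_nesting(traces)
        assert rel == {0: [], 1: []}

    def test_concentric_pair(self):
        traces = self._traces([30, 80], [(200, 200), (200, 200)])
        rel = mm.detect_nesting(traces)
        assert rel[0] == [1] and rel[1] == []

    def test_triple_nesting_multiple_enclosure(self):
        traces = self._traces([20, 50, 90], [(200, 200)] * 3)
        rel = mm.detect_nesting(traces)
        assert sorted(rel[0]) == [1, 2]
        assert rel[1] == [2] and rel[2] == []

    def test_nesting_graph_acyclic(self, small_field):
        import networkx as nx

        records = mm.analyze_field(small_field.mask, small_field.pixel_size)
        g = nx.DiGraph()
        g.add_nodes_from(range(len(records)))
        for i, rec in enumerate(records):
            g.add_edges_from((i, j) for j in rec.enclosed_by)
        assert nx.is_directed_acyclic_graph(g)


class TestEnclosureDistance:
    def test_concentric_analytic(self):
        shape = (400, 400)
        (inner,) = mm.skeletonize(annulus_mask(shape, (200, 200), 30), PX)
        (outer,) = mm.skeletonize(annulus_mask(shape, (200, 200), 80), PX)
        assert mm.enclosure_distance(inner, outer) == pytest.approx(50 * PX, abs=2 * PX)

    def test_translation_invariance(self):
        shape = (420, 420)
        a1 = annulus_mask(shape, (180, 180), 30)
        b1 = annulus_mask(shape, (180, 180), 80)
        a2 = np.roll(np.roll(a1, 37, axis=0), 55, axis=1)
        b2 = np.roll(np.roll(b1, 37, axis=0), 55, axis=1)
        (ta1,) = mm.skeletonize(a1, PX)
        (tb1,) = mm.skeletonize(b1, PX)
        (ta2,) = mm.skeletonize(a2, PX)
        (tb2,) = mm.skeletonize(b2, PX)
        assert mm.enclosure_distance(ta1, tb1) == pytest.approx(
            mm.enclosure_distance(ta2, tb2), abs=1e-9
        )


class TestBilayerThickness:
    def _field(self, spacing, pixel_size, noise=0.0, seed=4):
        rad = max(40 / pixel_size, spacing / pixel_size + 12)
        hw = 60 / pixel_size
        size = int(2 * (rad + spacing / (2 * pixel_size) + hw + 20))
        return synthetic.generate_vesicle_field(
            1, 0.0, image_shape=(size, size), pixel_size=pixel_size,
            radius_range_px=(rad, rad + 1), bilayer_spacing=float(spacing),
            spacing_limits=(10, 100), border_margin_px=hw + 3,
            noise_sigma=noise, seed=seed,
        )

    def test_noiseless_round_trip_31A(self):
        field = self._field(31.0, 1.0)
        (rec,) = mm.analyze_field(field.mask, 1.0, field.intensity)
        assert rec.bilayer_thickness_A == pytest.approx(31.0, abs=0.5)

    def test_noisy_round_trip_38A(self):
        field = self._field(38.0, 1.0, noise=0.1)  # noise s.d. 10% of contrast
        (rec,) = mm.analyze_field(field.mask, 1.0, field.intensity)
        assert rec.bilayer_thickness_A == pytest.approx(38.0, abs=1.0)

    def test_single_dark_ring_has_no_thickness(self):
        rr, cc = np.indices((200, 200))
        d = np.hypot(rr - 100.0, cc - 100.0)
        intensity = -np.exp(-0.5 * (np.abs(d - 50) / 1.5) ** 2)
        mask = (np.abs(d - 50) <= 3).astype(np.uint8)
        (trace,) = mm.skeletonize(mask, 1.0)
        assert mm.bilayer_thickness(trace, intensity, half_width_A=40.0) is None


class TestSummarize:
    def test_perimeter_100nm_gives_32nm_diameter(self):
        rec = mm.VesicleRecord(square_trace(), perimeter_nm=100.0)
        table = mm.summarize([rec])
        assert round(table.summary["mean_equivalent_diameter_nm"]) == 32

    def test_double_membrane_fraction_counting(self):
        records = [
            mm.VesicleRecord(square_trace(), 50.0, enclosed_by=[1] if i < 52 else [])
            for i in range(100)
        ]
        table = mm.summarize(records)
        assert table.summary["double_membrane_fraction"] == pytest.approx(0.52)

    def test_absent_thickness_statistics(self):
        records = [mm.VesicleRecord(square_trace(), 40.0) for _ in range(3)]
        table = mm.summarize(records)
        assert table.summary["n_thickness"] == 0
        assert table.summary["mean_bilayer_thickness_A"] is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.summarize([])
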