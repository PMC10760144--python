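import numpy as np
import pandas as pd
import pytest

from airscape import lumens


def tx_frame(xy, cell_ids=None, sample="S"):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame(
        {
            "x_location": xy[:, 0],
            "y_location": xy[:, 1],
            "feature_name": "g",
            "qv": 30.0,
            "cell_id": cell_ids if cell_ids is not None else [f"c{i}" for i in range(n)],
            "overlaps_nucleus": 1,
            "sample_id": sample,
        }
    )


def cells_frame(ids, types, xy=None):
    n = len(ids)
    xy = np.asarray(xy, dtype=float) if xy is not None else np.zeros((n, 2))
    return pd.DataFrame(
        {
            "cell_id": ids,
            "x_centroid": xy[:, 0],
            "y_centroid": xy[:, 1],
            "nucleus_area": 40.0,
            "sample_id": "S",
            "cell_type": types,
        }
    )


def annulus_cloud(center, r_in, r_out, density=2.0, seed=0):
    rng = np.random.default_rng(seed)
    area = np.pi * (r_out**2 - r_in**2)
    n = int(area * density)
    rad = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([center[0] + rad * np.cos(th), center[1] + rad * np.sin(th)])


def disk_cloud(center, r, density=2.0, seed=0):
    return annulus_cloud(center, 0.0, r, density, seed)


class TestRasterize:
    def test_single_transcript_single_pixel(self):
        img = lumens.rasterize(tx_frame([(5.0, 5.0)]), cells_frame(["c0"], ["AT1"]))
        assert img.mask.sum() == 1

    def test_immune_transcripts_excluded(self):
        tx = tx_frame([(0.0, 0.0), (10.0, 10.0)], ["c0", "c1"])
        cells = cells_frame(["c0", "c1"], ["T-cell", "AT1"])
        img = lumens.rasterize(tx, cells)
        assert img.mask.sum() == 1

    def test_unassigned_transcript_near_immune_cell_excluded(self):
        tx = tx_frame([(0.0, 0.0), (50.0, 50.0)], [None, "c1"])
        cells = cells_frame(["c0", "c1"], ["SPP1+ macrophage", "AT1"], [(1.0, 1.0), (50.0, 50.0)])
        img = lumens.rasterize(tx, cells)
        assert img.mask.sum() == 1

    def test_grid_matches_floor_quantization(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(1000, 2))
        cfg = lumens.RasterConfig(pixel_size=1.0)
        img = lumens.rasterize(tx_frame(pts), cells_frame(["x"], ["AT1"]), cfg)
        expected = {
            (int(np.floor(y - img.origin[1])), int(np.floor(x - img.origin[0])))
            for x, y in pts
        }
        got = set(zip(*np.nonzero(img.mask)))
        assert got == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lumens.rasterize(tx_frame(np.empty((0, 2))), cells_frame([], []))


class TestSegmentation:
    def test_annulus_yields_one_lumen_with_planted_area(self):
        pts = annulus_cloud((150, 150), 60, 90)
        img = lumens.rasterize(tx_frame(pts), cells_frame(["x"], ["AT1"]))
        seg = lumens.segment_lumens(img)
        assert seg.n_lumens == 1
        planted = np.pi * 60**2
        assert abs(next(iter(seg.areas_um2.values())) - planted) / planted < 0.10

    def test_solid_disk_has_no_lumens(self):
        pts = disk_cloud((100, 100), 80)
        img = lumens.rasterize(tx_frame(pts), cells_frame(["x"], ["AT1"]))
        seg = lumens.segment_lumens(img)
        assert seg.n_lumens == 0

    def test_two_holes_get_distinct_ids(self):
        shell = disk_cloud((200, 200), 180, density=2.0)
        keep = np.ones(len(shell), dtype=bool)
        for cx, cy, r in ((130, 200, 50), (280, 200, 45)):
            keep &= (shell[:, 0] - cx) ** 2 + (shell[:, 1] - cy) ** 2 > r**2
        img = lumens.rasterize(tx_frame(shell[keep]), cells_frame(["x"], ["AT1"]))
        seg = lumens.segment_lumens(img)
        assert seg.n_lumens == 2
        assert sorted(seg.areas_um2) == [1, 2]


class TestCellToLumen:
    @pytest.fixture(scope="class")
    def annulus_seg(self):
        pts = annulus_cloud((150, 150), 60, 90)
        img = lumens.rasterize(tx_frame(pts), cells_frame(["x"], ["AT1"]))
        return lumens.segment_lumens(img)

    def test_centroid_inside_lumen_joins_it(self, annulus_seg):
        cells = cells_frame(["c0"], ["AT1"], [(150.0, 150.0)])
        ids = lumens.assign_cells_to_lumens(cells, annulus_seg, wall_cutoff=10)
        assert ids.iloc[0] == 1

    def test_far_centroid_gets_zero(self, annulus_seg):
        cells = cells_frame(["c0"], ["AT1"], [(400.0, 400.0)])
        ids = lumens.assign_cells_to_lumens(cells, annulus_seg, wall_cutoff=10)
        assert ids.iloc[0] == 0

    def test_partition_property_and_brute_force(self, annulus_seg):
        rng = np.random.default_rng(1)
        th = rng.uniform(0, 2 * np.pi, 200)
        rad = rng.uniform(55, 100, 200)
        xy = np.column_stack([150 + rad * np.cos(th), 150 + rad * np.sin(th)])
        cells = cells_frame([f"c{i}" for i in range(200)], ["AT1"] * 200, xy)
        ids = lumens.assign_cells_to_lumens(cells, annulus_seg, wall_cutoff=10)
        assert len(ids) == 200  # exactly one id (possibly 0) per cell
        rows, cols = np.nonzero(annulus_seg.labels)
        centers = annulus_seg.image.pixel_centers(rows, cols)
        for i in range(200):
            d = np.linalg.norm(centers - xy[i], axis=1).min()
            assert (ids.iloc[i] > 0) == (d <= 10.0)

    def test_shrinking_cutoff_never_adds_members(self, annulus_seg):
        rng = np.random.default_rng(2)
        xy = rng.uniform(40, 260, size=(150, 2))
        cells = cells_frame([f"c{i}" for i in range(150)], ["AT1"] * 150, xy)
        wide = lumens.assign_cells_to_lumens(cells, annulus_seg, wall_cutoff=15)
        narrow = lumens.assign_cells_to_lumens(cells, annulus_seg, wall_cutoff=8)
        assert ((narrow > 0) <= (wide > 0)).all()


def lumen_row(lumen_id, n_cells, span, alveolar=0.7, airway=0.0, endo=0.0):
    row = {
        "lumen_id": lumen_id, "sample_id": "S", "n_cells": n_cells,
        "max_nucleus_distance": span, "area_um2": 10000.0,
    }
    from airscape.synthdata import AIRWAY_TYPES, ALVEOLAR_TYPES, NONCAP_ENDO_TYPES

    all_types = list(ALVEOLAR_TYPES) + list(AIRWAY_TYPES) + list(NONCAP_ENDO_TYPES) + ["Capillary"]
    for t in all_types:
        row[f"prop:{t}"] = 0.0
    for t in ALVEOLAR_TYPES:
        row[f"prop:{t}"] = alveolar / len(ALVEOLAR_TYPES)
    for t in AIRWAY_TYPES:
        row[f"prop:{t}"] = airway / len(AIRWAY_TYPES)
    for t in NONCAP_ENDO_TYPES:
        row[f"prop:{t}"] = endo / len(NONCAP_ENDO_TYPES)
    row["prop:Capillary"] = max(0.0, 1.0 - alveolar - airway - endo)
    return row


class TestAlveolarFilter:
    def test_size_and_span_boundaries(self):
        rows = [
            lumen_row(1, 24, 200),  # below cell minimum -> removed
            lumen_row(2, 25, 125),  # both boundaries inclusive -> kept
            lumen_row(3, 501, 200),  # above cell maximum -> removed
            lumen_row(4, 100, 124.9),  # below span -> removed
        ]
        df = pd.DataFrame(rows)
        cells = cells_frame(["c0"], ["AT1"])
        ids = pd.Series([0], index=pd.Index(["c0"], name="cell_id"), name="lumen_id")
        kept, rep = lumens.filter_alveolar(df, cells, ids)
        assert list(kept.lumen_id) == [2]
        assert rep.removed_size == 2
        assert rep.removed_span == 1

    def test_composition_triage_drops_airway_and_vascular_clusters(self):
        rows = [lumen_row(i, 100, 200, alveolar=0.7) for i in range(1, 9)]
        rows += [lumen_row(9, 100, 200, alveolar=0.0, airway=0.8)]
        rows += [lumen_row(10, 100, 200, alveolar=0.0, endo=0.8)]
        df = pd.DataFrame(rows)
        cells = cells_frame(["c0"], ["AT1"])
        ids = pd.Series([0], index=pd.Index(["c0"], name="cell_id"), name="lumen_id")
        kept, rep = lumens.filter_alveolar(df, cells, ids)
        assert set(kept.lumen_id) == set(range(1, 9))
        assert rep.removed_composition == 2

    def test_airway_niche_fraction_rule(self):
        rows = [lumen_row(i, 100, 200) for i in (1, 2)]
        df = pd.DataFrame(rows)
        members = [f"m{i}" for i in range(10)]
        cells = cells_frame(members, ["AT1"] * 10)
        ids = pd.Series([1] * 5 + [2] * 5, index=pd.Index(members, name="cell_id"), name="lumen_id")
        niche = pd.Series([9, 9, 1, 1, 1] + [1] * 5, index=pd.Index(members, name="cell_id"))
        kept, rep = lumens.filter_alveolar(
            df, cells, ids, cell_niche=niche, airway_niches=[9], kmeans_k=2
        )
        # lumen 1 has 40% of cells in the airway niche -> removed
        assert list(kept.lumen_id) == [2]
        assert rep.removed_airway_niche == 1

    def test_too_few_lumens_skips_composition_step(self):
        df = pd.DataFrame([lumen_row(1, 100, 200)])
        cells = cells_frame(["c0"], ["AT1"])
        ids = pd.Series([0], index=pd.Index(["c0"], name="cell_id"), name="lumen_id")
        with pytest.warns(UserWarning):
            kept, rep = lumens.filter_alveolar(df, cells, ids)
        assert rep.composition_skipped
        assert len(kept) == 1
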