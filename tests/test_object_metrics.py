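"""Per-object statistics against naive brute-force oracles and hand values."""

import math

import numpy as np
import pandas as pd
import pytest

import fretcoloc as fc
from conftest import small_scene


def brute_pearson(pairs):
    """Textbook product-moment formula with explicit Python loops."""
    n = len(pairs)
    mx = sum(p[0] for p in pairs) / n
    my = sum(p[1] for p in pairs) / n
    sxy = sum((x - mx) * (y - my) for x, y in pairs)
    sxx = sum((x - mx) ** 2 for x, _ in pairs)
    syy = sum((y - my) ** 2 for _, y in pairs)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def brute_colormix(pairs):
    total = 0.0
    for x, y in pairs:
        hi = max(x, y)
        total += (min(x, y) / hi) if hi > 0 else 0.0
    return total / len(pairs)


def brute_nfret(triplets):
    """Mean of FRETc / sqrt(DF*AF) over pixels where both channels > 0."""
    vals = [f / math.sqrt(d * a) for f, d, a in triplets if d > 0 and a > 0]
    return sum(vals) / len(vals) if vals else float("nan")


def _objects_from(labels):
    labels = np.asarray(labels)
    return fc.LabeledObjects(labels=labels, n_objects=int(labels.max()), provenance="union")


def _line_object(df_vals, af_vals):
    """Single-object scene holding the given pixel value sequences."""
    n = len(df_vals)
    labels = np.ones((1, n), dtype=np.int32)
    df = np.asarray(df_vals, dtype=np.uint16).reshape(1, n)
    af = np.asarray(af_vals, dtype=np.uint16).reshape(1, n)
    return _objects_from(labels), df, af


class TestPearsonPerObject:
    def test_perfect_linear_relation_is_one(self):
        objs, df, af = _line_object([10, 20, 30, 40], [25, 45, 65, 85])  # AF = 2 DF + 5
        assert fc.pearson_per_object(objs, df, af)[1] == pytest.approx(1.0)

    def test_perfect_anticorrelation_is_minus_one(self):
        df_vals = [10, 30, 60, 90]
        objs, df, af = _line_object(df_vals, [100 - v for v in df_vals])
        assert fc.pearson_per_object(objs, df, af)[1] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        objs, df, af = _line_object([1, 2, 3, 4], [2, 1, 4, 3])
        assert fc.pearson_per_object(objs, df, af)[1] == pytest.approx(0.6)

    def test_zero_variance_object_is_undefined(self):
        objs, df, af = _line_object([5, 5, 5], [1, 2, 3])
        assert math.isnan(fc.pearson_per_object(objs, df, af)[1])


class TestColormix:
    def test_equal_channels_give_complete_mix(self):
        objs, df, af = _line_object([50, 80, 120], [50, 80, 120])
        assert fc.colormix_per_object(objs, df, af)[1] == pytest.approx(1.0)

    def test_single_marker_gives_zero(self):
        objs, df, af = _line_object([50, 80, 120], [0, 0, 0])
        assert fc.colormix_per_object(objs, df, af)[1] == pytest.approx(0.0)

    def test_symmetric_half_ratio(self):
        objs, df, af = _line_object([50, 100], [100, 50])
        assert fc.colormix_per_object(objs, df, af)[1] == pytest.approx(0.5)


class TestAdRatio:
    def test_simple_ratio(self):
        objs, df, af = _line_object([200, 200], [400, 400])
        assert fc.ad_ratio_per_object(objs, df, af)[1] == pytest.approx(2.0)

    def test_zero_acceptor_is_zero(self):
        objs, df, af = _line_object([200, 200], [0, 0])
        assert fc.ad_ratio_per_object(objs, df, af)[1] == pytest.approx(0.0)

    def test_zero_donor_is_undefined(self):
        objs, df, af = _line_object([0, 0], [100, 100])
        assert math.isnan(fc.ad_ratio_per_object(objs, df, af)[1])


class TestNfretPerObject:
    @staticmethod
    def _fret_images(df, af, fretc):
        mk = lambda v, role: fc.ChannelImage(np.asarray(v, dtype=np.uint16), 12, role)
        stack = fc.TripleStack(mk(df, "donor"), mk(af, "acceptor"),
                               mk(np.zeros_like(df), "rawfret"))
        nfret, defined = fc.compute_nfret(np.asarray(fretc, dtype=float), stack)
        return stack, fc.FretImages(np.asarray(fretc, dtype=float), nfret, defined,
                                    fc.BleedthroughFactors(0.0, 0.0))

    def test_uniform_object_identical_in_both_modes(self):
        shape = (1, 5)
        df = np.full(shape, 200); af = np.full(shape, 400); fretc = np.full(shape, 60.0)
        stack, fret = self._fret_images(df, af, fretc)
        objs = _objects_from(np.ones(shape, dtype=np.int32))
        expected = 60.0 / math.sqrt(200 * 400)
        assert fc.nfret_per_object(objs, fret)[1] == pytest.approx(expected)
        assert fc.nfret_per_object(objs, fret, stack=stack, mode="ratio_of_means")[1] \
            == pytest.approx(expected)
        assert expected == pytest.approx(0.2121, abs=5e-5)

    def test_zero_fretc_gives_zero_nfret(self):
        shape = (1, 4)
        stack, fret = self._fret_images(np.full(shape, 100), np.full(shape, 100),
                                        np.zeros(shape))
        objs = _objects_from(np.ones(shape, dtype=np.int32))
        assert fc.nfret_per_object(objs, fret)[1] == pytest.approx(0.0)

    def test_object_with_no_defined_pixels_is_undefined(self):
        shape = (1, 4)
        stack, fret = self._fret_images(np.zeros(shape), np.full(shape, 100),
                                        np.full(shape, 5.0))
        objs = _objects_from(np.ones(shape, dtype=np.int32))
        assert math.isnan(fc.nfret_per_object(objs, fret)[1])


def test_metrics_match_brute_force_loops_on_random_scenes(true_factors):
    """Vectorized per-object Pearson / color-mix / NFRET equal naive loops (rtol 1e-10)."""
    for seed in range(20):
        stack, _ = small_scene(shape=(128, 128), n_objects=5, overlap_fraction=0.4,
                               intensity_correlation=0.5, poisson=False,
                               gaussian_sd=3.0, seed=900 + seed)
        res = fc.analyze_triple(stack, true_factors, threshold_method="otsu")
        objs = res.objects["union"]
        fret = res.fret
        pearsons = fc.pearson_per_object(objs, stack.donor, stack.acceptor)
        mixes = fc.colormix_per_object(objs, stack.donor, stack.acceptor)
        nfrets = fc.nfret_per_object(objs, fret)
        for oid in objs.object_ids():
            coords = list(zip(*np.nonzero(objs.labels == oid)))
            pix = [(float(stack.donor.pixels[rc]), float(stack.acceptor.pixels[rc]))
                   for rc in coords]
            tri = [(float(fret.fretc[rc]), float(stack.donor.pixels[rc]),
                    float(stack.acceptor.pixels[rc])) for rc in coords]
            bp = brute_pearson(pix)
            if math.isnan(bp):
                assert math.isnan(pearsons[oid])
            else:
                assert pearsons[oid] == pytest.approx(bp, rel=1e-10)
            assert mixes[oid] == pytest.approx(brute_colormix(pix), rel=1e-10)
            bn = brute_nfret(tri)
            if math.isnan(bn):
                assert math.isnan(nfrets[oid])
            else:
                assert nfrets[oid] == pytest.approx(bn, rel=1e-10)


def test_object_pearson_recovers_programmed_correlation():
    """Mean object Pearson estimates rho within 3 SEM across >= 100 objects."""
    for rho in (0.0, 0.5, 0.9):
        stack, _ = small_scene(shape=(512, 512), n_objects=110, radius_range=(6.0, 10.0),
                               overlap_fraction=1.0, intensity_correlation=rho,
                               poisson=False, gaussian_sd=4.0, seed=300 + int(rho * 10))
        res = fc.analyze_triple(stack, fc.BleedthroughFactors(0.15, 0.05),
                                threshold_method="otsu")
        vals = res.object_table["pearson"].dropna()
        assert len(vals) >= 100
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - rho) < 3 * max(sem, 1e-3)


class TestColocAreaFraction:
    @staticmethod
    def _mask(px):
        return fc.BinaryMask(np.asarray(px, dtype=bool), "manual", 0.0)

    def test_identical_masks_are_fully_colocalized(self, rng):
        a = rng.random((20, 20)) > 0.6
        pct, _ = fc.coloc_area_fraction(self._mask(a), self._mask(a))
        assert pct == pytest.approx(100.0)

    def test_disjoint_masks_are_zero(self):
        u = np.zeros((10, 10), dtype=bool); u[:5] = True
        i = np.zeros((10, 10), dtype=bool)
        pct, _ = fc.coloc_area_fraction(self._mask(u), self._mask(i))
        assert pct == 0.0

    def test_counting_example(self):
        u = np.zeros((20, 20), dtype=bool); u.flat[:200] = True
        i = np.zeros((20, 20), dtype=bool); i.flat[:50] = True
        pct, _ = fc.coloc_area_fraction(self._mask(u), self._mask(i))
        assert pct == pytest.approx(25.0)

    def test_empty_union_yields_zero_not_nan(self):
        empty = self._mask(np.zeros((5, 5), dtype=bool))
        assert fc.coloc_area_fraction(empty, empty)[0] == 0.0


class TestBuildObjectTable:
    def test_areas_sum_to_foreground_and_columns_fixed(self, distinct_analysis):
        table = distinct_analysis.object_table
        assert list(table.columns) == fc.OBJECT_TABLE_COLUMNS
        labeled_area = int((distinct_analysis.objects["union"].labels > 0).sum())
        assert int(table["area_px"].sum()) == labeled_area

    def test_object_touching_saturated_pixel_is_flagged(self, overexposed_analysis):
        table = overexposed_analysis.object_table
        assert table["saturated_flag"].any()
        # overexposed scene: bright objects are pinned at full scale
        assert table.loc[table["saturated_flag"], "mean_DF"].max() > 3000

    def test_empty_label_map_gives_empty_table(self, true_factors):
        z = np.zeros((8, 8), dtype=np.uint16)
        mk = lambda role: fc.ChannelImage(z, 12, role)
        stack = fc.TripleStack(mk("donor"), mk("acceptor"), mk("rawfret"))
        fret = fc.compute_fret_images(stack, true_factors)
        objs = fc.LabeledObjects(np.zeros((8, 8), dtype=np.int32), 0, "union")
        table = fc.build_object_table(stack, fret, objs)
        assert len(table) == 0 and list(table.columns) == fc.OBJECT_TABLE_COLUMNS


def test_whole_image_pearson_misleads_where_object_pearson_does_not(
        distinct_scene, distinct_analysis):
    """Object restriction removes the shared-background inflation of Pearson."""
    stack, _ = distinct_scene
    whole = fc.whole_image_pearson(stack.donor, stack.acceptor)
    per_object = distinct_analysis.object_table["pearson"].dropna().mean()
    assert abs(per_object) < 0.1
    assert math.isfinite(whole)


def test_saturation_artifact_raises_whole_image_pearson_and_colormix(
        distinct_scene, overexposed_scene):
    """Clipping both channels fakes colocalization: both scores strictly rise."""
    correct, _ = distinct_scene
    clipped, _ = overexposed_scene
    assert fc.whole_image_pearson(clipped.donor, clipped.acceptor) > \
        fc.whole_image_pearson(correct.donor, correct.acceptor)
    fg_correct = fc.auto_threshold(correct.donor, "otsu").pixels | \
        fc.auto_threshold(correct.acceptor, "otsu").pixels
    fg_clipped = fc.auto_threshold(clipped.donor, "otsu").pixels | \
        fc.auto_threshold(clipped.acceptor, "otsu").pixels
    cm_correct = fc.colormix_image(correct.donor, correct.acceptor)[fg_correct].mean()
    cm_clipped = fc.colormix_image(clipped.donor, clipped.acceptor)[fg_clipped].mean()
    assert cm_clipped > cm_correct
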