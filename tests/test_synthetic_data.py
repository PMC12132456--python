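"""Model spectra, scene generation, experiment designs, seed determinism."""

import numpy as np
import pytest

from cosidex.decoder import classify_cells
from cosidex.image_pipeline import extract_cell_spectra
from cosidex.reference_library import ReferenceLibrary, ReferenceSpectrum
from cosidex.spectral_core import cosine_similarity, pairwise_similarity_matrix
from cosidex.synthetic_data import (
    CellSpec,
    SceneSpec,
    SyntheticFP,
    confusable_pair,
    default_fp_panel,
    model_spectrum,
    simulate_experiment,
    simulate_scene,
)
from conftest import extract_experiment


def library_from_fps(fps, scheme=None):
    return ReferenceLibrary(
        references=[
            ReferenceSpectrum(fp_name=fp.name, spectrum=model_spectrum(fp, scheme))
            for fp in fps
        ]
    )


class TestModelSpectrum:
    def test_out_of_range_emission_gives_zero_spectrum(self, scheme):
        fp = SyntheticFP(name="uv", ex_max_nm=300.0, em_max_nm=330.0, em_width_nm=10.0)
        assert model_spectrum(fp, scheme).values.sum() == 0.0

    def test_identical_parameters_give_unit_similarity(self, scheme):
        a = SyntheticFP(name="a", ex_max_nm=488.0, em_max_nm=510.0)
        b = SyntheticFP(name="b", ex_max_nm=488.0, em_max_nm=510.0)
        sim = cosine_similarity(model_spectrum(a, scheme), model_spectrum(b, scheme))
        assert sim == pytest.approx(1.0)

    def test_green_vs_orange_fps_resolvable(self, scheme):
        egfp_like = SyntheticFP(name="g", ex_max_nm=488.0, em_max_nm=507.0)
        mko_like = SyntheticFP(name="o", ex_max_nm=548.0, em_max_nm=559.0)
        sim = cosine_similarity(
            model_spectrum(egfp_like, scheme), model_spectrum(mko_like, scheme)
        )
        assert sim < 0.5

    def test_notch_guard_zeroes_channels_near_laser(self, scheme):
        fp = SyntheticFP(name="g", ex_max_nm=488.0, em_max_nm=500.0)
        spec = model_spectrum(fp, scheme)
        block3 = scheme.block_slices()[2]
        centers = scheme.blocks[2].channel_centers_nm()
        guarded = spec.values[block3][centers < 498.0]
        assert np.all(guarded == 0.0)

    def test_stokes_shift_invariant_enforced(self):
        with pytest.raises(ValueError):
            SyntheticFP(name="bad", ex_max_nm=500.0, em_max_nm=490.0)


class TestDefaultPanel:
    def test_panel_of_12_is_resolvable(self, scheme):
        specs = [model_spectrum(fp, scheme) for fp in default_fp_panel(12)]
        mat = pairwise_similarity_matrix(specs)
        off_diag = mat[np.triu_indices(12, k=1)]
        assert off_diag.max() < 0.9

    def test_small_panels(self, scheme):
        assert len(default_fp_panel(1)) == 1
        specs = [model_spectrum(fp, scheme) for fp in default_fp_panel(3)]
        mat = pairwise_similarity_matrix(specs)
        assert mat[np.triu_indices(3, k=1)].max() < 0.9

    def test_out_of_range_size_rejected(self):
        for n in (0, 16):
            with pytest.raises(ValueError):
                default_fp_panel(n)

    def test_confusable_pair_is_confusable(self, scheme):
        a, b = confusable_pair()
        sim = cosine_similarity(model_spectrum(a, scheme), model_spectrum(b, scheme))
        assert sim > 0.95

    def test_confusable_pair_misclassifies_under_noise(self, scheme):
        a, b = confusable_pair()
        panel = {a.name: a, b.name: b}
        from cosidex.synthetic_data import _grid_layout

        rng = np.random.default_rng(7)
        centers, shape = _grid_layout(200, 3, rng)
        cells_spec = [
            CellSpec(center=c, radius=3, fp_name=(a.name if i < 100 else b.name),
                     expression_level=300.0)
            for i, c in enumerate(centers)
        ]
        scene = simulate_scene(
            SceneSpec(image_shape=shape, cells=cells_spec, seed=11, gaussian_sd=30.0),
            panel, scheme,
        )
        cells = extract_cell_spectra(scene.stack, scene.mask, truth_labels=scene.truth)
        res = classify_cells(cells, library_from_fps((a, b), scheme))
        wrong = sum(p != t for p, t in zip(res.predicted_fp, cells.truth_labels))
        assert wrong / cells.n_cells > 0.10


class TestSimulateScene:
    def test_noise_free_round_trip_unit_similarity(self, scheme):
        fp = default_fp_panel(1)[0]
        spec = SceneSpec(
            image_shape=(24, 24),
            cells=[CellSpec(center=(12, 12), radius=4, fp_name=fp.name,
                            expression_level=1e4)],
            seed=1, gaussian_sd=0.0, background_level=0.0,
        )
        scene = simulate_scene(spec, {fp.name: fp}, scheme)
        cells = extract_cell_spectra(scene.stack, scene.mask)
        sim = cosine_similarity(cells.matrix[0], model_spectrum(fp, scheme))
        assert sim == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_identical_stacks(self, scheme):
        fp = default_fp_panel(1)[0]
        spec = SceneSpec(
            image_shape=(24, 24),
            cells=[CellSpec(center=(12, 12), radius=4, fp_name=fp.name,
                            expression_level=1e3)],
            seed=5, gaussian_sd=10.0,
        )
        a = simulate_scene(spec, {fp.name: fp}, scheme)
        b = simulate_scene(spec, {fp.name: fp}, scheme)
        assert np.array_equal(a.stack.pixels, b.stack.pixels)
        assert np.array_equal(a.mask.labels, b.mask.labels)

    def test_out_of_bounds_cell_rejected(self, scheme):
        fp = default_fp_panel(1)[0]
        spec = SceneSpec(
            image_shape=(20, 20),
            cells=[CellSpec(center=(1, 1), radius=5, fp_name=fp.name,
                            expression_level=1e3)],
            seed=0,
        )
        with pytest.raises(ValueError, match="out of bounds"):
            simulate_scene(spec, {fp.name: fp}, scheme)

    def test_overlapping_cells_flagged(self, scheme):
        fp = default_fp_panel(1)[0]
        spec = SceneSpec(
            image_shape=(30, 30),
            cells=[
                CellSpec(center=(15, 13), radius=4, fp_name=fp.name,
                         expression_level=1e3),
                CellSpec(center=(15, 17), radius=4, fp_name=fp.name,
                         expression_level=1e3),
            ],
            seed=0,
        )
        scene = simulate_scene(spec, {fp.name: fp}, scheme)
        assert scene.overlapping_cells == [2]

    def test_scene_spec_json_round_trip(self, tmp_path):
        fp = default_fp_panel(1)[0]
        spec = SceneSpec(
            image_shape=(20, 20),
            cells=[CellSpec(center=(10, 10), radius=3, fp_name=fp.name,
                            expression_level=500.0)],
            seed=3,
        )
        path = tmp_path / "scene.json"
        spec.to_json(path)
        assert SceneSpec.from_json(path) == spec


class TestSimulateExperiment:
    def test_fpmo_truth_contains_no_missing_fp(self):
        exp = simulate_experiment("fpmo", n_fps=3, n_cells=60, seed=4,
                                  missing_fp="sFP460")
        truth = exp.scenes[0].truth
        assert "sFP460" not in truth.values()
        assert exp.missing_fp == "sFP460"

    def test_clonal_growth_monotone_and_diluting(self):
        exp = simulate_experiment("clonal_growth", n_fps=2, n_cells=4, days=3,
                                  seed=6, noise_sd=0.0)
        sizes = [len(s.truth) for s in exp.scenes]
        assert sizes[0] < sizes[1] < sizes[2]
        expr_by_day = [
            max(c.expression_level for c in s.spec.cells) for s in exp.scenes
        ]
        assert expr_by_day[0] > expr_by_day[1] > expr_by_day[2]

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            simulate_experiment("mystery", seed=0)

    def test_expression_scaling_leaves_labels_unchanged(self, noisefree_library3):
        exp = simulate_experiment("equal_mix", n_fps=3, n_cells=50,
                                  noise_sd=0.0, seed=21)
        cells = extract_experiment(exp)["equal_mix"]
        base = classify_cells(cells, noisefree_library3)
        scaled_matrix = cells.matrix.copy()
        scaled_matrix[::2] *= 10.0
        from cosidex.image_pipeline import CellSpectraMatrix

        scaled = CellSpectraMatrix(cell_ids=cells.cell_ids, matrix=scaled_matrix)
        after = classify_cells(scaled, noisefree_library3)
        assert base.predicted_fp == after.predicted_fp

    def test_error_monotone_in_reference_similarity(self, scheme):
        # sweep a pair from well-separated to nearly identical at fixed noise:
        # the misclassification rate must not decrease as similarity rises
        from cosidex.synthetic_data import _grid_layout

        sims, errors = [], []
        for offset in (40.0, 10.0, 4.0, 1.0):
            a = SyntheticFP(name="a", ex_max_nm=488.0, em_max_nm=507.0)
            b = SyntheticFP(name="b", ex_max_nm=488.0, em_max_nm=507.0 + offset)
            panel = {a.name: a, b.name: b}
            rng = np.random.default_rng(int(offset * 10))
            centers, shape = _grid_layout(150, 3, rng)
            cells_spec = [
                CellSpec(center=c, radius=3,
                         fp_name=(a.name if i < 75 else b.name),
                         expression_level=300.0)
                for i, c in enumerate(centers)
            ]
            scene = simulate_scene(
                SceneSpec(image_shape=shape, cells=cells_spec, seed=17,
                          gaussian_sd=30.0),
                panel, scheme,
            )
            cells = extract_cell_spectra(scene.stack, scene.mask,
                                         truth_labels=scene.truth)
            res = classify_cells(cells, library_from_fps((a, b), scheme))
            sims.append(cosine_similarity(model_spectrum(a, scheme),
                                          model_spectrum(b, scheme)))
            errors.append(
                sum(p != t for p, t in zip(res.predicted_fp, cells.truth_labels))
                / cells.n_cells
            )
        assert sims == sorted(sims)
        assert errors == sorted(errors)

    def test_noise_free_identifiability(self, noisefree_library3):
        exp = simulate_experiment("equal_mix", n_fps=3, n_cells=120,
                                  noise_sd=0.0, seed=31)
        cells = extract_experiment(exp)["equal_mix"]
        res = classify_cells(cells, noisefree_library3)
        assert all(p == t for p, t in zip(res.predicted_fp, cells.truth_labels))
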