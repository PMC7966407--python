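"""Geometry, montage constraints, synthetic sensitivity and forward model."""

import numpy as np
import pytest

import nirsdot as nd
from nirsdot.anatomy import (
    MAX_SEPARATION_MM,
    MIN_SEPARATION_MM,
    MontageInfeasibleError,
    compute_fov,
)


class TestToyAnatomy:
    def test_roi_is_contiguous_and_large_enough(self, surface):
        assert len(surface.roi_vertices) >= 5
        adj = surface.adjacency()
        roi = set(int(v) for v in surface.roi_vertices)
        seen = {next(iter(roi))}
        stack = list(seen)
        while stack:
            v = stack.pop()
            for w in adj[v] & roi - seen:
                seen.add(w)
                stack.append(w)
        assert seen == roi

    def test_deterministic_for_fixed_seed(self):
        a = nd.generate_toy_anatomy(n_vertices=200, seed=5)
        b = nd.generate_toy_anatomy(n_vertices=200, seed=5)
        np.testing.assert_array_equal(a.vertex_positions, b.vertex_positions)
        np.testing.assert_array_equal(a.roi_vertices, b.roi_vertices)
        c = nd.generate_toy_anatomy(n_vertices=200, seed=6)
        assert not np.array_equal(a.vertex_positions, c.vertex_positions)

    def test_scalp_strictly_outside_cortex(self, surface):
        r_cortex = np.linalg.norm(surface.vertex_positions, axis=1)
        r_scalp = np.linalg.norm(surface.scalp_positions, axis=1)
        assert np.all(r_scalp - r_cortex >= 10.0 - 1e-9)

    @pytest.mark.parametrize(
        "kwargs", [dict(n_vertices=10), dict(roi_radius_mm=0.001)]
    )
    def test_degenerate_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nd.generate_toy_anatomy(**kwargs, seed=0)


class TestMontage:
    def test_separation_constraints_hold(self, montage):
        for s, d in montage.channels:
            sep = montage.channel_separation_mm(s, d)
            assert MIN_SEPARATION_MM - 1e-9 <= sep <= MAX_SEPARATION_MM + 1e-9

    def test_every_source_in_two_channels(self, montage):
        counts = np.bincount(
            [s for s, _ in montage.channels], minlength=len(montage.source_positions)
        )
        assert counts.min() >= 2

    def test_minimal_montage_one_source(self, surface):
        m = nd.generate_montage(surface, n_sources=1, n_detectors=2, seed=0)
        assert len(m.channels) == 2
        assert all(s == 0 for s, _ in m.channels)

    def test_too_few_detectors_is_infeasible(self, surface):
        with pytest.raises(MontageInfeasibleError):
            nd.generate_montage(surface, n_sources=4, n_detectors=1, seed=0)


class TestSensitivity:
    def test_entries_nonnegative_and_row_peak_between_optodes(
        self, surface, montage, sensitivity
    ):
        A = sensitivity.A_per_wavelength[830.0]
        assert np.all(A >= 0)
        for c, (s, d) in enumerate(montage.channels):
            # brute-force argmax must sit between the two optode projections
            v = surface.vertex_positions[np.argmax(A[c])]
            src, det = montage.source_positions[s], montage.detector_positions[d]
            sep = np.linalg.norm(src - det)
            assert np.linalg.norm(v - src) <= sep
            assert np.linalg.norm(v - det) <= sep

    def test_wavelengths_differ_only_by_gain(self, sensitivity):
        a, b = (sensitivity.A_per_wavelength[lam] for lam in (685.0, 830.0))
        ratio = b[a > 1e-12] / a[a > 1e-12]
        assert np.allclose(ratio, ratio.flat[0])

    def test_fov_recomputation_matches_stored(self, sensitivity):
        fov = compute_fov(
            sensitivity.A_per_wavelength, sensitivity.fov_threshold_fraction
        )
        np.testing.assert_array_equal(fov, sensitivity.fov_vertices)

    def test_fov_threshold_definition(self, sensitivity):
        stacked = np.vstack(list(sensitivity.A_per_wavelength.values()))
        best = stacked.max(axis=0)
        thr = 0.1 * stacked.max()
        inside = np.zeros(stacked.shape[1], bool)
        inside[sensitivity.fov_vertices] = True
        assert np.all(best[inside] >= thr)
        assert np.all(best[~inside] < thr)

    def test_symmetric_under_optode_swap(self, surface, montage, sensitivity):
        # exchanging the source and detector of a channel leaves its
        # sensitivity row unchanged (the kernel depends on d_s + d_d)
        v = surface.vertex_positions
        for c, (s, d) in enumerate(montage.channels):
            src = montage.source_positions[s]
            det = montage.detector_positions[d]
            swapped = np.exp(
                -(np.linalg.norm(v - det, axis=1) + np.linalg.norm(v - src, axis=1))
                / 12.0
            )
            row = sensitivity.A_per_wavelength[685.0][c]
            np.testing.assert_allclose(row, row.max() * swapped / swapped.max(),
                                       rtol=1e-10)

    def test_roi_vertex_inside_fov(self, surface, sensitivity):
        assert np.any(np.isin(surface.roi_vertices, sensitivity.fov_vertices))

    def test_large_decay_includes_everything(self, surface, montage):
        sens = nd.compute_synthetic_sensitivity(surface, montage, decay_scale_mm=1e9)
        assert len(sens.fov_vertices) == surface.n_vertices


class TestForwardProject:
    def test_zero_absorption_gives_zero_od(self, sensitivity):
        V = sensitivity.n_vertices
        dmua = {lam: np.zeros((V, 4)) for lam in sensitivity.wavelengths}
        od = nd.forward_project(sensitivity, dmua)
        for lam in od.wavelengths:
            assert np.all(od.values[lam] == 0)

    def test_unit_impulse_reads_out_sensitivity_column(self, sensitivity):
        V = sensitivity.n_vertices
        v = int(sensitivity.fov_vertices[0])
        dmua = {lam: np.zeros((V, 1)) for lam in sensitivity.wavelengths}
        for lam in dmua:
            dmua[lam][v, 0] = 1.0
        od = nd.forward_project(sensitivity, dmua)
        for lam in od.wavelengths:
            np.testing.assert_allclose(
                od.values[lam][:, 0], sensitivity.A_per_wavelength[lam][:, v]
            )

    def test_linearity_against_loop_oracle(self, sensitivity, rng):
        V = sensitivity.n_vertices
        x = {lam: rng.normal(size=(V, 3)) for lam in sensitivity.wavelengths}
        y = {lam: rng.normal(size=(V, 3)) for lam in sensitivity.wavelengths}
        a, b = 0.7, -1.3
        comb = {lam: a * x[lam] + b * y[lam] for lam in x}
        lhs = nd.forward_project(sensitivity, comb)
        fx = nd.forward_project(sensitivity, x)
        fy = nd.forward_project(sensitivity, y)
        for lam in lhs.wavelengths:
            np.testing.assert_allclose(
                lhs.values[lam],
                a * fx.values[lam] + b * fy.values[lam],
                rtol=1e-12,
                atol=1e-14,
            )
        # explicit loop oracle on one wavelength, a few vertices
        lam = 830.0
        A = sensitivity.A_per_wavelength[lam]
        oracle = np.zeros_like(fx.values[lam][:, 0])
        for v in range(V):
            oracle += A[:, v] * x[lam][v, 0]
        np.testing.assert_allclose(fx.values[lam][:, 0], oracle, rtol=1e-12)

    def test_dimension_mismatch_raises(self, sensitivity):
        bad = {lam: np.zeros((3, 4)) for lam in sensitivity.wavelengths}
        with pytest.raises(ValueError):
            nd.forward_project(sensitivity, bad)
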