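"""Motion-correction contracts: matching, solver optimality, artifacts."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from vnc2p.registration import (
    MatchSet,
    RegistrationParams,
    compute_matches,
    detect_artifacts,
    estimate_motion,
    grid_search,
    register_movie,
    registration_energy,
    registration_quality,
    warp_frame,
)
from vnc2p.synthetic import (
    SyntheticConfig,
    invert_field,
    make_structural_template,
    warp_image,
)


def translation_field(shape, dr, dc):
    f = np.zeros(shape + (2,))
    f[..., 0] = dr
    f[..., 1] = dc
    return f


class TestComputeMatches:
    def test_identity_yields_zero_vectors(self, template):
        m = compute_matches(template, template)
        assert len(m) > 0
        np.testing.assert_array_equal(m.vectors, 0)

    def test_integer_translation_recovered(self, template):
        # oracle: exhaustive integer-shift search over +-8 px per keypoint
        field = translation_field(template.shape, 3, -2)
        frame = warp_image(template, invert_field(field))
        m = compute_matches(template, frame)
        assert len(m) > 0
        np.testing.assert_array_equal(np.median(m.vectors, axis=0), [3, -2])
        # cross-check a few keypoints against brute-force integer search
        for kp, vec in list(zip(m.keypoints, m.vectors))[:5]:
            r, c = kp
            if not (12 <= r < 52 and 12 <= c < 52):
                continue
            patch = template[r - 4:r + 5, c - 4:c + 5]
            best, best_err = None, np.inf
            for dr in range(-8, 9):
                for dc in range(-8, 9):
                    cand = frame[r + dr - 4:r + dr + 5, c + dc - 4:c + dc + 5]
                    err = np.abs(cand - patch).sum()
                    if err < best_err:
                        best, best_err = (dr, dc), err
            assert tuple(vec) == best

    def test_blank_frame_gives_empty_set(self):
        blank = np.full((64, 64), 7.0)
        assert len(compute_matches(blank, blank)) == 0

    def test_shape_mismatch_rejected(self, template):
        with pytest.raises(ValueError):
            compute_matches(template, template[:32])


class TestWarpFrame:
    def test_zero_field_is_identity(self, template):
        out = warp_frame(template, np.zeros(template.shape + (2,)))
        np.testing.assert_array_equal(out, template)

    def test_integer_translation_matches_index_shift(self, template):
        out = warp_frame(template, translation_field(template.shape, 2, 3))
        np.testing.assert_allclose(out[:-2, :-3], template[2:, 3:])

    def test_shape_mismatch_rejected(self, template):
        with pytest.raises(ValueError):
            warp_frame(template, np.zeros((8, 8, 2)))

    def test_warp_then_negated_warp_roundtrips(self, template):
        cfg = SyntheticConfig(rng_seed=9, deformation_amplitude=1.0, n_frames=4)
        from vnc2p.synthetic import make_deformation_sequence

        f = make_deformation_sequence(cfg)[-1]
        back = warp_frame(warp_frame(template, f), -f)
        err = np.abs(back - template)[3:-3, 3:-3]
        assert err.mean() < 0.02 * np.ptp(template)


class TestEstimateMotion:
    def test_zero_motion_fixed_point(self, template):
        for lam in (1.0, 100.0, 2000.0):
            res = estimate_motion(template, template, MatchSet.empty(),
                                  RegistrationParams(lam=lam))
            assert np.abs(res.field).max() < 0.1

    def test_pure_translation_recovery(self, template):
        field = translation_field(template.shape, 3, -2)
        frame = warp_image(template, invert_field(field))
        matches = compute_matches(template, frame)
        res = estimate_motion(template, frame, matches,
                              RegistrationParams(lam=2000.0, gamma=1.0))
        epe = np.sqrt(((res.field - field) ** 2).sum(-1)).mean()
        assert epe < 0.5

    def test_energy_monotone_within_tolerance(self, deformed_recording):
        _, _, _, movie = deformed_recording
        matches = compute_matches(movie.structural[0], movie.structural[5])
        res = estimate_motion(movie.structural[0], movie.structural[5], matches)
        e = np.asarray(res.energies)
        assert len(e) >= 2
        assert (np.diff(e) <= 1e-6 * np.abs(e[:-1])).all()

    def test_deformation_recovery_and_quality(self, deformed_recording):
        cfg, _, truth, movie = deformed_recording
        ref = movie.structural[0]
        errs = []
        for t in (3, 6, 9):
            matches = compute_matches(ref, movie.structural[t])
            res = estimate_motion(ref, movie.structural[t], matches)
            errs.append(np.sqrt(((res.field - truth.true_fields[t]) ** 2).sum(-1)).mean())
        assert np.mean(errs) < 0.5
        outcome = register_movie(movie, frame_indices=np.arange(0, 12, 3))
        assert outcome.quality > registration_quality(movie.structural[::3])

    def test_nan_rejected(self, template):
        bad = template.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            estimate_motion(template, bad)


def scatter_render(ref, field):
    """Exact integer-displacement rendering: I_t[x + w(x)] = I_r[x]."""
    out = ref.copy()
    h, w = ref.shape
    for r in range(h):
        for c in range(w):
            rr, cc = r + int(field[r, c, 0]), c + int(field[r, c, 1])
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = ref[r, c]
    return out


def block_field(blocks):
    f = np.zeros((8, 8, 2))
    for b, (r0, c0) in enumerate([(0, 0), (0, 4), (4, 0), (4, 4)]):
        f[r0:r0 + 4, c0:c0 + 4] = blocks[b]
    return f


@pytest.mark.parametrize("blocks", [
    [(0, -1)] * 4,
    [(1, 1)] * 4,
    [(1, 0), (1, 0), (0, 0), (0, 0)],
])
def test_solver_energy_beats_exhaustive_enumeration(blocks):
    """On 8x8 instances with integer ground truth, the solver's energy must
    not exceed the minimum over all +-1 px integer fields constant on a 2x2
    grid of blocks (9^4 candidates, exhaustive)."""
    rng = np.random.default_rng(42)
    ref = ndimage.gaussian_filter(rng.uniform(100, 4000, (12, 12)), 0.8)[2:10, 2:10]
    frame = scatter_render(ref, block_field(blocks))
    params = RegistrationParams(lam=10.0, gamma=0.0, pyramid_levels=1)
    opts = list(itertools.product([-1, 0, 1], repeat=2))
    brute = min(
        registration_energy(block_field(combo), ref, frame, None, params)
        for combo in itertools.product(opts, repeat=4)
    )
    res = estimate_motion(ref, frame, None, params)
    assert res.final_energy <= brute + 1e-6


class TestDetectArtifacts:
    def test_zero_field_clean(self):
        rep = detect_artifacts(np.zeros((32, 32, 2)))
        assert not rep.flagged and not rep.clusters

    def test_radial_sink_flagged(self):
        # w(x) = -0.8 (x - c) has analytic divergence -1.6
        field = np.zeros((32, 32, 2))
        rr, cc = np.mgrid[0:32, 0:32]
        patch = (np.abs(rr - 16) <= 3) & (np.abs(cc - 16) <= 3)  # 7x7
        field[..., 0] = np.where(patch, -0.8 * (rr - 16), 0.0)
        field[..., 1] = np.where(patch, -0.8 * (cc - 16), 0.0)
        rep = detect_artifacts(field)
        assert rep.flagged
        assert max(len(c) for c in rep.clusters) > 20
        assert rep.divergence[16, 16] == pytest.approx(-1.6)

    def test_uniform_translation_clean(self):
        rep = detect_artifacts(translation_field((32, 32), 5, -7))
        np.testing.assert_allclose(rep.divergence, 0.0, atol=1e-12)
        assert not rep.flagged

    def test_matches_brute_force_on_random_fields(self):
        # independent recomputation: own divergence + BFS components
        rng = np.random.default_rng(0)
        for _ in range(20):
            field = ndimage.gaussian_filter(
                rng.normal(0, 4.0, (24, 24, 2)), (2, 2, 0)
            )
            rep = detect_artifacts(field)
            div = np.gradient(field[..., 0], axis=0) + np.gradient(field[..., 1], axis=1)
            mask = div < -1.2
            seen = np.zeros_like(mask)
            sizes = []
            for r in range(24):
                for c in range(24):
                    if mask[r, c] and not seen[r, c]:
                        stack, size = [(r, c)], 0
                        seen[r, c] = True
                        while stack:
                            y, x = stack.pop()
                            size += 1
                            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                                ny, nx = y + dy, x + dx
                                if 0 <= ny < 24 and 0 <= nx < 24 and mask[ny, nx] \
                                        and not seen[ny, nx]:
                                    seen[ny, nx] = True
                                    stack.append((ny, nx))
                        sizes.append(size)
            assert sorted(len(c) for c in rep.clusters) == sorted(sizes)
            assert rep.flagged == any(s > 20 for s in sizes)

    def test_nonfinite_rejected(self):
        bad = np.zeros((8, 8, 2))
        bad[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            detect_artifacts(bad)


class TestQuality:
    def test_identical_frames_equal_single_frame_gradient(self, template):
        stack = np.repeat(template[None], 4, axis=0)
        gr, gc = np.gradient(template)
        assert registration_quality(stack) == pytest.approx(np.hypot(gr, gc).mean())

    def test_blank_movie_zero(self):
        assert registration_quality(np.full((3, 16, 16), 5.0)) == 0.0

    def test_single_frame_rejected(self, template):
        with pytest.raises(ValueError):
            registration_quality(template[None])


class TestGridSearch:
    def test_single_clean_point_returned(self, deformed_recording):
        _, _, _, movie = deformed_recording
        params = grid_search(movie, [150.0], [1.0], frame_step=6)
        assert params.lam == 150.0 and params.gamma == 1.0

    def test_artifact_producing_lambda_excluded(self):
        # a bright blob vanishing between frames collapses low-lambda fields
        # into a sink; high lambda stays rigid
        cfg = SyntheticConfig(rng_seed=11, deformation_amplitude=0.0,
                              noise_sd=0.0, n_blobs=12)
        tpl = make_structural_template(cfg)
        rr, cc = np.mgrid[0:64, 0:64]
        blob = 4000 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 3.0**2))
        from vnc2p.io import TwoChannelMovie

        stack = np.stack([tpl + blob, tpl, tpl + blob, tpl])
        movie = TwoChannelMovie(activity=stack, structural=stack, frame_rate=8.0)
        params = grid_search(movie, [100.0, 2000.0], [1.0], frame_step=1)
        assert params.lam == 2000.0

    def test_quality_tie_breaks_to_larger_lambda(self, template):
        from vnc2p.io import TwoChannelMovie

        stack = np.repeat(template[None], 4, axis=0)
        movie = TwoChannelMovie(activity=stack, structural=stack, frame_rate=8.0)
        params = grid_search(movie, [500.0, 1500.0], [1.0], frame_step=2)
        assert params.lam == 1500.0

    def test_empty_grid_rejected(self, deformed_recording):
        _, _, _, movie = deformed_recording
        with pytest.raises(ValueError):
            grid_search(movie, [], [1.0])
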