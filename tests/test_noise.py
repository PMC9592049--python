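import numpy as np
import pytest
from scipy import stats

from srdenoise import (
    AcquisitionParams,
    acquire_frame,
    acquire_stack,
    make_answer,
    make_nuclei_phantom,
)
from srdenoise.phantom import CleanImage, PhantomParams

from conftest import small_params
from oracles import scalar_acquire_draws


def constant_clean(value: float, size: int = 32) -> CleanImage:
    pix = np.full((size, size), value)
    return CleanImage(pixels=pix, modality="3PF", cell_masks=np.ones_like(pix, dtype=bool))


def test_noiseless_identity():
    clean = constant_clean(7.5)
    params = AcquisitionParams(threshold_T=0.0, gaussian_sigma=0.0, poisson_gain=0.0, n_frames=1)
    frame = acquire_frame(clean, params, np.random.default_rng(0))
    assert np.allclose(frame, 7.5)


def test_zero_signal_stays_zero_under_deep_threshold():
    # T >= 6 sigma: per-pixel breach probability < 1e-9
    clean = constant_clean(0.0, size=64)
    params = AcquisitionParams(threshold_T=60.0, gaussian_sigma=10.0, poisson_gain=0.0, n_frames=1)
    frame = acquire_frame(clean, params, np.random.default_rng(3))
    assert np.all(frame == 0.0)


def test_mean_matches_scalar_monte_carlo_oracle():
    """E[y] for S=10, T=5, sigma=2 agrees with the brute-force scalar model."""
    S, T, sigma = 10.0, 5.0, 2.0
    oracle = scalar_acquire_draws(S, T, sigma, gain=0.0, n=10**6, rng=np.random.default_rng(42))
    clean = constant_clean(S, size=500)
    params = AcquisitionParams(threshold_T=T, gaussian_sigma=sigma, poisson_gain=0.0, n_frames=1)
    frame = acquire_frame(clean, params, np.random.default_rng(43))
    se = np.sqrt(oracle.var() / oracle.size + frame.var() / frame.size)
    assert abs(frame.mean() - oracle.mean()) < 3 * se


@pytest.mark.parametrize(
    "S,T,sigma,gain",
    [(10.0, 5.0, 2.0, 0.0), (5.0, 20.0, 15.0, 0.0), (50.0, 30.0, 10.0, 0.5)],
)
def test_marginal_distribution_matches_oracle(S, T, sigma, gain):
    """Per-pixel marginal of acquire_frame == scalar oracle (KS, alpha=0.001)."""
    n = 10**5
    oracle = scalar_acquire_draws(S, T, sigma, gain, n=n, rng=np.random.default_rng(7))
    side = int(np.sqrt(n))
    clean = constant_clean(S, size=side)
    params = AcquisitionParams(threshold_T=T, gaussian_sigma=sigma, poisson_gain=gain, n_frames=1)
    frame = acquire_frame(clean, params, np.random.default_rng(8))
    _, p = stats.ks_2samp(oracle, frame.ravel())
    assert p > 0.001


def test_stack_determinism_and_single_frame_equivalence(nuclei_clean):
    params = AcquisitionParams(n_frames=4, seed=99)
    s1 = acquire_stack(nuclei_clean, params)
    s2 = acquire_stack(nuclei_clean, params)
    assert np.array_equal(s1.frames, s2.frames)
    # one-frame stack equals a single acquire_frame draw at the derived substream
    p1 = AcquisitionParams(n_frames=1, seed=99)
    single = acquire_stack(nuclei_clean, p1)
    child = np.random.SeedSequence(99).spawn(1)[0]
    direct = acquire_frame(nuclei_clean, p1, np.random.default_rng(child))
    assert np.array_equal(single.frames[0], direct)


def test_frames_nonnegative(nuclei_batch):
    stack, _ = nuclei_batch
    assert stack.frames.min() >= 0.0


def test_threshold_monotonicity(nuclei_clean):
    """Raising T (same random stream) never increases any pixel."""
    frames = []
    for T in (20.0, 40.0, 80.0):
        params = AcquisitionParams(threshold_T=T, gaussian_sigma=30.0, poisson_gain=0.25, n_frames=1)
        frames.append(acquire_frame(nuclei_clean, params, np.random.default_rng(5)))
    assert np.all(frames[1] <= frames[0])
    assert np.all(frames[2] <= frames[1])


def test_answer_is_frame_mean(nuclei_batch):
    stack, answer = nuclei_batch
    assert np.allclose(answer.pixels, stack.frames.mean(axis=0))
    assert answer.n_averaged == stack.frames.shape[0]


def test_answer_of_identical_frames_and_two_frame_average():
    f = np.arange(16.0).reshape(4, 4)
    params = AcquisitionParams(n_frames=2, seed=0)
    from srdenoise.noise import FrameStack

    stack = FrameStack(frames=np.stack([np.zeros((4, 4)), 2 * f]), params=params)
    assert np.allclose(make_answer(stack).pixels, f)


def test_noiseless_answer_is_thresholded_signal(nuclei_clean):
    # 4 frames: the mean of identical frames is exact in binary arithmetic
    params = AcquisitionParams(threshold_T=30.0, gaussian_sigma=0.0, poisson_gain=0.0, n_frames=4, seed=1)
    answer = make_answer(acquire_stack(nuclei_clean, params))
    assert np.array_equal(answer.pixels, np.maximum(nuclei_clean.pixels - 30.0, 0.0))


def test_answer_variance_scales_inversely_with_frame_count():
    """Across repeated stacks, per-pixel answer variance falls as 1/N."""
    clean = constant_clean(50.0, size=24)
    variances = {}
    for n_frames in (4, 16):
        answers = []
        for rep in range(50):
            params = AcquisitionParams(
                threshold_T=30.0, gaussian_sigma=25.0, poisson_gain=0.0, n_frames=n_frames, seed=1000 + rep
            )
            answers.append(make_answer(acquire_stack(clean, params)).pixels)
        variances[n_frames] = np.var(np.stack(answers), axis=0).mean()
    ratio = variances[4] / variances[16]
    assert abs(ratio - 4.0) / 4.0 < 0.20


def test_stochastic_resonance_boosts_subthreshold_signal():
    """With S < T, noise makes the answer strictly positive on average."""
    clean = constant_clean(20.0, size=32)
    noisy_params = AcquisitionParams(threshold_T=50.0, gaussian_sigma=25.0, poisson_gain=0.0, n_frames=50, seed=6)
    answer = make_answer(acquire_stack(clean, noisy_params))
    # one-sample t-test of pixel means against zero
    t, p = stats.ttest_1samp(answer.pixels.ravel(), 0.0, alternative="greater")
    assert p < 0.01
    assert answer.pixels.mean() > 0
    quiet_params = AcquisitionParams(threshold_T=50.0, gaussian_sigma=0.0, poisson_gain=0.0, n_frames=50, seed=6)
    quiet = make_answer(acquire_stack(clean, quiet_params))
    assert np.all(quiet.pixels == 0.0)
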