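import numpy as np
import pytest

from connreg import RegularizerSpec, broken_line, feature_map_from_sample, gaussian_kernel


@pytest.fixture(scope="session")
def line_sample():
    """The canonical 64x64 horizontal broken line (gap 2, contrast 0.3, noise 0.05)."""
    return broken_line(seed=0)


@pytest.fixture(scope="session")
def line_features(line_sample):
    return feature_map_from_sample(line_sample, margin=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gauss3():
    return gaussian_kernel(3, 1.0)


@pytest.fixture
def std_spec():
    """Gaussian-only regularization at the weights used throughout the examples."""
    return RegularizerSpec(lambda_std=0.1, epsilon=1.0)


def brute_force_inner_product(u, kernel, against):
    """O(N^2 |k|) oracle for <u, k * g(u)> with explicit reflect indexing.

    ``against`` maps the field to the convolved argument (e.g. ``1 - u`` for
    the STD term, ``-u`` for the connectivity term).
    """
    u = np.asarray(u, dtype=float)
    g = against(u)
    kh, kw = kernel.weights.shape
    rh, rw = kh // 2, kw // 2
    h, w = u.shape

    def reflect(i, n):
        # scipy's 'reflect' mode: (d c b a | a b c d)
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i

    total = 0.0
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    ii = reflect(i + a - rh, h)
                    jj = reflect(j + b - rw, w)
                    acc += kernel.weights[a, b] * g[ii, jj]
            total += u[i, j] * acc
    return total
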