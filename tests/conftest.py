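"""Shared fixtures and independent oracle helpers for the test suite."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def data_with_exact_corr(R, n, rng):
    """Data whose *sample* correlation (ddof=1) equals R exactly.

    Columns of an orthonormalized zero-mean Gaussian basis are mixed with
    the Cholesky factor of R; used wherever a test needs a correlation
    matrix realized by actual data (regression-residual oracles).
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    chol = np.linalg.cholesky(R)
    return np.sqrt(n - 1) * q @ chol.T


def partial_corr_residual_oracle(x, y, controls):
    """Partial correlation via explicit regression residuals."""
    C = np.column_stack([np.ones(len(x)), controls]) if controls is not None \
        else np.ones((len(x), 1))
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def auc_pair_oracle(score, label):
    """AUC by brute-force pair counting, ties counted one half."""
    score = np.asarray(score, float)
    label = np.asarray(label, bool)
    pos = score[label]
    neg = score[~label]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
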