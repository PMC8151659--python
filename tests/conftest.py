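"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import vrgait as vg


@pytest.fixture(scope="session")
def default_config():
    return vg.RunConfig()


@pytest.fixture(scope="session")
def noiseless_trial():
    """20-stride synthetic trial with no noise and no clock offset."""
    spec = vg.SyntheticGaitSpec(n_strides=20, noise_sd_pos=0.0, clock_offset_s=0.0, seed=1)
    return spec, vg.simulate_trial(spec)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_trial, default_config):
    spec, trial = noiseless_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = vg.process_trial(
            trial.left, trial.right, default_config, spec.heel_offset, spec.heel_offset
        )
    return res


@pytest.fixture(scope="session")
def noisy_trial():
    """200-stride trial with 3 mm positional noise (fixed seed)."""
    spec = vg.SyntheticGaitSpec(n_strides=200, noise_sd_pos=0.003, seed=42)
    return spec, vg.simulate_trial(spec)


def optimal_match(detected_t, reference_t, tol_s):
    """Exhaustive optimal one-to-one matching oracle.

    Maximizes the number of matched pairs within tolerance, breaking ties by
    minimum total |dt|.  Exponential search, only for small instances.
    Returns (n_matched, total_abs_dt).
    """
    detected_t = list(detected_t)
    reference_t = list(reference_t)
    n_ref = len(reference_t)
    best = [0, float("inf")]

    def rec(i, used, count, total):
        remaining = len(detected_t) - i
        if count + remaining < best[0]:
            return
        if i == len(detected_t):
            if count > best[0] or (count == best[0] and total < best[1]):
                best[0], best[1] = count, total
            return
        for j in range(n_ref):
            if used[j]:
                continue
            d = abs(detected_t[i] - reference_t[j])
            if d <= tol_s:
                used[j] = True
                rec(i + 1, used, count + 1, total + d)
                used[j] = False
        rec(i + 1, used, count, total)  # leave detected_t[i] unmatched

    rec(0, [False] * n_ref, 0, 0.0)
    return best[0], best[1] if best[0] else 0.0


def random_event_streams(rng, tol_s=3.0 / 90.0, max_events=8):
    """A realistic detected/reference stream pair: jittered shared events with
    independent drops and occasional spurious detections, spacing >> tolerance."""
    n = int(rng.integers(2, max_events + 1))
    base = np.cumsum(rng.uniform(0.45, 0.75, size=n))
    keep_det = rng.random(n) > 0.15
    keep_ref = rng.random(n) > 0.15
    det = base[keep_det] + rng.normal(0.0, tol_s / 3.0, size=int(keep_det.sum()))
    ref = base[keep_ref]
    if rng.random() < 0.3:  # a spurious detection far from everything
        det = np.append(det, base[-1] + rng.uniform(5.0, 6.0))
    return np.sort(det)[:max_events], np.sort(ref)[:max_events]
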