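"""Shared builders for inflow-curve test ensembles."""

import numpy as np

from cereflow import SignalCurve
from cereflow.synthetic import gamma_variate

FRAMES = np.arange(1, 13, dtype=float)
MASTER_TTP = 5.0  # onset 2 + shape 3 * scale 1


def master_curve(amplitude=100.0, onset=2.0, shape=3.0, scale=1.0,
                 frames=FRAMES):
    return gamma_variate(frames, amplitude, onset, shape, scale)


def warped_master(time_scale, time_shift, noise_sd=0.0, rng=None,
                  amplitude=100.0):
    """The master curve with the warp (scale, shift) applied to its time
    axis: c(t) = master(scale * t + shift); peak at (5 - shift) / scale."""
    vals = gamma_variate(time_scale * FRAMES + time_shift, amplitude,
                         2.0, 3.0, 1.0)
    if noise_sd:
        vals = vals + rng.normal(0.0, noise_sd, FRAMES.size)
    return SignalCurve(np.clip(vals, 0.0, None))


def transform_ensemble(n, seed, noise_sd=2.0, shift_range=(-1.5, 1.5),
                       scale_range=(0.8, 1.25), log_uniform_scales=False):
    """Random warps of the master curve.

    ``log_uniform_scales`` draws scales log-uniformly over the same range so
    their geometric mean is exactly 1 and the population mean transform is
    the identity (uniform-in-scale draws have GM 1.0167 over [0.8, 1.25],
    displacing the ensemble's own mean frame from the master's).
    """
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n):
        b = rng.uniform(*shift_range)
        if log_uniform_scales:
            a = np.exp(rng.uniform(np.log(scale_range[0]),
                                   np.log(scale_range[1])))
        else:
            a = rng.uniform(*scale_range)
        curves.append(warped_master(a, b, noise_sd=noise_sd, rng=rng))
    return curves


def shift_only_ensemble(n, seed, noise_sd=0.0, shift_range=(-1.5, 1.5)):
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(*shift_range, size=n)
    curves = [warped_master(1.0, b, noise_sd=noise_sd, rng=rng)
              for b in shifts]
    return curves, shifts
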