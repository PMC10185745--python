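"""Independent grating-response oracle for Gabor kernel tuning checks."""

import numpy as np


def grating_patch(ksize, theta, wavelength, phase=0.0):
    r = (ksize - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(ksize) - r, np.arange(ksize) - r)
    u = cols * np.cos(theta) + rows * np.sin(theta)
    return np.cos(2 * np.pi * u / wavelength + phase)


def grating_energy(kern, theta, wavelength):
    """Phase-independent response energy of a kernel to a grating."""
    k = kern.shape[0]
    rc = (kern * grating_patch(k, theta, wavelength, 0.0)).sum()
    rs = (kern * grating_patch(k, theta, wavelength, np.pi / 2)).sum()
    return np.hypot(rc, rs)


def best_grating(kern, wavelengths=None):
    """Exhaustive (orientation, wavelength) scan; returns the argmax."""
    k = kern.shape[0]
    if wavelengths is None:
        wavelengths = np.arange(2.0, k + 0.5, 0.5)
    thetas = np.arange(0, np.pi, np.pi / 36)
    best, arg = -np.inf, None
    for th in thetas:
        for lam in wavelengths:
            e = grating_energy(kern, th, lam)
            if e > best:
                best, arg = e, (th, lam)
    return arg


def angdiff(a, b):
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)
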