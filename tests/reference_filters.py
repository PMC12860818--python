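"""Literal loop-based reference filters (bilateral), independent of the
vectorized/jitted implementations."""

import math

import numpy as np


def ref_bilateral3d(img, sigma_domain, sigma_range, truncate=2.0):
    """Brute-force 3D bilateral filter with replicate padding via index clipping."""
    img = np.asarray(img, dtype=np.float64)
    radius = int(math.ceil(truncate * sigma_domain))
    nx, ny, nz = img.shape
    out = np.empty_like(img)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = img[i, j, k]
                num = den = 0.0
                for a in range(-radius, radius + 1):
                    ii = min(max(i + a, 0), nx - 1)
                    for b in range(-radius, radius + 1):
                        jj = min(max(j + b, 0), ny - 1)
                        for d in range(-radius, radius + 1):
                            kk = min(max(k + d, 0), nz - 1)
                            v = img[ii, jj, kk]
                            w = math.exp(
                                -(a * a + b * b + d * d)
                                / (2.0 * sigma_domain**2)
                            ) * math.exp(
                                -((v - c) ** 2) / (2.0 * sigma_range**2)
                            )
                            num += w * v
                            den += w
                out[i, j, k] = num / den
    return out
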