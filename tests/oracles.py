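"""Independent brute-force reference implementations used by the tests.

These deliberately use explicit Python loops (or all-pairs computations)
and never call into the package's own numerical kernels.
"""

import numpy as np


def loop_depthwise_conv2d(x, kernel, stride=1, padding=0):
    """Direct per-channel convolution: Y[i,j,c] = sum_mn X[i*s+m, j*s+n, c] K[m,n,c]."""
    n, c, h, w = x.shape
    k = kernel.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    out = np.zeros((n, c, ho, wo))
    for b in range(n):
        for ch in range(c):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for m in range(k):
                        for nn in range(k):
                            acc += xp[b, ch, i * stride + m, j * stride + nn] \
                                * kernel[ch, m, nn]
                    out[b, ch, i, j] = acc
    return out


def loop_pointwise_conv2d(x, weights):
    """Y[i,j,co] = sum_k X[i,j,k] * W[k,co]."""
    n, cin, h, w = x.shape
    cout = weights.shape[1]
    out = np.zeros((n, cout, h, w))
    for b in range(n):
        for co in range(cout):
            for i in range(h):
                for j in range(w):
                    out[b, co, i, j] = sum(
                        x[b, k, i, j] * weights[k, co] for k in range(cin))
    return out


def loop_se_gate(x, fc1_w, fc2_w):
    """Squeeze (channel means), excitation (fc-relu-fc-sigmoid), rescale."""
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(n):
        z = np.array([x[b, ch].sum() / (h * w) for ch in range(c)])
        s = np.maximum(z @ fc1_w, 0.0)
        f = 1.0 / (1.0 + np.exp(-(s @ fc2_w)))
        for ch in range(c):
            out[b, ch] = f[ch] * x[b, ch]
    return out


def surface_points(mask, spacing):
    """Boundary voxels (6-connectivity, explicit neighbour checks) in mm."""
    mask = np.asarray(mask, bool)
    pts = []
    d, h, w = mask.shape
    for i in range(d):
        for j in range(h):
            for k in range(w):
                if not mask[i, j, k]:
                    continue
                border = False
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < d and 0 <= jj < h and 0 <= kk < w) \
                            or not mask[ii, jj, kk]:
                        border = True
                        break
                if border:
                    pts.append((i * spacing[0], j * spacing[1], k * spacing[2]))
    return np.array(pts)


def brute_force_hd95(a, b, spacing=(1.0, 1.0, 1.0)):
    """All-pairs pooled symmetric 95th-percentile surface distance."""
    pa = surface_points(a, spacing)
    pb = surface_points(b, spacing)
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return float(np.percentile(pooled, 95))
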