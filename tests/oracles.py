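"""Independent straight-line oracles used by the unit and acceptance suites.

These deliberately avoid the package's tensor/ops machinery: plain NumPy
loops and einsums, so they can serve as an independent cross-check of the
attention-gate arithmetic.
"""

import numpy as np


def gate_oracle(x: np.ndarray, g: np.ndarray, gate) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the additive attention gate by hand.

    Block-mean downsample of the skip feature, 1x1 projections with the
    shared additive bias, ReLU, psi projection with its own bias, sigmoid,
    half-pixel-centre bilinear upsample, elementwise product with the skip.
    """
    n, cx, hx, wx = x.shape
    hg, wg = g.shape[2:]
    fh, fw = hx // hg, wx // wg
    xd = x.reshape(n, cx, hg, fh, wg, fw).mean(axis=(3, 5))
    wx_ = gate.theta_x.weight.data[:, :, 0, 0]
    wg_ = gate.phi_g.weight.data[:, :, 0, 0]
    b = gate.phi_g.bias.data
    psi = gate.psi.weight.data[:, :, 0, 0]
    b_psi = gate.psi.bias.data
    add = (
        np.einsum("fc,nchw->nfhw", wx_, xd)
        + np.einsum("fc,nchw->nfhw", wg_, g)
        + b[None, :, None, None]
    )
    q = np.einsum("of,nfhw->nohw", psi, np.maximum(add, 0.0)) + b_psi[None, :, None, None]
    alpha_small = 1.0 / (1.0 + np.exp(-q))
    alpha = np.empty((n, 1, hx, wx))
    for i in range(hx):
        si = np.clip((i + 0.5) * hg / hx - 0.5, 0, hg - 1)
        i0 = int(np.floor(si))
        fi = si - i0
        i1 = min(i0 + 1, hg - 1)
        for j in range(wx):
            sj = np.clip((j + 0.5) * wg / wx - 0.5, 0, wg - 1)
            j0 = int(np.floor(sj))
            fj = sj - j0
            j1 = min(j0 + 1, wg - 1)
            alpha[:, :, i, j] = (
                alpha_small[:, :, i0, j0] * (1 - fi) * (1 - fj)
                + alpha_small[:, :, i1, j0] * fi * (1 - fj)
                + alpha_small[:, :, i0, j1] * (1 - fi) * fj
                + alpha_small[:, :, i1, j1] * fi * fj
            )
    return x * alpha, alpha
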