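"""Independent brute-force reference implementations used by the tests.

Everything here is written as literal scalar loops (or direct formula
transcriptions) so that agreement with the package's vectorized code is a
meaningful check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def conv2d_same_loop(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Single-channel same-padded cross-correlation by explicit loops."""
    h, w = x.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    rr, cc = r + a - ph, c + b - pw
                    if 0 <= rr < h and 0 <= cc < w:
                        acc += kernel[a, b] * x[rr, cc]
            out[r, c] = acc
    return out


def depthwise_separable_loop(x: np.ndarray, dw: np.ndarray,
                             pw: np.ndarray,
                             bias: np.ndarray | None = None) -> np.ndarray:
    """Per-channel conv, then per-pixel matrix multiply across channels."""
    cin, h, w = x.shape
    cout = pw.shape[0]
    mid = np.zeros((cin, h, w))
    for ch in range(cin):
        mid[ch] = conv2d_same_loop(x[ch], dw[ch])
    out = np.zeros((cout, h, w))
    for r in range(h):
        for c in range(w):
            for o in range(cout):
                acc = 0.0
                for ch in range(cin):
                    acc += pw[o, ch] * mid[ch, r, c]
                if bias is not None:
                    acc += bias[o]
                out[o, r, c] = acc
    return out


def attention_gate_loop(u: np.ndarray, g: np.ndarray, w_u: np.ndarray,
                        w_g: np.ndarray, b_g: np.ndarray, psi: np.ndarray,
                        b_psi: float) -> np.ndarray:
    """Literal per-pixel evaluation of the additive attention coefficient."""
    cu, h, w = u.shape
    ci = w_u.shape[0]
    out = np.zeros_like(u)
    for r in range(h):
        for c in range(w):
            q = b_psi
            for i in range(ci):
                z = b_g[i]
                for k in range(cu):
                    z += w_u[i, k] * u[k, r, c]
                for k in range(g.shape[0]):
                    z += w_g[i, k] * g[k, r, c]
                q += psi[i] * max(z, 0.0)
            alpha = 1.0 / (1.0 + math.exp(-q))
            for k in range(cu):
                out[k, r, c] = alpha * u[k, r, c]
    return out


def rr_block_unrolled(x: np.ndarray, params: dict, t: int) -> np.ndarray:
    """Hand-unrolled recurrence using the depthwise-separable loop oracle."""

    def g(v):
        return np.maximum(depthwise_separable_loop(
            v, params["depthwise"], params["pointwise"], params.get("bias")), 0.0)

    z = g(x)
    for _ in range(t):
        z = g(x + z)
    proj = params.get("proj")
    if proj is None:
        res = x
    else:
        cout, cin = proj.shape
        _, h, w = x.shape
        res = np.zeros((cout, h, w))
        for r in range(h):
            for c in range(w):
                for o in range(cout):
                    res[o, r, c] = sum(proj[o, k] * x[k, r, c]
                                       for k in range(cin))
    return res + z


def dense_peephole_lstm_step(x, h, c, w, peephole_on_previous=False):
    """Scalar peephole LSTM step: the 1x1-spatial reduction of the ConvLSTM
    cell. All arguments are 1-D vectors except `w`, a dict of 2-D/1-D
    arrays keyed like the ConvLSTM weight names."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    f = sig(w["W_xf"] @ x + w["W_hf"] @ h + w["W_cf"] * c + w["b_f"])
    i = sig(w["W_xi"] @ x + w["W_hi"] @ h + w["W_ci"] * c + w["b_i"])
    g = np.tanh(w["W_xg"] @ x + w["W_hg"] @ h + w["b_g"])
    c_new = f * c + i * g
    peep = c if peephole_on_previous else c_new
    o = sig(w["W_xo"] @ x + w["W_ho"] @ h + w["W_co"] * peep + w["b_o"])
    return o * np.tanh(c_new), c_new


def convlstm_step_loop(x_t, H, C, w, peephole_on_previous=False):
    """Scalar-loop ConvLSTM step on (C,H,W) tensors with same padding."""
    ch, hh, ww = H.shape
    cx = x_t.shape[0]
    k = w.W_xf.shape[-1]
    p = k // 2

    def conv_at(kernels, src, o, r, c):
        acc = 0.0
        for ci in range(src.shape[0]):
            for a in range(k):
                for b in range(k):
                    rr, cc = r + a - p, c + b - p
                    if 0 <= rr < hh and 0 <= cc < ww:
                        acc += kernels[o, ci, a, b] * src[ci, rr, cc]
        return acc

    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    peep = lambda arr, o, r, c: arr[o, r % arr.shape[1], c % arr.shape[2]] \
        if arr.shape[1] > 1 else arr[o, 0, 0]
    Hn = np.zeros_like(H)
    Cn = np.zeros_like(C)
    for o in range(ch):
        for r in range(hh):
            for c in range(ww):
                f = sig(conv_at(w.W_xf, x_t, o, r, c) + conv_at(w.W_hf, H, o, r, c)
                        + peep(w.W_cf, o, r, c) * C[o, r, c] + w.b_f[o])
                i = sig(conv_at(w.W_xi, x_t, o, r, c) + conv_at(w.W_hi, H, o, r, c)
                        + peep(w.W_ci, o, r, c) * C[o, r, c] + w.b_i[o])
                g = math.tanh(conv_at(w.W_xg, x_t, o, r, c)
                              + conv_at(w.W_hg, H, o, r, c) + w.b_g[o])
                c_new = f * C[o, r, c] + i * g
                pv = C[o, r, c] if peephole_on_previous else c_new
                ogate = sig(conv_at(w.W_xo, x_t, o, r, c)
                            + conv_at(w.W_ho, H, o, r, c)
                            + peep(w.W_co, o, r, c) * pv + w.b_o[o])
                Cn[o, r, c] = c_new
                Hn[o, r, c] = ogate * math.tanh(c_new)
    return Hn, Cn


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """4-connected components by explicit BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                queue = [(r0, c0)]
                seen[r0, c0] = True
                while queue:
                    r, c = queue.pop()
                    comp.add((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                components.append(comp)
    return components


def ellipse_pixel_count(center, radii, shape) -> int:
    """Per-pixel membership count of the discretized ellipse."""
    r0, c0 = center
    rv, rh = radii
    count = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - r0) ** 2 / rv ** 2 + (c - c0) ** 2 / rh ** 2 <= 1.0:
                count += 1
    return count


def vein_width_profile(frame: np.ndarray, spec, label_row: int | None = None) -> float:
    """Measure the vein width by integrating the intensity deficit across a
    row through the disc center (anti-aliased coverage sums to the width)."""
    row = int(spec.disc_center[0]) if label_row is None else label_row
    col = int(spec.disc_center[1])
    contrast = spec.background_intensity - spec.vessel_intensity
    profile = spec.disc_intensity - frame[row]
    window = profile[max(col - 15, 0):col + 16]
    return float(window.sum() / contrast)


def confusion_loop(pred, true) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for p, t in zip(pred, true):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def auc_all_pairs(scores, labels) -> float:
    """P(s_pos > s_neg) + 0.5 * P(s_pos = s_neg) over all pos/neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
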