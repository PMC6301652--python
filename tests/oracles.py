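"""Independent brute-force oracles shared by the unit and acceptance tests.

Deliberately naive implementations: they must stay independent of the
code paths they are used to check.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_edm(mask):
    """Exact distance map by explicit min over all background pixels."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if fg.size and bg.size:
        out[mask] = cdist(fg, bg).min(axis=1)
    return out


def exhaustive_three_class(img):
    """Globally optimal (t_low, t_high) and the attained s^2/w objective,
    by vectorized enumeration of all threshold pairs."""
    hist = np.bincount(np.asarray(img).ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    lv = np.arange(256.0)
    cw = np.cumsum(p)
    cs = np.cumsum(p * lv)

    def sc(w, s):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)

    t1 = np.arange(255)[:, None]
    t2 = np.arange(255)[None, :]
    total = (
        sc(cw[t1], cs[t1])
        + sc(cw[t2] - cw[t1], cs[t2] - cs[t1])
        + sc(cw[255] - cw[t2], cs[255] - cs[t2])
    )
    total[t1 >= t2] = -np.inf
    idx = np.unravel_index(np.argmax(total), total.shape)
    return int(idx[0]), int(idx[1]), float(total[idx])


def trapezoid_auc(scores, positive):
    """ROC AUC by explicit trapezoidal integration over thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    positive = np.asarray(positive, dtype=bool)
    thresholds = np.unique(scores)[::-1]
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        called = scores >= t
        tpr.append((called & positive).sum() / n_pos)
        fpr.append((called & ~positive).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))
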