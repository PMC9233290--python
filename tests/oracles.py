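"""Independent brute-force oracles used to validate the library.

Everything here is written from first principles (flood fill, pixel-set
intersections, direct formulas) and deliberately avoids the code paths it
is used to check.
"""

from __future__ import annotations

from collections import deque

import numpy as np

LESION_LABELS = (2, 3, 4, 5, 6, 7, 8)  # MA, HEM, CWS, HE, PC, IRMA, NV


def flood_fill_components(mask, label, connectivity=8):
    """Connected pixel sets of one label value via BFS flood fill."""
    mask = np.asarray(mask)
    h, w = mask.shape
    if connectivity == 8:
        neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neighbors = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] != label or seen[r, c]:
                continue
            queue = deque([(r, c)])
            seen[r, c] = True
            comp = set()
            while queue:
                cr, cc = queue.popleft()
                comp.add((cr, cc))
                for dr, dc in neighbors:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and not seen[nr, nc] and mask[nr, nc] == label:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            components.append(frozenset(comp))
    return components


def match_oracle(pred, ref, connectivity=8):
    """Exhaustive pairwise pixel-set matching; returns per-class dict of
    (tp, fp, fn, ref_detected)."""
    out = {}
    for label in LESION_LABELS:
        p_comps = flood_fill_components(pred, label, connectivity)
        r_comps = flood_fill_components(ref, label, connectivity)
        tp = sum(1 for p in p_comps if any(p & r for r in r_comps))
        ref_det = sum(1 for r in r_comps if any(p & r for p in p_comps))
        out[label] = (tp, len(p_comps) - tp, len(r_comps) - ref_det, ref_det)
    return out


def adjusted_precision_oracle(pred, ref, connectivity=8):
    """Per-class precision counting any-lesion overlap as correct."""
    ref = np.asarray(ref)
    lesion = np.isin(ref, LESION_LABELS)
    out = {}
    for label in LESION_LABELS:
        comps = flood_fill_components(pred, label, connectivity)
        if not comps:
            out[label] = None
            continue
        tp = sum(1 for p in comps if any(lesion[r, c] for r, c in p))
        out[label] = tp / len(comps)
    return out


def fp_confusion_oracle(pred, ref, connectivity=8):
    """Predicted-component attribution table as a nested dict
    {pred_label: {ref_label_or_'BG': count}}."""
    ref = np.asarray(ref)
    table = {p: {q: 0 for q in list(LESION_LABELS) + ["BG"]} for p in LESION_LABELS}
    for label in LESION_LABELS:
        for comp in flood_fill_components(pred, label, connectivity):
            overlaps = {q: 0 for q in LESION_LABELS}
            for r, c in comp:
                v = int(ref[r, c])
                if v in overlaps:
                    overlaps[v] += 1
            if overlaps[label] > 0:
                table[label][label] += 1
                continue
            best, best_n = "BG", 0
            for q in LESION_LABELS:  # fixed tie-break order
                if overlaps[q] > best_n:
                    best, best_n = q, overlaps[q]
            table[label][best] += 1
    return table


def image_level_oracle(preds, refs):
    """Presence/absence truth table per class: (tp, fp, fn) totals."""
    out = {label: [0, 0, 0] for label in LESION_LABELS}
    for pred, ref in zip(preds, refs):
        p_set = set(np.unique(pred).tolist())
        r_set = set(np.unique(ref).tolist())
        for label in LESION_LABELS:
            if label in p_set and label in r_set:
                out[label][0] += 1
            elif label in p_set:
                out[label][1] += 1
            elif label in r_set:
                out[label][2] += 1
    return {k: tuple(v) for k, v in out.items()}


def qwk_oracle(conf):
    """Textbook quadratic weighted kappa from a confusion matrix."""
    conf = np.asarray(conf, dtype=float)
    k = conf.shape[0]
    total = conf.sum()
    po_num = 0.0
    pe_num = 0.0
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    for i in range(k):
        for j in range(k):
            w = ((i - j) ** 2) / ((k - 1) ** 2)
            po_num += w * conf[i, j] / total
            pe_num += w * row[i] * col[j] / total**2
    return 1.0 - po_num / pe_num


def auc_oracle(scores_pos_class, is_pos):
    """One-vs-rest AUC via the Mann-Whitney U statistic with midranks."""
    s = np.asarray(scores_pos_class, dtype=float)
    y = np.asarray(is_pos, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def icc21_oracle(x):
    """ICC(2,1) from explicit ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((x - grand) ** 2) - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def random_lesion_mask(rng, shape=(40, 40), density=0.5, n_blobs=6):
    """Random small mask mixing blob-like lesions and salt noise."""
    h, w = shape
    mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_blobs):
        label = int(rng.choice(LESION_LABELS))
        r0, c0 = int(rng.integers(h)), int(rng.integers(w))
        rad = int(rng.integers(1, 4))
        rr, cc = np.mgrid[max(r0 - rad, 0) : min(r0 + rad + 1, h), max(c0 - rad, 0) : min(c0 + rad + 1, w)]
        keep = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        mask[rr[keep], cc[keep]] = label
    n_noise = int(density * h * w * 0.05)
    rs = rng.integers(0, h, n_noise)
    cs = rng.integers(0, w, n_noise)
    vs = rng.choice(LESION_LABELS, n_noise)
    mask[rs, cs] = vs
    return mask
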