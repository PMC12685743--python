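"""Shared fixtures and brute-force reference implementations.

The oracles here are deliberately naive (all-pairs distances, BFS
labelling, explicit window enumeration, textbook formulas) so they stay
independent of the vectorised/library code paths they check.
"""

import datetime as dt
import math

import numpy as np
import pytest

import sargassum as sg


# ---------------------------------------------------------------- oracles

def brute_force_valid_mask(land, cloud, px_km, land_buffer_km, cloud_buffer_km):
    """All-pairs Euclidean-distance exclusion mask."""
    n_rows, n_cols = land.shape
    valid = np.ones_like(land, dtype=bool)
    flagged = [(land, land_buffer_km), (cloud, cloud_buffer_km)]
    for r in range(n_rows):
        for c in range(n_cols):
            for flag, buf in flagged:
                if flag[r, c]:
                    valid[r, c] = False
                    continue
                fr, fc = np.nonzero(flag)
                if fr.size and np.min(np.hypot(fr - r, fc - c)) * px_km <= buf:
                    valid[r, c] = False
    return valid


def bfs_label(mask):
    """8-connected component labelling by breadth-first search."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        nxt += 1
        queue = [seed]
        labels[seed] = nxt
        while queue:
            r, c = queue.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not labels[rr, cc]):
                        labels[rr, cc] = nxt
                        queue.append((rr, cc))
    return labels


def oracle_background_median(patch_pixels, afai_values, detected, valid, radius):
    """Enumerate eligible background pixels within the patch dilation."""
    n_rows, n_cols = afai_values.shape
    sample = []
    for r in range(n_rows):
        for c in range(n_cols):
            cheb = min(max(abs(r - pr), abs(c - pc)) for pr, pc in patch_pixels)
            if cheb <= radius and valid[r, c] and not detected[r, c] \
                    and np.isfinite(afai_values[r, c]):
                sample.append(afai_values[r, c])
    return float(np.median(sample)) if sample else None


def oracle_pooled_t(x, y):
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return t, p


def oracle_welch_t(x, y):
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def oracle_f_test(x, y):
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    from scipy.stats import f as fdist
    if vx >= vy:
        f, dfn, dfd = vx / vy, len(x) - 1, len(y) - 1
    else:
        f, dfn, dfd = vy / vx, len(y) - 1, len(x) - 1
    return f, min(1.0, 2 * fdist.sf(f, dfn, dfd))


def oracle_box(values):
    v = np.sort(np.asarray(values, float))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
    inside = v[(v >= lo) & (v <= hi)]
    return q1, med, q3, inside.min(), inside.max(), v[(v < lo) | (v > hi)]


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def flat_scene():
    """64x64 open-ocean scene, flat background, no land/cloud/noise."""
    cfg = sg.SceneConfig(grid_rows=64, grid_cols=64, seed=3)
    scene, truth = sg.generate_scene(cfg)
    return scene, truth


def make_scene(**kwargs):
    cfg = sg.SceneConfig(**kwargs)
    return sg.generate_scene(cfg)


def make_series(values_by_month, region="test"):
    """BiomassSeries from {(year, month): biomass_t}."""
    import pandas as pd

    rows = []
    for (year, month), b in sorted(values_by_month.items()):
        d = dt.date(year, month, 15)
        rows.append({"year": year, "month": month, "biomass_t": b,
                     "ecological_year": sg.ecological_year(d),
                     "season": sg.season(d)})
    return sg.BiomassSeries(region=region, table=pd.DataFrame(rows))
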