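"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: direct
summation, exhaustive enumeration, explicit ANOVA decomposition, and
scipy's Euler composition.
"""

import itertools

import numpy as np
from scipy import stats as sps
from scipy.spatial.transform import Rotation


def brute_inertia(points):
    """Direct per-point summation of sum_i (|r|^2 I - r r^T)."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    t = np.zeros((3, 3))
    for p in pts:
        r = p - c
        t += (r @ r) * np.eye(3) - np.outer(r, r)
    return c, t


def compose_yxz_scipy(phiy, phix, phiz):
    """Intrinsic y-x-z rotation via scipy (upper-case = intrinsic)."""
    return Rotation.from_euler("YXZ", [phiy, phix, phiz], degrees=True).as_matrix()


def mwu_enumeration(a, b):
    """Exact two-sided Mann-Whitney p via enumeration of all C(N, na) splits."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)

    def u_stat(idx):
        s = set(idx)
        u = 0.0
        for i in s:
            for j in range(n):
                if j in s:
                    continue
                u += (pooled[i] > pooled[j]) + 0.5 * (pooled[i] == pooled[j])
        return u

    obs = u_stat(range(na))
    vals = np.array([u_stat(c) for c in itertools.combinations(range(n), na)])
    p = 2 * min((vals <= obs).mean(), (vals >= obs).mean())
    return obs, min(1.0, p)


def ansari_scores(pooled):
    ranks = sps.rankdata(pooled)
    return np.minimum(ranks, len(pooled) + 1 - ranks)


def ansari_enumeration(a, b):
    """Exact two-sided Ansari-Bradley p via enumeration."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)
    scores = ansari_scores(pooled)
    obs = scores[:na].sum()
    vals = np.array(
        [scores[list(c)].sum() for c in itertools.combinations(range(n), na)]
    )
    p = 2 * min((vals <= obs).mean(), (vals >= obs).mean())
    return obs, min(1.0, p)


def icc_bruteforce(table):
    """ICC(A,1) from an explicit two-way ANOVA decomposition (loops)."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (x[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (x[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (x[i, j] - grand) ** 2
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def icc_consistency(table):
    """ICC(C,1): consistency version, for the bias-penalty comparison."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def open_cylinder(radius=10.0, height=100.0, n_circ=64, n_rows=101):
    """Uncapped cylinder along +z as (vertices, faces) arrays."""
    ang = np.arange(n_circ) * 2 * np.pi / n_circ
    verts = []
    for i in range(n_rows):
        z = height * i / (n_rows - 1)
        verts.append(
            np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(n_circ, z)]
            )
        )
    verts = np.vstack(verts)
    faces = []
    for i in range(n_rows - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            faces.append((a, b, d))
            faces.append((a, d, c))
    return verts, np.asarray(faces, dtype=np.int64)


def random_rotation_matrix(rng):
    return Rotation.random(rng=rng).as_matrix()
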