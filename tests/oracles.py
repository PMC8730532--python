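"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (enumeration, flood fill,
direct convolution, dense linear algebra, grid search) and deliberately
avoids the code paths it checks.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np


def hwe_exact_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p-value by enumerating every heterozygote configuration.

    Uses exact rational arithmetic for the conditional probabilities
    P(het = h | allele counts), then sums P(config) <= P(observed).
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    probs: dict[int, Fraction] = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        # multinomial count of genotype assignments x 2^h allele orderings,
        # over the total ways to pair 2n alleles into n genotypes
        num = (
            Fraction(math.factorial(n), math.factorial(h) * math.factorial(hom_minor) * math.factorial(hom_major))
            * 2**h
        )
        probs[h] = num
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_het]
    tol = Fraction(1, 10**9)
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + tol)))


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int, int]]]:
    """BFS component labeling; components ordered by first lexicographic voxel."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)
        ]
        if connectivity == 18:
            offsets = [o for o in offsets if abs(o[0]) + abs(o[1]) + abs(o[2]) <= 2]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            i, j, k = queue.popleft()
            comp.add((i, j, k))
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if (
                    0 <= ni < mask.shape[0]
                    and 0 <= nj < mask.shape[1]
                    and 0 <= nk < mask.shape[2]
                    and mask[ni, nj, nk]
                    and not seen[ni, nj, nk]
                ):
                    seen[ni, nj, nk] = True
                    queue.append((ni, nj, nk))
        comps.append(comp)
    return comps


def dense_gaussian_convolution(vol: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct 3D convolution with the truncated, normalized Gaussian kernel,
    reflect boundary handling."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    padded = np.pad(vol, radius, mode="symmetric")  # scipy's "reflect" == np.pad "symmetric"
    out = np.zeros_like(vol, dtype=float)
    nx, ny, nz = vol.shape
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            for dk in range(-radius, radius + 1):
                w = k1[di + radius] * k1[dj + radius] * k1[dk + radius]
                out += w * padded[
                    radius + di : radius + di + nx,
                    radius + dj : radius + dj + ny,
                    radius + dk : radius + dk + nz,
                ]
    return out


def dense_reml_loglik(y: np.ndarray, x: np.ndarray, a: np.ndarray,
                      sg: float, se: float) -> float:
    """REML log-likelihood via explicit inverse and determinants."""
    n = len(y)
    v = sg * a + se * np.eye(n)
    vinv = np.linalg.inv(v)
    _, logdet_v = np.linalg.slogdet(v)
    xtvx = x.T @ vinv @ x
    _, logdet_xtvx = np.linalg.slogdet(xtvx)
    p = vinv - vinv @ x @ np.linalg.inv(xtvx) @ x.T @ vinv
    return float(-0.5 * (logdet_v + logdet_xtvx + y @ p @ y))


def grid_search_reml(y: np.ndarray, x: np.ndarray, a: np.ndarray,
                     step: float = 0.001) -> tuple[float, float]:
    """Profile the restricted likelihood over h2 on a grid.

    For each h the total variance is profiled in closed form:
    sigma_t = y' P~ y / (N - C) with V~ = h A + (1-h) I.
    Returns (best h2, best log-likelihood).
    """
    n, c = x.shape
    best_h, best_ll = 0.0, -np.inf
    for h in np.arange(0.0, 1.0 + step / 2, step):
        h = min(h, 1.0 - 1e-9)  # keep V positive definite at the top end
        vt = h * a + (1.0 - h) * np.eye(n)
        vt_inv = np.linalg.inv(vt)
        xtvx = x.T @ vt_inv @ x
        pt = vt_inv - vt_inv @ x @ np.linalg.inv(xtvx) @ x.T @ vt_inv
        ypy = float(y @ pt @ y)
        sigma_t = ypy / (n - c)
        ll = dense_reml_loglik(y, x, a, h * sigma_t, (1.0 - h) * sigma_t)
        if ll > best_ll:
            best_h, best_ll = float(h), ll
    return best_h, best_ll


def groupby_mean(values: np.ndarray, groups: list[list[int]]) -> np.ndarray:
    """Per-subject mean over explicit column groups, via plain Python sums."""
    out = np.zeros((values.shape[0], len(groups)))
    for g_i, cols in enumerate(groups):
        for s in range(values.shape[0]):
            out[s, g_i] = sum(values[s, c] for c in cols) / len(cols)
    return out


def sort_and_slice_select(p: np.ndarray, coords: np.ndarray, alpha: float,
                          fraction: float, arm: str) -> set[tuple[int, int, int]]:
    """Reference top-fraction voxel selection by explicit Python sorting."""
    items = []
    for pos in range(len(p)):
        pv = float(p[pos])
        c = tuple(int(v) for v in coords[pos])
        if arm == "significant" and pv < alpha:
            items.append((pv, c))
        elif arm == "insignificant" and pv >= alpha:
            items.append((-pv, c))
    items.sort()
    n_keep = math.ceil(fraction * len(items))
    return {c for _, c in items[:n_keep]}
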