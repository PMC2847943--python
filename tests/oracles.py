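"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition by a different
computational route than the library (explicit loops, pairwise distances,
exhaustive search), so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def count_at_least(values, t) -> int:
    """Voxel count >= t by explicit iteration."""
    return sum(1 for v in np.asarray(values).ravel() if v >= t)


def mean_by_sum(values) -> float:
    vals = list(np.asarray(values, dtype=float).ravel())
    return sum(vals) / len(vals)


def otsu_exhaustive(values, nbins: int = 256) -> float:
    """Between-class-variance maximization by explicit search over bin edges."""
    x = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(x, bins=nbins)
    n = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_var = None, -1.0
    for k in range(nbins - 1):
        n0 = counts[: k + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = float((counts[: k + 1] * centers[: k + 1]).sum()) / n0
        mu1 = float((counts[k + 1 :] * centers[k + 1 :]).sum()) / n1
        var = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_t = edges[k + 1]
    return float(best_t)


def local_thickness_bruteforce(phase: np.ndarray) -> np.ndarray:
    """Maximal-inscribed-sphere diameters by pairwise distances.

    Same convention as the library: the phase is padded with background, the
    sphere at y covers voxels within R(y) (distance to the nearest background
    voxel center) and has diameter 2(R(y) - 1/2); tau(x) is the largest
    diameter over spheres covering x.
    """
    phase = np.pad(np.asarray(phase, dtype=bool), 1, constant_values=False)
    fg = np.argwhere(phase)
    bg = np.argwhere(~phase)
    # R: distance to nearest background voxel center (chunked pairwise)
    R = np.empty(len(fg))
    for i in range(0, len(fg), 512):
        d2 = ((fg[i : i + 512, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
        R[i : i + 512] = np.sqrt(d2.min(axis=1))
    tau = np.zeros(len(fg))
    for i in range(0, len(fg), 512):
        d2 = ((fg[i : i + 512, None, :] - fg[None, :, :]) ** 2).sum(axis=2)
        covered = d2 <= R[None, :] ** 2 + 1e-9
        cand = np.where(covered, 2.0 * R[None, :] - 1.0, -np.inf)
        tau[i : i + 512] = cand.max(axis=1)
    out = np.zeros(phase.shape)
    out[tuple(fg.T)] = tau
    return out[tuple(slice(1, -1) for _ in range(phase.ndim))]


def mean_diameter_bruteforce(phase: np.ndarray) -> float:
    """Volume-weighted mean inscribed-sphere diameter in voxels."""
    tau = local_thickness_bruteforce(phase)
    return float(tau[np.asarray(phase, dtype=bool)].mean())


def intercepts_bruteforce(window: np.ndarray, pixel_size: float) -> dict[str, float]:
    """Run-length stereology along axis 0 by explicit per-pixel scanning."""
    window = np.asarray(window, dtype=bool)
    nz, ny = window.shape
    bone_runs, marrow_runs = [], []
    n_icpt = 0
    for j in range(ny):
        col = window[:, j]
        i = 0
        while i < nz:
            v = col[i]
            k = i
            while k < nz and col[k] == v:
                k += 1
            length = k - i
            edge = i == 0 or k == nz
            if not (edge and length != nz):
                if v:
                    bone_runs.append(length)
                    n_icpt += 1
                else:
                    marrow_runs.append(length)
            i = k
    tbn = n_icpt / (ny * nz * pixel_size)
    tbth = (sum(bone_runs) / len(bone_runs)) * pixel_size if bone_runs else 0.0
    tbsp_icpt = (sum(marrow_runs) / len(marrow_runs)) * pixel_size if marrow_runs else 0.0
    tbsp = max(1.0 / tbn - tbth, 0.0) if tbn > 0 else tbsp_icpt
    bone = sum(1 for v in window.ravel() if v)
    return {"BVTV": bone / window.size, "TbN": tbn, "TbTh": tbth, "TbSp": tbsp}


def ray_sum_dxa(values: np.ndarray, spacing: float, zi, yi) -> float:
    """Areal BMD (g/cm^2) of a (z, y) window by explicit per-ray summation."""
    total, n = 0.0, 0
    for z in zi:
        for y in yi:
            ray = 0.0
            for x in range(values.shape[2]):
                ray += float(values[z, y, x]) * (spacing / 10.0)  # mg/cm^3 * cm
            total += ray / 1000.0
            n += 1
    return total / n


def random_blob_mask(shape, rng, p: float = 0.5) -> np.ndarray:
    """Smooth random boolean mask with both phases present."""
    from scipy import ndimage
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    mask = field > np.quantile(field, p)
    if not mask.any():
        mask.flat[0] = True
    if mask.all():
        mask.flat[0] = False
    return mask
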