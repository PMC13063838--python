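"""Independent brute-force reference implementations for texture features.

Everything here enumerates voxels or voxel pairs with plain Python loops
and the textbook formulas, deliberately sharing no code with the package's
vectorized implementations, so agreement on small volumes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def glcm_matrix_brute(levels, mask, direction, offset):
    """Symmetric normalized GLCM by exhaustive ordered-pair enumeration."""
    nx, ny, nz = levels.shape
    counts: dict[tuple[int, int], int] = {}
    vec = tuple(offset * c for c in direction)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                xx, yy, zz = x + vec[0], y + vec[1], z + vec[2]
                if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                    continue
                if not mask[xx, yy, zz]:
                    continue
                a, b = int(levels[x, y, z]), int(levels[xx, yy, zz])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None
    m = np.zeros((256, 256))
    for (a, b), c in counts.items():
        m[a, b] = c / total
    return m


def glcm_stat_brute(m, stat):
    val = 0.0
    if stat == "correlation":
        px = m.sum(axis=1)
        mu = sum(i * px[i] for i in range(256))
        var = sum((i - mu) ** 2 * px[i] for i in range(256))
        if var == 0:
            return 0.0
        num = sum(
            i * j * m[i, j] for i in range(256) for j in range(256) if m[i, j] > 0
        )
        return (num - mu * mu) / var
    for i in range(256):
        for j in range(256):
            p = m[i, j]
            if p == 0:
                continue
            if stat == "homogeniety":
                val += p / (1 + (i - j) ** 2)
            elif stat == "contrast":
                val += (i - j) ** 2 * p
            elif stat == "energy":
                val += p * p
            elif stat == "entropy":
                val -= p * math.log2(p)
    return val


def runs_brute(levels, mask, direction):
    """All maximal same-level runs along a direction, by walking each line."""
    nx, ny, nz = levels.shape
    in_run = set()
    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or (x, y, z) in in_run:
                    continue
                # walk backwards to find the true run start
                px_, py, pz = x - direction[0], y - direction[1], z - direction[2]
                if (
                    0 <= px_ < nx and 0 <= py < ny and 0 <= pz < nz
                    and mask[px_, py, pz]
                    and levels[px_, py, pz] == levels[x, y, z]
                ):
                    continue  # not a run start
                length = 0
                cx, cy, cz = x, y, z
                while (
                    0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
                    and mask[cx, cy, cz]
                    and levels[cx, cy, cz] == levels[x, y, z]
                ):
                    in_run.add((cx, cy, cz))
                    length += 1
                    cx, cy, cz = cx + direction[0], cy + direction[1], cz + direction[2]
                runs.append((int(levels[x, y, z]), length))
    return runs


def glrlm_stats_brute(levels, mask, n_vox):
    """The ten run-length statistics averaged over the 13 directions."""
    per_dir: dict[str, list[float]] = {
        s: [] for s in
        ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRHGE")
    }
    for d in DIRECTIONS:
        runs = runs_brute(levels, mask, d)
        if not runs:
            continue
        nr = len(runs)
        gl: dict[int, int] = {}
        rl: dict[int, int] = {}
        for g, ln in runs:
            gl[g] = gl.get(g, 0) + 1
            rl[ln] = rl.get(ln, 0) + 1
        per_dir["SRE"].append(sum(1 / ln**2 for _, ln in runs) / nr)
        per_dir["LRE"].append(sum(ln**2 for _, ln in runs) / nr)
        per_dir["GLN"].append(sum(c**2 for c in gl.values()) / nr)
        per_dir["RLN"].append(sum(c**2 for c in rl.values()) / nr)
        per_dir["RP"].append(nr / n_vox)
        per_dir["LGRE"].append(sum(1 / (g + 1) ** 2 for g, _ in runs) / nr)
        per_dir["HGRE"].append(sum((g + 1) ** 2 for g, _ in runs) / nr)
        per_dir["SRLGE"].append(sum(1 / ((g + 1) ** 2 * ln**2) for g, ln in runs) / nr)
        per_dir["SRHGE"].append(sum((g + 1) ** 2 / ln**2 for g, ln in runs) / nr)
        per_dir["LRHGE"].append(sum((g + 1) ** 2 * ln**2 for g, ln in runs) / nr)
    return {s: (float(np.mean(v)) if v else float("nan")) for s, v in per_dir.items()}


def first_order_brute(levels, mask):
    vals = sorted(float(levels[i]) for i in zip(*np.nonzero(mask)))
    n = len(vals)
    mean = sum(vals) / n
    med = (
        vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
    )
    energy = sum(v * v for v in vals) / n
    hist: dict[float, int] = {}
    for v in vals:
        hist[v] = hist.get(v, 0) + 1
    entropy = -sum((c / n) * math.log2(c / n) for c in hist.values())
    out = {"mean": mean, "median": med, "energy": energy, "entropy": entropy}
    if n >= 2:
        var = sum((v - mean) ** 2 for v in vals) / (n - 1)
        out["SD"] = math.sqrt(var)
        pop_var = sum((v - mean) ** 2 for v in vals) / n
        if pop_var == 0:
            out["skewness"] = 0.0
            out["kurtosis"] = 0.0
        else:
            m3 = sum((v - mean) ** 3 for v in vals) / n
            m4 = sum((v - mean) ** 4 for v in vals) / n
            out["skewness"] = m3 / pop_var**1.5
            out["kurtosis"] = m4 / pop_var**2 - 3.0
    return out


def surface_area_brute(mask, spacing):
    """Exposed-face count with per-axis face areas, voxel by voxel."""
    nx, ny, nz = mask.shape
    sx, sy, sz = spacing
    areas = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for ax, (dx, dy, dz) in enumerate(
                    [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
                ):
                    for sgn in (1, -1):
                        xx, yy, zz = x + sgn * dx, y + sgn * dy, z + sgn * dz
                        if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                            total += areas[ax]
                        elif not mask[xx, yy, zz]:
                            total += areas[ax]
    return total


def location_brute(core, atlas, groups):
    n = 0
    hits = [0] * len(groups)
    nx, ny, nz = core.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not core[x, y, z]:
                    continue
                n += 1
                for gi, g in enumerate(groups):
                    if atlas[x, y, z] in g:
                        hits[gi] += 1
    return [h / n for h in hits]


def cumulative_dynamic_auc_brute(times, events, scores, t):
    """Comparable-pair AUC at time t for uncensored data: cases have an
    event by t, controls survive beyond t; ties in score count 1/2."""
    cases = [i for i in range(len(times)) if times[i] <= t and events[i] == 1]
    controls = [i for i in range(len(times)) if times[i] > t]
    if not cases or not controls:
        return float("nan")
    s = 0.0
    for i in cases:
        for j in controls:
            if scores[i] > scores[j]:
                s += 1.0
            elif scores[i] == scores[j]:
                s += 0.5
    return s / (len(cases) * len(controls))
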