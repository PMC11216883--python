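"""Naive, loop-based reference implementations used as independent oracles.

Deliberately written as explicit double loops / flood fills over small
arrays so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def loop_mean(plane: np.ndarray, mask: np.ndarray) -> float:
    total, count = 0.0, 0
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            if mask[y, x]:
                total += float(plane[y, x])
                count += 1
    return total / count


def loop_sum(plane: np.ndarray, mask: np.ndarray) -> float:
    total = 0.0
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            if mask[y, x]:
                total += float(plane[y, x])
    return total


def loop_max_project(stack: np.ndarray) -> np.ndarray:
    z, h, w = stack.shape
    out = np.empty((h, w), dtype=float)
    for y in range(h):
        for x in range(w):
            best = stack[0, y, x]
            for k in range(1, z):
                if stack[k, y, x] > best:
                    best = stack[k, y, x]
            out[y, x] = best
    return out


def loop_mean_of_minima(planes: list[np.ndarray]) -> float:
    minima = []
    for p in planes:
        m = p[0, 0]
        for y in range(p.shape[0]):
            for x in range(p.shape[1]):
                if p[y, x] < m:
                    m = p[y, x]
        minima.append(float(m))
    return sum(minima) / len(minima)


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """8-connectivity labeling by explicit stack-based flood fill."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    areas = []
    nxt = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or labels[sy, sx]:
                continue
            nxt += 1
            stack = [(sy, sx)]
            labels[sy, sx] = nxt
            area = 0
            while stack:
                y, x = stack.pop()
                area += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx_ = y + dy, x + dx
                        if (
                            0 <= ny < h
                            and 0 <= nx_ < w
                            and mask[ny, nx_]
                            and not labels[ny, nx_]
                        ):
                            labels[ny, nx_] = nxt
                            stack.append((ny, nx_))
            areas.append(area)
    return labels, areas


def filter_labels_by_area(
    labels: np.ndarray, areas: list[int], min_area_px: float
) -> np.ndarray:
    keep = {i + 1 for i, a in enumerate(areas) if a >= min_area_px}
    out = np.zeros(labels.shape, dtype=bool)
    for y in range(labels.shape[0]):
        for x in range(labels.shape[1]):
            if labels[y, x] in keep:
                out[y, x] = True
    return out


def shoelace_area(vertices) -> float:
    s = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2
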