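"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written as plain frame-by-frame scans, sharing no code with
the package.
"""

from __future__ import annotations

import numpy as np

THRESHOLD = 0.001


def brute_epoch_table(velocity: np.ndarray, teleport: np.ndarray) -> list[tuple[str, int, int]]:
    """Enumerate all maximal constant-state runs and apply the length rules.

    Returns (kind, start, end) half-open tuples covering every frame, with
    sub-threshold runs < 12 frames and run/backtrack runs < 2 frames
    relabelled 'discarded' (and adjacent discarded stretches merged).
    """
    n = len(velocity)

    def state(i: int) -> str:
        if teleport[i]:
            return "teleport"
        if velocity[i] >= THRESHOLD:
            return "run"
        if velocity[i] <= -THRESHOLD:
            return "backtrack"
        return "freeze"

    raw = []
    i = 0
    while i < n:
        j = i
        while j < n and state(j) == state(i):
            j += 1
        raw.append((state(i), i, j))
        i = j

    relabelled = []
    for kind, start, end in raw:
        length = end - start
        if kind == "freeze" and length < 12:
            kind = "discarded"
        elif kind in ("run", "backtrack") and length < 2:
            kind = "discarded"
        relabelled.append((kind, start, end))

    merged: list[tuple[str, int, int]] = []
    for kind, start, end in relabelled:
        if merged and merged[-1][0] == kind:
            merged[-1] = (kind, merged[-1][1], end)
        else:
            merged.append((kind, start, end))
    return merged


def brute_find_peaks(
    x: np.ndarray, height: float, prominence: float, distance: int
) -> list[int]:
    """Exhaustive peak scan with the height/distance/prominence contract.

    Candidate peaks are strict local maxima; the height filter applies
    first, then the distance rule (higher peaks claim their neighbourhood,
    processed in decreasing height order), then the prominence filter
    (lowest descent to a higher point on either side).
    """
    n = len(x)
    # local maxima with plateau support: a flat top counts once, at its midpoint
    cands = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                cands.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    cands = [i for i in cands if x[i] >= height]

    removed: set[int] = set()
    # equal heights: the rightmost peak is processed (and kept) first
    for i in sorted(cands, key=lambda k: (x[k], k), reverse=True):
        if i in removed:
            continue
        for j in cands:
            if j != i and j not in removed and abs(j - i) < distance:
                removed.add(j)
    kept = [i for i in cands if i not in removed]

    def prom(i: int) -> float:
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        return x[i] - max(left_min, right_min)

    return [i for i in kept if prom(i) >= prominence]


def random_session_velocity(
    rng: np.random.Generator, n_frames: int
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity + teleport traces exercising all epoch kinds and edge lengths."""
    velocity = np.empty(n_frames)
    teleport = np.zeros(n_frames, dtype=bool)
    i = 0
    while i < n_frames:
        kind = rng.choice(["still", "forward", "backward", "teleport"], p=[0.35, 0.4, 0.15, 0.1])
        length = int(rng.integers(1, 30))
        end = min(n_frames, i + length)
        if kind == "still":
            velocity[i:end] = rng.uniform(-0.0009, 0.0009, end - i)
        elif kind == "forward":
            velocity[i:end] = rng.uniform(0.001, 30.0, end - i)
        elif kind == "backward":
            velocity[i:end] = rng.uniform(-10.0, -0.001, end - i)
        else:
            velocity[i:end] = 0.0
            teleport[i:end] = True
        i = end
    return velocity, teleport
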