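"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (literal set
arithmetic, exhaustive enumeration) and share no code with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np


def minkowski_dilation(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """A ⊕ B = {a + b : a in A, b in B} as literal set arithmetic.

    ``se`` is a binary structuring element whose origin is its centre
    pixel; translates falling outside the raster are discarded.
    """
    mask = np.asarray(mask).astype(bool)
    se = np.asarray(se).astype(bool)
    orow, ocol = se.shape[0] // 2, se.shape[1] // 2
    out = np.zeros_like(mask)
    A = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}
    B = {(int(r) - orow, int(c) - ocol) for r, c in zip(*np.nonzero(se))}
    for (ar, ac) in A:
        for (br, bc) in B:
            rr, cc = ar + br, ac + bc
            if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                out[rr, cc] = True
    return out


def minkowski_erosion(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """A ⊖ B = {c : B translated to c is contained in A}.

    Translates reaching outside the raster disqualify c (border pixels are
    treated as background), matching erosion of a finite raster.
    """
    mask = np.asarray(mask).astype(bool)
    se = np.asarray(se).astype(bool)
    orow, ocol = se.shape[0] // 2, se.shape[1] // 2
    B = [(int(r) - orow, int(c) - ocol) for r, c in zip(*np.nonzero(se))]
    out = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            ok = True
            for (br, bc) in B:
                rr, cc = r + br, c + bc
                if not (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def flood_fill_threshold(
    img: np.ndarray,
    seed: tuple[int, int],
    bbox: tuple[int, int, int, int],
    level: float,
) -> np.ndarray:
    """4-connected flood fill over pixels >= level inside an inclusive bbox."""
    img = np.asarray(img, dtype=float)
    r0, c0, r1, c1 = bbox
    out = np.zeros(img.shape, dtype=bool)
    stack = [seed]
    while stack:
        r, c = stack.pop()
        if not (r0 <= r <= r1 and c0 <= c <= c1) or out[r, c] or img[r, c] < level:
            continue
        out[r, c] = True
        stack.extend([(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)])
    return out


def enumerate_components(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """Exhaustive connected-component enumeration by BFS."""
    mask = np.asarray(mask).astype(bool)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def brute_force_threshold(r: np.ndarray, h: np.ndarray) -> int:
    """Exhaustive argmin of eps_tau = sum_{f<tau} (r-h)(f) + sum_{f>=tau} r(f)
    over tau = 0..len(h)+... ; ``r`` may extend beyond ``h`` (model tail)."""
    F = len(r) - 1
    f_max = len(h) - 1
    best_tau, best_eps = None, None
    for tau in range(f_max + 2):
        eps = 0.0
        for f in range(tau):
            eps += r[f] - (h[f] if f <= f_max else 0.0)
        for f in range(tau, F + 1):
            eps += r[f]
        if best_eps is None or eps < best_eps - 1e-15:
            best_tau, best_eps = tau, eps
    return best_tau
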