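"""Compiled core of the cellular Potts simulator.

Flat-array state, precomputed periodic neighbour tables and an inlined
xorshift128+ RNG keep a single pixel-copy attempt cheap enough that a
full 300x300-lattice Monte Carlo step (90 000 attempts) runs in a few
milliseconds on one core.  All functions are numba-jitted and operate
on plain ndarrays; the public wrapper lives in
:mod:`pottsml.cpm_sim`.

State arrays (C = number of cells, N = lattice_size**2):
  labels  int16[N]    cell id per pixel, row-major, 1-based (fits L2)
  area    int64[C+1]  pixel count per cell
  perim   int64[C+1]  boundary-pixel count per cell
  comx/y  float64[C+1] centre of mass, wrapped into [0, size)
  kappa   float64[C+1] motility strength
  theta / polx / poly  polarity angle and unit vector
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ring order: E, NE, N, NW, W, SW, S, SE (edge neighbours at even slots)
_RING_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
_RING_DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)


def build_neighbour_tables(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Periodic first-order (N,4) and ring-ordered (N,8) index tables."""
    y, x = np.divmod(np.arange(size * size), size)

    def idx(dx, dy):
        return ((y + dy) % size) * size + (x + dx) % size

    nbr4 = np.stack([idx(1, 0), idx(0, 1), idx(-1, 0), idx(0, -1)], axis=1)
    nbr8 = np.stack([idx(dx, dy) for dx, dy in zip(_RING_DX, _RING_DY)],
                    axis=1)
    return nbr4.astype(np.int32), nbr8.astype(np.int32)


# ---------------------------------------------------------------- RNG --

@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return (s0 + s1) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _rand_double(state):
    return (_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _rand_below(state, n):
    return int(_rand_double(state) * n)


def seed_state(seed: int) -> np.ndarray:
    """Expand a small integer seed into a nonzero xorshift128+ state."""
    mask = (1 << 64) - 1
    z = int(seed) & mask
    words = []
    for _ in range(2):  # splitmix64 expansion
        z = (z + 0x9E3779B97F4A7C15) & mask
        t = z
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & mask
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & mask
        words.append(t ^ (t >> 31))
    if words[0] == 0 and words[1] == 0:
        words[0] = 1
    return np.array(words, dtype=np.uint64)


# ------------------------------------------------------------ geometry --

@njit(cache=True, inline="always")
def _is_boundary(labels, nbr4, p, i, new_lab, owner):
    """Boundary status of pixel p if pixel i carried ``new_lab``."""
    for k in range(4):
        q = nbr4[p, k]
        lab = new_lab if q == i else labels[q]
        if lab != owner:
            return 1
    return 0


@njit(cache=True, inline="always")
def delta_perimeters(labels, nbr4, i, sig_to):
    """Boundary-pixel-count changes (dP_from, dP_to) for flipping pixel i.

    Only the two cells exchanging the pixel can change their counts:
    a third cell's pixel keeps a differing neighbour either way.
    """
    sig_from = labels[i]
    dp_from = -_is_boundary(labels, nbr4, i, i, sig_from, sig_from)
    dp_to = _is_boundary(labels, nbr4, i, i, sig_to, sig_to)
    for k in range(4):
        p = nbr4[i, k]
        owner = labels[p]
        if owner == sig_from or owner == sig_to:
            before = _is_boundary(labels, nbr4, p, i, sig_from, owner)
            after = _is_boundary(labels, nbr4, p, i, sig_to, owner)
            if owner == sig_from:
                dp_from += after - before
            else:
                dp_to += after - before
    return dp_from, dp_to


@njit(cache=True, inline="always")
def _perim_energy(p, p_t, lam_p):
    if p > p_t:
        d = p - p_t
        return lam_p * d * d
    return 0.0


@njit(cache=True, fastmath=True, inline="always")
def _delta_full(labels, nbr4, nbr8, area, perim, comx, comy,
                kappa, polx, poly, i, sig_to,
                size, j_cc, a_t, lam_a, lam_p, p_t, adh_order):
    """Fused energy change + perimeter deltas for one pixel copy.

    Reads the 13-pixel first-order star-of-star of i exactly once and
    derives the adhesion change and both boundary-count changes from
    registers.  For an edge neighbour p owned by the losing cell the
    new label of i always differs from the owner, so p's post-move
    boundary status is 1 and its change reduces to 1 - rest(p), where
    rest(p) is p's boundary status ignoring i; symmetrically for the
    gaining cell.  Returns (dh, dp_from, dp_to).
    """
    f = labels[i]
    t = sig_to
    e = nbr4[i, 0]
    n = nbr4[i, 1]
    w = nbr4[i, 2]
    s = nbr4[i, 3]
    le = labels[e]
    ln = labels[n]
    lw = labels[w]
    ls = labels[s]
    # adhesion (first-order pairs incident on i)
    cnt = 0
    cnt += int(le != t) - int(le != f)
    cnt += int(ln != t) - int(ln != f)
    cnt += int(lw != t) - int(lw != f)
    cnt += int(ls != t) - int(ls != f)
    dh = j_cc * cnt
    if adh_order == 2:  # diagonal pairs
        cnt2 = 0
        lab = labels[nbr8[i, 1]]
        cnt2 += int(lab != t) - int(lab != f)
        lab = labels[nbr8[i, 3]]
        cnt2 += int(lab != t) - int(lab != f)
        lab = labels[nbr8[i, 5]]
        cnt2 += int(lab != t) - int(lab != f)
        lab = labels[nbr8[i, 7]]
        cnt2 += int(lab != t) - int(lab != f)
        dh += j_cc * cnt2
    # perimeter deltas (boundary-pixel counts of the two cells)
    dpf = -int((le != f) | (ln != f) | (lw != f) | (ls != f))
    dpt = int((le != t) | (ln != t) | (lw != t) | (ls != t))
    if le == f or le == t:
        rest = int((labels[nbr4[e, 0]] != le) | (labels[nbr4[e, 1]] != le)
                   | (labels[nbr4[e, 3]] != le))
        if le == f:
            dpf += 1 - rest
        else:
            dpt += rest - 1
    if ln == f or ln == t:
        rest = int((labels[nbr4[n, 1]] != ln) | (labels[nbr4[n, 2]] != ln)
                   | (labels[nbr4[n, 0]] != ln))
        if ln == f:
            dpf += 1 - rest
        else:
            dpt += rest - 1
    if lw == f or lw == t:
        rest = int((labels[nbr4[w, 2]] != lw) | (labels[nbr4[w, 3]] != lw)
                   | (labels[nbr4[w, 1]] != lw))
        if lw == f:
            dpf += 1 - rest
        else:
            dpt += rest - 1
    if ls == f or ls == t:
        rest = int((labels[nbr4[s, 3]] != ls) | (labels[nbr4[s, 0]] != ls)
                   | (labels[nbr4[s, 2]] != ls))
        if ls == f:
            dpf += 1 - rest
        else:
            dpt += rest - 1
    if perim[f] + dpf > p_t or perim[f] > p_t or perim[t] + dpt > p_t \
            or perim[t] > p_t:
        dh += (_perim_energy(perim[f] + dpf, p_t, lam_p)
               - _perim_energy(perim[f], p_t, lam_p)
               + _perim_energy(perim[t] + dpt, p_t, lam_p)
               - _perim_energy(perim[t], p_t, lam_p))
    # area + motility
    af = area[f]
    at_ = area[t]
    dh += lam_a * 2.0 * (float(at_ - af) + 1.0)
    x = float(i % size)
    y = float(i // size)
    half = 0.5 * size
    if kappa[t] != 0.0:
        dxg = x - comx[t]
        if dxg > half:
            dxg -= size
        elif dxg < -half:
            dxg += size
        dyg = y - comy[t]
        if dyg > half:
            dyg -= size
        elif dyg < -half:
            dyg += size
        dh -= kappa[t] * (polx[t] * dxg + poly[t] * dyg) / (at_ + 1)
    if kappa[f] != 0.0 and af > 1:
        dxl = x - comx[f]
        if dxl > half:
            dxl -= size
        elif dxl < -half:
            dxl += size
        dyl = y - comy[f]
        if dyl > half:
            dyl -= size
        elif dyl < -half:
            dyl += size
        dh += kappa[f] * (polx[f] * dxl + poly[f] * dyl) / (af - 1)
    return dh, dpf, dpt


@njit(cache=True)
def delta_hamiltonian_px(labels, nbr4, nbr8, area, perim, comx, comy,
                         kappa, polx, poly, i, sig_to,
                         size, j_cc, a_t, lam_a, lam_p, p_t, adh_order):
    """Full energy change for copying label ``sig_to`` onto pixel i.

    Reference-Hamiltonian change (adhesion + area + one-sided
    perimeter) plus the motility bias -kappa (p . dR) for both the
    gaining and the losing cell.
    """
    dh, _, _ = _delta_full(labels, nbr4, nbr8, area, perim, comx, comy,
                           kappa, polx, poly, i, sig_to, size, j_cc, a_t,
                           lam_a, lam_p, p_t, adh_order)
    return dh


# -------------------------------------------------------- connectivity --

def _build_simple_lut() -> np.ndarray:
    """Ring-mask lookup: 1 = provably safe to remove the centre pixel.

    Bit k of the mask marks ring neighbour k (order E,NE,N,NW,W,SW,S,SE)
    as belonging to the same cell.  Safe means the member pixels form a
    single circular arc containing an edge (4-) neighbour with no
    corner-only arc; anything else falls back to the exact check.
    """
    lut = np.zeros(256, dtype=np.uint8)
    for mask in range(256):
        m = [(mask >> k) & 1 for k in range(8)]
        arcs_with_edge = 0
        arcs_corner_only = 0
        for k in range(8):
            if m[k] == 1 and m[(k + 7) % 8] == 0:
                has_edge = False
                j = k
                while m[j % 8] == 1:
                    if (j % 8) % 2 == 0:
                        has_edge = True
                    j += 1
                    if j - k == 8:
                        break
                if has_edge:
                    arcs_with_edge += 1
                else:
                    arcs_corner_only += 1
        if arcs_with_edge == 1 and arcs_corner_only == 0:
            lut[mask] = 1
    return lut


_SIMPLE_LUT = _build_simple_lut()


@njit(cache=True, inline="always")
def _local_simple(labels, nbr8, i, sig):
    """Ring test: 1 = provably safe to remove, 0 = needs exact check."""
    mask = 0
    for k in range(8):
        if labels[nbr8[i, k]] == sig:
            mask |= 1 << k
    return _SIMPLE_LUT[mask]


@njit(cache=True)
def _connected_without(labels, nbr4, i, sig, target_count, visited, stack,
                       gen):
    """Exact check: is cell ``sig`` minus pixel i still 4-connected?

    Every component of the cell minus i contains a first-order
    neighbour of i (the original cell is connected through i), so the
    cell stays connected iff all of i's in-cell 4-neighbours lie in
    one component.  The flood fill starts from one of them and stops
    as soon as the others are found, which keeps the typical cost to
    a few pixels; ``target_count`` bounds the worst case.
    """
    seed = -1
    want = 0
    for k in range(4):
        q = nbr4[i, k]
        if labels[q] == sig:
            if seed < 0:
                seed = q
            else:
                want += 1
    if seed < 0:
        return 0
    if want == 0:
        return 1
    visited[i] = gen  # treat removed pixel as blocked
    visited[seed] = gen
    top = 0
    stack[top] = seed
    top += 1
    remaining = want
    explored = 1
    while top > 0:
        top -= 1
        p = stack[top]
        for k in range(4):
            q = nbr4[p, k]
            if labels[q] == sig and visited[q] != gen:
                visited[q] = gen
                # is q one of i's other 4-neighbours?
                for kk in range(4):
                    if nbr4[i, kk] == q:
                        remaining -= 1
                        break
                if remaining == 0:
                    return 1
                stack[top] = q
                top += 1
                explored += 1
                if explored > target_count:
                    return 0
    return 0


@njit(cache=True)
def connectivity_ok_px(labels, nbr4, nbr8, area, i, visited, stack, gen):
    """True iff removing pixel i keeps its cell non-empty and connected."""
    sig = labels[i]
    if area[sig] <= 1:
        return 0
    if _local_simple(labels, nbr8, i, sig) == 1:
        return 1
    return _connected_without(labels, nbr4, i, sig, area[sig] - 1,
                              visited, stack, gen)


# ---------------------------------------------------------------- sweep --

@njit(cache=True, fastmath=True)
def _apply_move_dp(labels, area, perim, comx, comy, i, sig_to,
                   dpf, dpt, size):
    """Commit an accepted pixel copy; incremental bookkeeping.

    COMs stay wrapped into [0, size); displacements use the minimum
    image, so the stored value may leave [0, size) by less than one
    pixel per move and is re-wrapped.
    """
    sig_from = labels[i]
    x = float(i % size)
    y = float(i // size)
    half = 0.5 * size
    af = area[sig_from]
    at_ = area[sig_to]
    dxg = x - comx[sig_to]
    if dxg > half:
        dxg -= size
    elif dxg < -half:
        dxg += size
    dyg = y - comy[sig_to]
    if dyg > half:
        dyg -= size
    elif dyg < -half:
        dyg += size
    cx = comx[sig_to] + dxg / (at_ + 1)
    if cx >= size:
        cx -= size
    elif cx < 0.0:
        cx += size
    comx[sig_to] = cx
    cy = comy[sig_to] + dyg / (at_ + 1)
    if cy >= size:
        cy -= size
    elif cy < 0.0:
        cy += size
    comy[sig_to] = cy
    dxl = x - comx[sig_from]
    if dxl > half:
        dxl -= size
    elif dxl < -half:
        dxl += size
    dyl = y - comy[sig_from]
    if dyl > half:
        dyl -= size
    elif dyl < -half:
        dyl += size
    cx = comx[sig_from] - dxl / (af - 1)
    if cx >= size:
        cx -= size
    elif cx < 0.0:
        cx += size
    comx[sig_from] = cx
    cy = comy[sig_from] - dyl / (af - 1)
    if cy >= size:
        cy -= size
    elif cy < 0.0:
        cy += size
    comy[sig_from] = cy
    labels[i] = sig_to
    area[sig_from] -= 1
    area[sig_to] += 1
    perim[sig_from] += dpf
    perim[sig_to] += dpt


@njit(cache=True)
def apply_move(labels, nbr4, area, perim, comx, comy, i, sig_to, size):
    dpf, dpt = delta_perimeters(labels, nbr4, i, sig_to)
    _apply_move_dp(labels, area, perim, comx, comy, i, sig_to,
                   dpf, dpt, size)


@njit(cache=True, fastmath=True)
def run_mcs(labels, nbr4, nbr8, area, perim, comx, comy,
            kappa, theta, polx, poly,
            rng_state, visited, stack, gen_box, n_mcs,
            size, j_cc, a_t, lam_a, lam_p, p_t, temperature, eta_max,
            copy_nn, adh_order):
    """Run ``n_mcs`` Monte Carlo steps in place.

    One MCS = size**2 pixel-copy attempts followed by one polarity
    update of every cell.  An attempt is accepted iff the Metropolis
    draw passes AND the losing cell stays connected; the cheap
    rejections run first, which leaves the accepted set unchanged.
    The perimeter scan is skipped when both cells sit safely below the
    penalty threshold (one-sided penalty: the term is exactly zero);
    a pixel copy changes a boundary count by at most 5.

    Returns the number of accepted moves.
    """
    n_px = size * size
    n_cells = area.shape[0] - 1
    accepted = 0
    inv_t = 1.0 / temperature
    for _ in range(n_mcs):
        for _a in range(n_px):
            u = _next_u64(rng_state)
            i = int((u >> np.uint64(11)) * (1.0 / 9007199254740992.0) * n_px)
            d = int(u & np.uint64(7)) % copy_nn
            j = nbr4[i, d] if d < 4 else nbr8[i, 2 * (d - 4) + 1]
            sig_to = labels[j]
            sig_from = labels[i]
            if sig_to == sig_from:
                continue
            dh, dpf, dpt = _delta_full(labels, nbr4, nbr8, area, perim,
                                       comx, comy, kappa, polx, poly,
                                       i, sig_to, size, j_cc, a_t,
                                       lam_a, lam_p, p_t, adh_order)
            if dh > 0.0 and _rand_double(rng_state) >= np.exp(-dh * inv_t):
                continue
            if area[sig_from] <= 1:
                continue
            if _local_simple(labels, nbr8, i, sig_from) == 0:
                gen_box[0] += 1
                if _connected_without(labels, nbr4, i, sig_from,
                                      area[sig_from] - 1, visited, stack,
                                      gen_box[0]) == 0:
                    continue
            _apply_move_dp(labels, area, perim, comx, comy, i, sig_to,
                           dpf, dpt, size)
            accepted += 1
        for c in range(1, n_cells + 1):
            eta = (2.0 * _rand_double(rng_state) - 1.0) * eta_max
            theta[c] += eta
            polx[c] = np.cos(theta[c])
            poly[c] = np.sin(theta[c])
    return accepted
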