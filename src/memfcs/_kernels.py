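"""Numba inner loops for the Monte Carlo diffusion simulation.

The kernels consume pre-drawn random arrays (one normal pair per particle
per step for displacements, one uniform per particle per step for the
trap/hop state machinery) so that they are bit-compatible with the
plain-numpy reference steppers in :mod:`memfcs.simulator`.
"""

import numpy as np
from numba import njit

MODE_FREE = 0
MODE_TRAPPED = 1
MODE_HOP = 2

SHAPE_SQUARE = 0
SHAPE_CIRCLE = 1


@njit(cache=True)
def _wrap_square(v, L):
    v = v % L
    if v < 0.0:
        v += L
    return v


@njit(cache=True)
def run_chunk(x, y, ux, uy, trapped,
              normals, uniforms,
              sigma, L, shape, mode,
              p_trap, p_untrap, p_hop,
              grid, n_grid,
              spots_x, spots_y, neg2_inv_w0sq,
              out, out_trapped,
              sample_every, step_index0, out_row0):
    """Advance the ensemble by ``normals.shape[0]`` steps, sampling intensity.

    Positions ``x, y`` are wrapped into the domain; ``ux, uy`` accumulate the
    unwrapped displacements (for MSD analysis on the torus). Returns the next
    output row index.
    """
    n = x.shape[0]
    n_steps = normals.shape[0]
    n_spots = spots_x.shape[0]
    row = out_row0
    inv_cell = n_grid / L
    c = 0.5 * L
    R = 0.5 * L
    for s in range(n_steps):
        for i in range(n):
            if mode == MODE_TRAPPED:
                u = uniforms[s, i]
                if trapped[i] == 1:
                    if u < p_untrap:
                        trapped[i] = 0
                else:
                    if u < p_trap:
                        trapped[i] = 1
                if trapped[i] == 1:
                    continue
            dx = sigma * normals[s, i, 0]
            dy = sigma * normals[s, i, 1]
            nx = x[i] + dx
            ny = y[i] + dy
            if shape == SHAPE_SQUARE:
                nx = _wrap_square(nx, L)
                ny = _wrap_square(ny, L)
            else:
                ddx = nx - c
                ddy = ny - c
                r2 = ddx * ddx + ddy * ddy
                if r2 > R * R:
                    r = np.sqrt(r2)
                    f = (2.0 * R - r) / r
                    nx = c - ddx * f
                    ny = c - ddy * f
            if mode == MODE_HOP:
                gi0 = int(x[i] * inv_cell)
                gj0 = int(y[i] * inv_cell)
                gi1 = int(nx * inv_cell)
                gj1 = int(ny * inv_cell)
                if gi0 >= n_grid:
                    gi0 = n_grid - 1
                if gj0 >= n_grid:
                    gj0 = n_grid - 1
                if gi1 >= n_grid:
                    gi1 = n_grid - 1
                if gj1 >= n_grid:
                    gj1 = n_grid - 1
                if grid[gi0, gj0] != grid[gi1, gj1]:
                    if uniforms[s, i] >= p_hop:
                        continue  # bounce: move rejected this step
            x[i] = nx
            y[i] = ny
            ux[i] += dx
            uy[i] += dy
        gstep = step_index0 + s + 1
        if gstep % sample_every == 0:
            for k in range(n_spots):
                acc = 0.0
                sx = spots_x[k]
                sy = spots_y[k]
                for i in range(n):
                    ddx = x[i] - sx
                    ddy = y[i] - sy
                    if shape == SHAPE_SQUARE:
                        if ddx > 0.5 * L:
                            ddx -= L
                        elif ddx < -0.5 * L:
                            ddx += L
                        if ddy > 0.5 * L:
                            ddy -= L
                        elif ddy < -0.5 * L:
                            ddy += L
                    acc += np.exp(neg2_inv_w0sq * (ddx * ddx + ddy * ddy))
                out[row, k] = acc
            nt = 0
            for i in range(n):
                if trapped[i] == 1:
                    nt += 1
            out_trapped[row] = nt
            row += 1
    return row
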