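"""Independent reference solutions used as oracles in the test suite.

These are computed by routes independent of the particle simulator: the
closed-form error-function solution of strip bleaching under 1D diffusion in
an unbounded uniform domain, and a Crank–Nicolson finite-difference solution
of the same problem inside the ellipsoidal nucleus, where the elliptical
cross-section area A(x) = 1 − (x/a)² enters the 1D reduction
∂u/∂t = (D/A) ∂x(A ∂x u). The two agree in the wide-nucleus limit.
"""

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erf


def diffusion_strip_rfi_erf(times, D, half_w, depth):
    """Closed-form strip readout for pure 1D diffusion in an infinite domain.

    Post-bleach concentration relative to equilibrium:
    c(x,t) = 1 − (depth/2)·[erf((w/2−x)/√(4Dt)) + erf((w/2+x)/√(4Dt))],
    averaged over the strip and scaled so equilibrium is RFI 100.
    """
    x = np.linspace(-half_w, half_w, 401)
    out = np.empty(len(times))
    for i, t in enumerate(times):
        if t <= 0:
            out[i] = 100.0 * (1.0 - depth)
            continue
        s = np.sqrt(4.0 * D * t)
        c = 1.0 - 0.5 * depth * (erf((half_w - x) / s) + erf((half_w + x) / s))
        out[i] = 100.0 * np.trapezoid(c, x) / (2.0 * half_w)
    return out


def diffusion_strip_rfi_pde(times, D, half_w, depth, a, n_cells=None, dt=0.01):
    """Strip readout for pure diffusion inside the ellipsoid, by finite differences.

    Solves ∂u/∂t = (D/A) ∂x(A ∂x u) with A(x) = 1 − (x/a)² (the ellipsoid's
    cross-section area profile) and zero flux at x = ±a, from the sharp bleach
    profile u(x,0) = 1 − depth inside the strip. Crank–Nicolson in time on a
    conservative flux form; the A→0 ends carry no flux by construction.
    """
    if n_cells is None:
        n_cells = int(2 * a / 0.025)  # 0.025 µm cells resolve the strip edges
    xe = np.linspace(-a, a, n_cells + 1)  # faces
    xc = 0.5 * (xe[:-1] + xe[1:])  # cell centres
    dx = xe[1] - xe[0]
    A_face = 1.0 - (xe / a) ** 2
    A_cell = np.clip(1.0 - (xc / a) ** 2, 1e-12, None)

    # L u  ≈ (D / A_i) [A_{i+1/2}(u_{i+1}-u_i) - A_{i-1/2}(u_i-u_{i-1})] / dx²
    west = A_face[:-1] / A_cell
    east = A_face[1:] / A_cell
    r = D * dt / (2.0 * dx * dx)
    # banded matrices for (I - r L) u^{n+1} = (I + r L) u^n
    lower = -r * west
    upper = -r * east
    diag = 1.0 + r * (west + east)
    ab = np.zeros((3, n_cells))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]

    u = np.where(np.abs(xc) <= half_w, 1.0 - depth, 1.0)
    in_strip = np.abs(xc) <= half_w
    norm = np.sum(A_cell[in_strip])

    t_max = max(float(np.max(times)), 0.0)
    n_steps = int(np.ceil(t_max / dt)) if t_max > 0 else 0
    grid_t = np.arange(n_steps + 1) * dt
    readouts = np.empty(n_steps + 1)
    readouts[0] = 100.0 * np.sum(u[in_strip] * A_cell[in_strip]) / norm
    for k in range(1, n_steps + 1):
        rhs = u.copy()
        rhs[1:-1] += r * (
            east[1:-1] * (u[2:] - u[1:-1]) - west[1:-1] * (u[1:-1] - u[:-2])
        )
        rhs[0] += r * east[0] * (u[1] - u[0])
        rhs[-1] += r * (-west[-1] * (u[-1] - u[-2]))
        u = solve_banded((1, 1), ab, rhs)
        readouts[k] = 100.0 * np.sum(u[in_strip] * A_cell[in_strip]) / norm
    out = np.interp(np.clip(times, 0.0, None), grid_t, readouts)
    out = np.where(np.asarray(times) <= 0, 100.0 * (1.0 - depth), out)
    return out
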