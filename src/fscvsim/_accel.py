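"""Fixed-step RK4 integrator for the release–reuptake–transfer compartment model.

The inner loop is the hot path of kinetic fitting (it runs once per residual
evaluation, for every multistart).  When numba is importable the scalar-loop
variant is JIT-compiled; otherwise a numpy variant vectorized across responses
is used.  Both produce identical trajectories to floating-point roundoff.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _integrate_py(release, dt, vmax, km, k_transfer):
    """RK4 over ``n_steps`` intervals for ``n_resp`` independent subjects.

    release : (n_resp, n_steps) array, release rate in uM/s, treated as
        piecewise-constant on each step (stimulus trains are step functions,
        so switching instants coincide with grid points).
    Returns (c_u, c_m) arrays of shape (n_resp, n_steps + 1): the release
    compartment and the measured (electrode) compartment, both starting at 0.
    Michaelis–Menten uptake is clamped to zero for (transient) negative
    concentrations so RK4 stage excursions cannot inject mass.
    """
    n_resp, n_steps = release.shape
    c_u = np.zeros((n_resp, n_steps + 1))
    c_m = np.zeros((n_resp, n_steps + 1))
    u = np.zeros(n_resp)
    m = np.zeros(n_resp)
    for s in range(n_steps):
        r = release[:, s]

        uu = np.maximum(u, 0.0)
        k1u = r - vmax * uu / (km + uu)
        k1m = k_transfer * (u - m)

        u2 = u + 0.5 * dt * k1u
        m2 = m + 0.5 * dt * k1m
        uu = np.maximum(u2, 0.0)
        k2u = r - vmax * uu / (km + uu)
        k2m = k_transfer * (u2 - m2)

        u3 = u + 0.5 * dt * k2u
        m3 = m + 0.5 * dt * k2m
        uu = np.maximum(u3, 0.0)
        k3u = r - vmax * uu / (km + uu)
        k3m = k_transfer * (u3 - m3)

        u4 = u + dt * k3u
        m4 = m + dt * k3m
        uu = np.maximum(u4, 0.0)
        k4u = r - vmax * uu / (km + uu)
        k4m = k_transfer * (u4 - m4)

        u = u + (dt / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        m = m + (dt / 6.0) * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        c_u[:, s + 1] = u
        c_m[:, s + 1] = m
    return c_u, c_m


if HAVE_NUMBA:

    @njit(cache=True)
    def _integrate_numba(release, dt, vmax, km, k_transfer):  # pragma: no cover
        n_resp, n_steps = release.shape
        c_u = np.zeros((n_resp, n_steps + 1))
        c_m = np.zeros((n_resp, n_steps + 1))
        for i in range(n_resp):
            u = 0.0
            m = 0.0
            for s in range(n_steps):
                r = release[i, s]

                uu = u if u > 0.0 else 0.0
                k1u = r - vmax * uu / (km + uu)
                k1m = k_transfer * (u - m)

                u2 = u + 0.5 * dt * k1u
                m2 = m + 0.5 * dt * k1m
                uu = u2 if u2 > 0.0 else 0.0
                k2u = r - vmax * uu / (km + uu)
                k2m = k_transfer * (u2 - m2)

                u3 = u + 0.5 * dt * k2u
                m3 = m + 0.5 * dt * k2m
                uu = u3 if u3 > 0.0 else 0.0
                k3u = r - vmax * uu / (km + uu)
                k3m = k_transfer * (u3 - m3)

                u4 = u + dt * k3u
                m4 = m + dt * k3m
                uu = u4 if u4 > 0.0 else 0.0
                k4u = r - vmax * uu / (km + uu)
                k4m = k_transfer * (u4 - m4)

                u = u + (dt / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
                m = m + (dt / 6.0) * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
                c_u[i, s + 1] = u
                c_m[i, s + 1] = m
        return c_u, c_m

    def integrate_release_reuptake(release, dt, vmax, km, k_transfer):
        release = np.ascontiguousarray(release, dtype=np.float64)
        return _integrate_numba(release, float(dt), float(vmax), float(km), float(k_transfer))

else:

    def integrate_release_reuptake(release, dt, vmax, km, k_transfer):
        release = np.asarray(release, dtype=np.float64)
        return _integrate_py(release, float(dt), float(vmax), float(km), float(k_transfer))
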