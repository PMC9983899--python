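"""Compiled Kalman forward/backward pass for the pairwise (d = 2) model.

The filter discretizes each observation gap with a single Euler step:
transition I + A*dt, offset a*dt, process covariance dt*Q (zero at dt = 0).
Missing components are handled by selecting the observed sub-block; the
covariance update uses the Joseph form and is symmetrized every step.

All algebra is written as explicit 2x2 scalar arithmetic so the kernel
compiles to tight machine code; the pure-numpy joint-Gaussian oracle in
``state_space`` provides the independent cross-check.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
SINGULAR_INNOVATION = 1
NONFINITE = 2


@njit(cache=False)
def filter_smooth(t, y, starts, ends, a, A, Q, R, mu0, S0,
                  pm, pP, fm, fP, sm, sP, cross):
    """Run filter + RTS smoother over concatenated per-animal segments.

    t : (n,) times; y : (n, 2) observations, NaN = missing component.
    starts/ends : (n_seg,) segment boundaries (each segment one animal).
    Outputs written in place: predicted (pm, pP), filtered (fm, fP),
    smoothed (sm, sP) means/covariances and cross[i] = Cov(x_{i+1}, x_i)
    for i, i+1 in the same segment.

    Returns (loglik, status, bad_index).
    """
    LOG2PI = 1.8378770664093453
    ll = 0.0
    for s_i in range(starts.shape[0]):
        s = starts[s_i]
        e = ends[s_i]
        # ---------------- forward pass ----------------
        for i in range(s, e):
            if i == s:
                m0 = mu0[0]
                m1 = mu0[1]
                P00 = S0[0, 0]
                P01 = S0[0, 1]
                P11 = S0[1, 1]
            else:
                dt = t[i] - t[i - 1]
                F00 = 1.0 + A[0, 0] * dt
                F01 = A[0, 1] * dt
                F10 = A[1, 0] * dt
                F11 = 1.0 + A[1, 1] * dt
                x0 = fm[i - 1, 0]
                x1 = fm[i - 1, 1]
                m0 = F00 * x0 + F01 * x1 + a[0] * dt
                m1 = F10 * x0 + F11 * x1 + a[1] * dt
                q00 = fP[i - 1, 0, 0]
                q01 = fP[i - 1, 0, 1]
                q11 = fP[i - 1, 1, 1]
                # F P F^T + dt Q
                t00 = F00 * q00 + F01 * q01
                t01 = F00 * q01 + F01 * q11
                t10 = F10 * q00 + F11 * q01
                t11 = F10 * q01 + F11 * q11
                P00 = t00 * F00 + t01 * F01 + dt * Q[0, 0]
                P01 = t00 * F10 + t01 * F11 + dt * Q[0, 1]
                P11 = t10 * F10 + t11 * F11 + dt * Q[1, 1]
            pm[i, 0] = m0
            pm[i, 1] = m1
            pP[i, 0, 0] = P00
            pP[i, 0, 1] = P01
            pP[i, 1, 0] = P01
            pP[i, 1, 1] = P11
            if not (np.isfinite(m0) and np.isfinite(m1)
                    and np.isfinite(P00) and np.isfinite(P11)):
                return ll, NONFINITE, i

            o0 = not np.isnan(y[i, 0])
            o1 = not np.isnan(y[i, 1])
            if o0 and o1:
                S00 = P00 + R[0, 0]
                S01 = P01 + R[0, 1]
                S11 = P11 + R[1, 1]
                det = S00 * S11 - S01 * S01
                if det <= 0.0 or not np.isfinite(det):
                    return ll, SINGULAR_INNOVATION, i
                i00 = S11 / det
                i01 = -S01 / det
                i11 = S00 / det
                v0 = y[i, 0] - m0
                v1 = y[i, 1] - m1
                # K = P S^{-1}
                K00 = P00 * i00 + P01 * i01
                K01 = P00 * i01 + P01 * i11
                K10 = P01 * i00 + P11 * i01
                K11 = P01 * i01 + P11 * i11
                fm[i, 0] = m0 + K00 * v0 + K01 * v1
                fm[i, 1] = m1 + K10 * v0 + K11 * v1
                # Joseph: (I-K) P (I-K)^T + K R K^T
                a00 = 1.0 - K00
                a01 = -K01
                a10 = -K10
                a11 = 1.0 - K11
                t00 = a00 * P00 + a01 * P01
                t01 = a00 * P01 + a01 * P11
                t10 = a10 * P00 + a11 * P01
                t11 = a10 * P01 + a11 * P11
                c00 = t00 * a00 + t01 * a01
                c01 = t00 * a10 + t01 * a11
                c11 = t10 * a10 + t11 * a11
                r00 = K00 * R[0, 0] + K01 * R[0, 1]
                r01 = K00 * R[0, 1] + K01 * R[1, 1]
                r10 = K10 * R[0, 0] + K11 * R[0, 1]
                r11 = K10 * R[0, 1] + K11 * R[1, 1]
                c00 += r00 * K00 + r01 * K01
                c01 += r00 * K10 + r01 * K11
                c11 += r10 * K10 + r11 * K11
                fP[i, 0, 0] = c00
                fP[i, 0, 1] = c01
                fP[i, 1, 0] = c01
                fP[i, 1, 1] = c11
                quad = v0 * (i00 * v0 + i01 * v1) + v1 * (i01 * v0 + i11 * v1)
                ll += -0.5 * (2.0 * LOG2PI + np.log(det) + quad)
            elif o0 or o1:
                if o0:
                    j = 0
                else:
                    j = 1
                if j == 0:
                    Pjj = P00
                    Pc0 = P00
                    Pc1 = P01
                else:
                    Pjj = P11
                    Pc0 = P01
                    Pc1 = P11
                Svar = Pjj + R[j, j]
                if Svar <= 0.0 or not np.isfinite(Svar):
                    return ll, SINGULAR_INNOVATION, i
                k0 = Pc0 / Svar
                k1 = Pc1 / Svar
                v = y[i, j] - (m0 if j == 0 else m1)
                fm[i, 0] = m0 + k0 * v
                fm[i, 1] = m1 + k1 * v
                # (I - k e_j^T) P (I - k e_j^T)^T + R_jj k k^T
                if j == 0:
                    a00 = 1.0 - k0
                    a01 = 0.0
                    a10 = -k1
                    a11 = 1.0
                else:
                    a00 = 1.0
                    a01 = -k0
                    a10 = 0.0
                    a11 = 1.0 - k1
                t00 = a00 * P00 + a01 * P01
                t01 = a00 * P01 + a01 * P11
                t10 = a10 * P00 + a11 * P01
                t11 = a10 * P01 + a11 * P11
                c00 = t00 * a00 + t01 * a01
                c01 = t00 * a10 + t01 * a11
                c11 = t10 * a10 + t11 * a11
                rjj = R[j, j]
                c00 += rjj * k0 * k0
                c01 += rjj * k0 * k1
                c11 += rjj * k1 * k1
                fP[i, 0, 0] = c00
                fP[i, 0, 1] = c01
                fP[i, 1, 0] = c01
                fP[i, 1, 1] = c11
                ll += -0.5 * (LOG2PI + np.log(Svar) + v * v / Svar)
            else:
                # fully missing record: no update, likelihood unchanged
                fm[i, 0] = m0
                fm[i, 1] = m1
                fP[i, 0, 0] = P00
                fP[i, 0, 1] = P01
                fP[i, 1, 0] = P01
                fP[i, 1, 1] = P11

        # ---------------- backward (RTS) pass ----------------
        if e > s:
            sm[e - 1, 0] = fm[e - 1, 0]
            sm[e - 1, 1] = fm[e - 1, 1]
            sP[e - 1, 0, 0] = fP[e - 1, 0, 0]
            sP[e - 1, 0, 1] = fP[e - 1, 0, 1]
            sP[e - 1, 1, 0] = fP[e - 1, 0, 1]
            sP[e - 1, 1, 1] = fP[e - 1, 1, 1]
        for i in range(e - 2, s - 1, -1):
            dt = t[i + 1] - t[i]
            F00 = 1.0 + A[0, 0] * dt
            F01 = A[0, 1] * dt
            F10 = A[1, 0] * dt
            F11 = 1.0 + A[1, 1] * dt
            Pp00 = pP[i + 1, 0, 0]
            Pp01 = pP[i + 1, 0, 1]
            Pp11 = pP[i + 1, 1, 1]
            det = Pp00 * Pp11 - Pp01 * Pp01
            if det <= 0.0 or not np.isfinite(det):
                # near-singular predicted covariance: jitter the diagonal
                eps = 1e-10 * (abs(Pp00) + abs(Pp11) + 1.0)
                Pp00 += eps
                Pp11 += eps
                det = Pp00 * Pp11 - Pp01 * Pp01
            if det <= 0.0 or not np.isfinite(det):
                J00 = J01 = J10 = J11 = 0.0
            else:
                i00 = Pp11 / det
                i01 = -Pp01 / det
                i11 = Pp00 / det
                q00 = fP[i, 0, 0]
                q01 = fP[i, 0, 1]
                q11 = fP[i, 1, 1]
                # J = Pf F^T Ppred^{-1}
                b00 = q00 * F00 + q01 * F01
                b01 = q00 * F10 + q01 * F11
                b10 = q01 * F00 + q11 * F01
                b11 = q01 * F10 + q11 * F11
                J00 = b00 * i00 + b01 * i01
                J01 = b00 * i01 + b01 * i11
                J10 = b10 * i00 + b11 * i01
                J11 = b10 * i01 + b11 * i11
            dm0 = sm[i + 1, 0] - pm[i + 1, 0]
            dm1 = sm[i + 1, 1] - pm[i + 1, 1]
            sm[i, 0] = fm[i, 0] + J00 * dm0 + J01 * dm1
            sm[i, 1] = fm[i, 1] + J10 * dm0 + J11 * dm1
            d00 = sP[i + 1, 0, 0] - Pp00
            d01 = sP[i + 1, 0, 1] - Pp01
            d11 = sP[i + 1, 1, 1] - Pp11
            t00 = J00 * d00 + J01 * d01
            t01 = J00 * d01 + J01 * d11
            t10 = J10 * d00 + J11 * d01
            t11 = J10 * d01 + J11 * d11
            c00 = fP[i, 0, 0] + t00 * J00 + t01 * J01
            c01 = fP[i, 0, 1] + t00 * J10 + t01 * J11
            c11 = fP[i, 1, 1] + t10 * J10 + t11 * J11
            sP[i, 0, 0] = c00
            sP[i, 0, 1] = c01
            sP[i, 1, 0] = c01
            sP[i, 1, 1] = c11
            # Cov(x_{i+1}, x_i | all data) = Ps_{i+1} J^T
            s00 = sP[i + 1, 0, 0]
            s01 = sP[i + 1, 0, 1]
            s11 = sP[i + 1, 1, 1]
            cross[i, 0, 0] = s00 * J00 + s01 * J01
            cross[i, 0, 1] = s00 * J10 + s01 * J11
            cross[i, 1, 0] = s01 * J00 + s11 * J01
            cross[i, 1, 1] = s01 * J10 + s11 * J11
    return ll, OK, -1
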