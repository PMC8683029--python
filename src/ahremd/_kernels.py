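"""Hot-loop propagation kernels for the 1D single-particle systems.

Long campaigns on the 1D toy systems are dominated by per-step numpy call
overhead, so the BAOAB step with the Gaussian-mixture ladder bias is also
provided as a scalar-loop kernel compiled with numba when available.  The
numpy fallback performs the same arithmetic, so either path is deterministic
given the pre-drawn noise block.

Potential kinds: 0 = quartic double well (p1 = barrier h, p2 = a^2),
1 = harmonic (p1 = k, p2 = center).  The mixture parameters are the
concatenated components of all CV models (the bias sums over CVs), with
``amps`` = weight / (sigma * sqrt(2 pi)); the bias force on x is
prefactor * sum_m amps_m exp(-z^2/2) (z/sigma_m) * sign(x), z = (|x|-mu_m)/sigma_m.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - presence depends on the environment
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False

__all__ = ["HAVE_NUMBA", "ladder_block"]


def _force_py(x, pot_kind, p1, p2, prefs, mus, sigs, amps):
    if pot_kind == 0:
        f = -4.0 * p1 * x * (x * x / p2 - 1.0) / p2
    else:
        f = -p1 * (x - p2)
    if len(mus):
        d = np.abs(x)
        fb = 0.0
        for m in range(len(mus)):
            z = (d - mus[m]) / sigs[m]
            fb = fb + amps[m] * np.exp(-0.5 * z * z) * (z / sigs[m])
        f = f + prefs * fb * np.sign(x)
    return f


def _ladder_block_py(x, v, pot_kind, p1, p2, prefs, mus, sigs, amps,
                     a_coef, b_coef, dt, noise):
    """Vectorized fallback; x, v are flat (R,) arrays, mutated in place."""
    half = 0.5 * dt
    f = _force_py(x, pot_kind, p1, p2, prefs, mus, sigs, amps)
    for t in range(noise.shape[0]):
        v += half * f
        x += half * v
        v *= a_coef
        v += b_coef * noise[t]
        x += half * v
        f = _force_py(x, pot_kind, p1, p2, prefs, mus, sigs, amps)
        v += half * f


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _ladder_block_nb(x, v, pot_kind, p1, p2, prefs, mus, sigs, amps,
                         a_coef, b_coef, dt, noise):  # pragma: no cover
        R = x.shape[0]
        T = noise.shape[0]
        M = mus.shape[0]
        half = 0.5 * dt
        for r in range(R):
            xr = x[r]
            vr = v[r]
            pref = prefs[r]
            if pot_kind == 0:
                f = -4.0 * p1 * xr * (xr * xr / p2 - 1.0) / p2
            else:
                f = -p1 * (xr - p2)
            if M and pref != 0.0:
                d = abs(xr)
                s = 1.0 if xr > 0.0 else (-1.0 if xr < 0.0 else 0.0)
                fb = 0.0
                for m in range(M):
                    z = (d - mus[m]) / sigs[m]
                    fb += amps[m] * np.exp(-0.5 * z * z) * (z / sigs[m])
                f += pref * fb * s
            for t in range(T):
                vr += half * f
                xr += half * vr
                vr = a_coef * vr + b_coef * noise[t, r]
                xr += half * vr
                if pot_kind == 0:
                    f = -4.0 * p1 * xr * (xr * xr / p2 - 1.0) / p2
                else:
                    f = -p1 * (xr - p2)
                if M and pref != 0.0:
                    d = abs(xr)
                    s = 1.0 if xr > 0.0 else (-1.0 if xr < 0.0 else 0.0)
                    fb = 0.0
                    for m in range(M):
                        z = (d - mus[m]) / sigs[m]
                        fb += amps[m] * np.exp(-0.5 * z * z) * (z / sigs[m])
                    f += pref * fb * s
                vr += half * f
            x[r] = xr
            v[r] = vr


def ladder_block(x, v, pot_kind, p1, p2, prefs, mus, sigs, amps,
                 a_coef, b_coef, dt, noise):
    """Advance the flat replica stack by ``noise.shape[0]`` BAOAB steps."""
    fn = _ladder_block_nb if HAVE_NUMBA else _ladder_block_py
    fn(x, v, pot_kind, p1, p2, prefs, mus, sigs, amps, a_coef, b_coef, dt,
       noise)


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def em_univariate(x, w, mu, sig, floor, tol, max_iter):  # pragma: no cover
        """EM for a univariate GMM; w/mu/sig are updated in place.

        Returns (ll_path, n_iter, converged) with ll_path the mean
        log-likelihood before each M step (non-decreasing).
        """
        n = x.shape[0]
        K = w.shape[0]
        sqrt2pi = np.sqrt(2.0 * np.pi)
        ll_path = np.empty(max_iter)
        tmp = np.empty(K)
        ex = np.empty(K)
        nk = np.empty(K)
        sx = np.empty(K)
        sxx = np.empty(K)
        logc = np.empty(K)
        inv2v = np.empty(K)
        prev = -1e308
        converged = False
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            for k in range(K):
                nk[k] = 0.0
                sx[k] = 0.0
                sxx[k] = 0.0
                logc[k] = np.log(w[k] + 1e-300) - np.log(sig[k] * sqrt2pi)
                inv2v[k] = 0.5 / (sig[k] * sig[k])
            ll = 0.0
            for i in range(n):
                xi = x[i]
                mmax = -1e308
                for k in range(K):
                    d = xi - mu[k]
                    tmp[k] = logc[k] - d * d * inv2v[k]
                    if tmp[k] > mmax:
                        mmax = tmp[k]
                s = 0.0
                for k in range(K):
                    ex[k] = np.exp(tmp[k] - mmax)
                    s += ex[k]
                ll += mmax + np.log(s)
                inv_s = 1.0 / s
                for k in range(K):
                    r = ex[k] * inv_s
                    nk[k] += r
                    sx[k] += r * xi
                    sxx[k] += r * xi * xi
            ll /= n
            ll_path[it] = ll
            for k in range(K):
                w[k] = nk[k] / n
                if nk[k] > 1e-300:
                    mu[k] = sx[k] / nk[k]
                    var = sxx[k] / nk[k] - mu[k] * mu[k]
                else:
                    var = 0.0
                if var < floor * floor:
                    sig[k] = floor
                else:
                    sig[k] = np.sqrt(var)
            if prev > -1e307 and abs(ll - prev) <= tol * max(abs(prev), 1e-12):
                converged = True
                break
            prev = ll
        return ll_path[:n_iter], n_iter, converged

else:
    em_univariate = None
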