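"""Batched nonlinear least-squares peak fitting.

All quantification in this package reduces to fitting one of four line-shape
models plus a linear baseline over a ppm window:

* ``lorentzian``          -- A / (1 + u^2),            u = (x - f0) / gamma
* ``gaussian``            -- A exp(-u^2 / 2),          u = (x - f0) / sigma
* ``double_gaussian``     -- two Gaussians with a shared width
* ``inverse_lorentzian``  -- a negative Lorentzian lobe, reported as a
  positive magnitude (used for the edited negative tNAA control signal)

plus a complex reference model (absorption + dispersion Lorentzian with a
zero-order phase) used for per-transient creatine fitting.

The pipelines fit tens of thousands of such problems per cohort, so the
solver is a Levenberg--Marquardt iteration vectorised over a batch axis:
every problem in a batch shares the x grid, and each iteration solves all
(P x P) normal-equation systems at once.  Analytic Jacobians are supplied by
each model.  Closed-form areas and widths:

* Lorentzian  area = pi * A * gamma,  FWHM = 2 * gamma
* Gaussian    area = A * sigma * sqrt(2 pi),  FWHM = 2 * sigma * sqrt(2 ln 2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "lorentzian_absorption",
    "lorentzian_dispersion",
    "gaussian_absorption",
    "lorentzian_area",
    "gaussian_area",
    "lorentzian_fwhm",
    "gaussian_fwhm",
    "batched_lm",
    "SinglePeakModel",
    "DoubleGaussianModel",
    "ComplexLorentzianModel",
]

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ----------------------------------------------------------------- shapes

def lorentzian_absorption(x, f0, gamma):
    u = (np.asarray(x) - f0) / gamma
    return 1.0 / (1.0 + u * u)


def lorentzian_dispersion(x, f0, gamma):
    u = (np.asarray(x) - f0) / gamma
    return u / (1.0 + u * u)


def gaussian_absorption(x, f0, sigma):
    u = (np.asarray(x) - f0) / sigma
    return np.exp(-0.5 * u * u)


def lorentzian_area(amplitude, gamma):
    """Analytic area of A / (1 + ((x-f0)/gamma)^2): pi * A * gamma."""
    return np.pi * amplitude * gamma


def gaussian_area(amplitude, sigma):
    """Analytic area of A exp(-(x-f0)^2 / (2 sigma^2)): A sigma sqrt(2 pi)."""
    return amplitude * sigma * np.sqrt(2.0 * np.pi)


def lorentzian_fwhm(gamma):
    return 2.0 * gamma


def gaussian_fwhm(sigma):
    return GAUSS_FWHM_FACTOR * sigma


# ----------------------------------------------------------------- solver

def batched_lm(model, x, y, p0, max_iter=60, tol=1e-8, lam0=1e-3):
    """Levenberg--Marquardt over a batch of problems sharing one x grid.

    Problems that converge drop out of the iteration (active-set), so a few
    hard stragglers do not multiply the cost of the whole batch.

    Parameters
    ----------
    model
        Object with ``eval_jac(x, params) -> (m, J)`` where ``m`` has shape
        (B, M) and ``J`` (B, M, P), and ``project(params) -> params`` that
        maps parameters back into their valid domain (e.g. positive widths).
    x : (M,) array
    y : (B, M) array
        Data in residual space (real; complex models stack re/im).
    p0 : (B, P) array
        Initial parameters.

    Returns
    -------
    params : (B, P), cost : (B,), converged : (B,) bool
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p_all = np.array(p0, dtype=np.float64)
    B, P = p_all.shape
    eye = np.eye(P)

    cost_all = np.empty(B)
    converged_all = np.zeros(B, dtype=bool)

    active = np.arange(B)
    p = p_all.copy()
    m, J = model.eval_jac(x, p)
    r = y - m
    cost = np.einsum("bm,bm->b", r, r)
    lam = np.full(B, lam0)
    ya = y

    for _ in range(max_iter):
        Jt = J.transpose(0, 2, 1)
        JTJ = Jt @ J
        JTr = (Jt @ r[:, :, None])[:, :, 0]
        diag = np.einsum("bpp->bp", JTJ)
        damp = np.maximum(diag, 1e-12)
        A = JTJ + lam[:, None, None] * (damp[:, :, None] * eye)
        try:
            delta = np.linalg.solve(A, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("bpq,bq->bp", np.linalg.pinv(A), JTr)
        bad = ~np.isfinite(delta).all(axis=1)
        if bad.any():
            delta[bad] = 0.0

        p_trial = model.project(p + delta)
        m_t, J_t = model.eval_jac(x, p_trial)
        r_t = ya - m_t
        cost_t = np.einsum("bm,bm->b", r_t, r_t)
        improved = (cost_t <= cost) & np.isfinite(cost_t)

        step = np.max(np.abs(delta) / (1.0 + np.abs(p)), axis=1)
        dcost = cost - cost_t
        done = improved & (
            (step < tol) | (dcost <= 1e-12 * (cost + 1e-300))
        )

        upd = improved[:, None]
        p = np.where(upd, p_trial, p)
        r = np.where(upd, r_t, r)
        J = np.where(upd[:, :, None], J_t, J)
        cost = np.where(improved, cost_t, cost)
        lam = np.clip(np.where(improved, lam * 0.3, lam * 4.0), 1e-12, 1e8)

        if done.any():
            idx = active[done]
            p_all[idx] = p[done]
            cost_all[idx] = cost[done]
            converged_all[idx] = True
            keep = ~done
            if not keep.any():
                active = active[:0]
                break
            active = active[keep]
            if hasattr(model, "take"):
                model.take(keep)
            p = p[keep]
            r = r[keep]
            J = J[keep]
            cost = cost[keep]
            lam = lam[keep]
            ya = ya[keep]

    if active.size:
        p_all[active] = p
        cost_all[active] = cost

    return p_all, cost_all, converged_all


def _batched_lstsq(phi: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve min ||phi c - y|| for each batch item; phi (B, M, K), y (B, M)."""
    pt = phi.transpose(0, 2, 1)
    g = pt @ phi
    rhs = (pt @ y[:, :, None])[:, :, 0]
    k = g.shape[-1]
    scale = np.maximum(np.einsum("bkk->bk", g).max(axis=-1), 1e-30)
    g = g + (1e-10 * scale)[:, None, None] * np.eye(k)
    try:
        return np.linalg.solve(g, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.einsum("bkq,bq->bk", np.linalg.pinv(g), rhs)


def _linear_baseline_guess(x, y):
    """Rough per-problem baseline from the window edges; y is (B, M)."""
    k = max(3, len(x) // 12)
    y0 = y[:, :k].mean(axis=1)
    y1 = y[:, -k:].mean(axis=1)
    x0 = x[:k].mean()
    x1 = x[-k:].mean()
    slope = (y1 - y0) / (x1 - x0)
    xc = 0.5 * (x[0] + x[-1])
    intercept = 0.5 * (y0 + y1) + slope * (xc - 0.5 * (x0 + x1))
    return intercept, slope, xc


# ----------------------------------------------------------------- models

@dataclass
class SinglePeakModel:
    """One absorption peak (Lorentzian or Gaussian) + linear baseline.

    Parameters are ``[A, f0, w, b0, b1, c_1..c_K]``; the model is
    ``sign * A * shape((x - f0)/w) + b0 + b1 * (x - xc) + sum_k c_k N_k(x)``
    with ``xc`` the window centre (for conditioning) and ``N_k`` optional
    fixed nuisance bases (shape (B, M, K)).  ``sign=-1`` fits a negative
    lobe whose magnitude A stays positive (inverse Lorentzian).  Nuisance
    bases are used to absorb subtraction artifacts of known shape (e.g.
    residual creatine in edited difference spectra) that would otherwise
    bias the peak parameters.
    """

    shape: str  # "lorentzian" | "gaussian"
    sign: float = 1.0
    xc: float = 0.0
    nuisance: object = None  # (B, M, K) fixed bases or None

    @property
    def n_nuisance(self) -> int:
        return 0 if self.nuisance is None else self.nuisance.shape[2]

    def eval_jac(self, x, p):
        A, f0, w, b0, b1 = (p[:, i:i + 1] for i in range(5))
        u = (x[None, :] - f0) / w
        if self.shape == "lorentzian":
            s = 1.0 / (1.0 + u * u)
            ds_du = -2.0 * u * s * s
        elif self.shape == "gaussian":
            s = np.exp(-0.5 * u * u)
            ds_du = -u * s
        else:  # pragma: no cover
            raise ValueError(f"unknown shape {self.shape!r}")
        xb = x[None, :] - self.xc
        m = self.sign * A * s + b0 + b1 * xb
        K = self.n_nuisance
        J = np.empty(p.shape[:1] + x.shape + (5 + K,))
        J[..., 0] = self.sign * s
        J[..., 1] = self.sign * A * ds_du * (-1.0 / w)
        J[..., 2] = self.sign * A * ds_du * (-u / w)
        J[..., 3] = 1.0
        J[..., 4] = xb
        if K:
            nb = self.nuisance
            m = m + np.einsum("bmk,bk->bm", nb, p[:, 5:])
            J[..., 5:] = nb
        return m, J

    def project(self, p):
        p = p.copy()
        p[:, 2] = np.abs(p[:, 2])
        np.clip(p[:, 2], 1e-6, None, out=p[:, 2])
        return p

    def take(self, keep):
        """Keep only the given batch rows (active-set support)."""
        if self.nuisance is not None:
            self.nuisance = self.nuisance[keep]

    def guess(self, x, y, f0_init=None, w_init=0.03):
        B = y.shape[0]
        b0, b1, xc = _linear_baseline_guess(x, y)
        self.xc = xc
        resid = self.sign * (y - b0[:, None] - b1[:, None] * (x[None, :] - xc))
        imax = np.argmax(resid, axis=1)
        f0 = x[imax] if f0_init is None else np.full(B, f0_init)
        # exact linear solve for amplitude + baseline (+ nuisance) at the
        # initial (f0, w)
        u = (x[None, :] - f0[:, None]) / w_init
        if self.shape == "lorentzian":
            s = 1.0 / (1.0 + u * u)
        else:
            s = np.exp(-0.5 * u * u)
        cols = [
            self.sign * s,
            np.ones_like(s),
            np.broadcast_to(x - xc, s.shape),
        ]
        phi = np.concatenate(
            [np.stack(cols, axis=2)]
            + ([self.nuisance] if self.nuisance is not None else []),
            axis=2,
        )
        c = _batched_lstsq(phi, y)
        K = self.n_nuisance
        p0 = np.empty((B, 5 + K))
        p0[:, 0] = np.maximum(c[:, 0], 1e-6)
        p0[:, 1] = f0
        p0[:, 2] = w_init
        p0[:, 3] = c[:, 1]
        p0[:, 4] = c[:, 2]
        if K:
            p0[:, 5:] = c[:, 3:]
        return p0


@dataclass
class DoubleGaussianModel:
    """Two Gaussians with shared width + linear baseline.

    Parameters ``[A1, A2, f1, f2, sigma, b0, b1]``.  Used for the edited Glx
    multiplet near 3.75 ppm, whose sub-peaks are unresolved at 3 T.
    """

    xc: float = 0.0

    n_params = 7

    def eval_jac(self, x, p):
        A1, A2, f1, f2, s, b0, b1 = (p[:, i:i + 1] for i in range(7))
        u1 = (x[None, :] - f1) / s
        u2 = (x[None, :] - f2) / s
        g1 = np.exp(-0.5 * u1 * u1)
        g2 = np.exp(-0.5 * u2 * u2)
        xb = x[None, :] - self.xc
        m = A1 * g1 + A2 * g2 + b0 + b1 * xb
        J = np.empty(p.shape[:1] + x.shape + (7,))
        J[..., 0] = g1
        J[..., 1] = g2
        J[..., 2] = A1 * g1 * u1 / s
        J[..., 3] = A2 * g2 * u2 / s
        J[..., 4] = (A1 * g1 * u1 * u1 + A2 * g2 * u2 * u2) / s
        J[..., 5] = 1.0
        J[..., 6] = xb
        return m, J

    def project(self, p):
        p = p.copy()
        p[:, 4] = np.abs(p[:, 4])
        np.clip(p[:, 4], 1e-6, None, out=p[:, 4])
        # keep the sub-peaks ordered (f1 < f2) to avoid label swapping
        swap = p[:, 2] > p[:, 3]
        if swap.any():
            p[swap, 2], p[swap, 3] = p[swap, 3].copy(), p[swap, 2].copy()
            p[swap, 0], p[swap, 1] = p[swap, 1].copy(), p[swap, 0].copy()
        return p

    def guess(self, x, y, centers=(3.71, 3.79), w_init=0.05):
        B = y.shape[0]
        _, _, xc = _linear_baseline_guess(x, y)
        self.xc = xc
        u1 = (x[None, :] - centers[0]) / w_init
        u2 = (x[None, :] - centers[1]) / w_init
        g1 = np.exp(-0.5 * u1 * u1)
        g2 = np.exp(-0.5 * u2 * u2)
        ones = np.ones((1, len(x)))
        xb = (x - xc)[None, :]
        phi = np.broadcast_to(
            np.stack([g1, g2, ones, xb], axis=2), (B, len(x), 4)
        )
        c = _batched_lstsq(np.ascontiguousarray(phi), y)
        p0 = np.empty((B, 7))
        p0[:, 0] = np.maximum(c[:, 0], 1e-6)
        p0[:, 1] = np.maximum(c[:, 1], 1e-6)
        p0[:, 2] = centers[0]
        p0[:, 3] = centers[1]
        p0[:, 4] = w_init
        p0[:, 5] = c[:, 2]
        p0[:, 6] = c[:, 3]
        return p0


@dataclass
class ComplexLorentzianModel:
    """Complex Lorentzian (absorption + i dispersion) with zero-order phase.

    Parameters ``[A, f0, gamma, phi, r0, r1, i0, i1]``; the model is::

        m(x) = A exp(i phi) (Labs + i Ldisp) + (r0 + r1 xb) + i (i0 + i1 xb)

    and the residual space stacks [Re, Im], so the data passed to the solver
    must be ``np.concatenate([spec.real, spec.imag], axis=1)``.  Used for the
    per-transient creatine reference fit that drives frequency/phase
    correction.
    """

    xc: float = 0.0

    n_params = 8

    def eval_jac(self, x, p):
        A, f0, g, phi, r0, r1, i0, i1 = (p[:, i:i + 1] for i in range(8))
        u = (x[None, :] - f0) / g
        den = 1.0 / (1.0 + u * u)
        labs = den
        ldisp = u * den
        dlabs_du = -2.0 * u * den * den
        dldisp_du = (1.0 - u * u) * den * den
        cos, sin = np.cos(phi), np.sin(phi)
        # complex peak rotated by phi, split into channels
        pk_re = labs * cos - ldisp * sin
        pk_im = labs * sin + ldisp * cos
        dpk_re_du = dlabs_du * cos - dldisp_du * sin
        dpk_im_du = dlabs_du * sin + dldisp_du * cos
        xb = x[None, :] - self.xc
        m_re = A * pk_re + r0 + r1 * xb
        m_im = A * pk_im + i0 + i1 * xb
        B, M = m_re.shape
        m = np.concatenate([m_re, m_im], axis=1)
        J = np.zeros((B, 2 * M, 8))
        du_df0 = -1.0 / g
        du_dg = -u / g
        J[:, :M, 0] = pk_re
        J[:, M:, 0] = pk_im
        J[:, :M, 1] = A * dpk_re_du * du_df0
        J[:, M:, 1] = A * dpk_im_du * du_df0
        J[:, :M, 2] = A * dpk_re_du * du_dg
        J[:, M:, 2] = A * dpk_im_du * du_dg
        J[:, :M, 3] = -A * pk_im
        J[:, M:, 3] = A * pk_re
        J[:, :M, 4] = 1.0
        J[:, :M, 5] = xb
        J[:, M:, 6] = 1.0
        J[:, M:, 7] = xb
        return m, J

    def project(self, p):
        p = p.copy()
        p[:, 2] = np.abs(p[:, 2])
        np.clip(p[:, 2], 1e-6, None, out=p[:, 2])
        # fold negative amplitudes into the phase
        neg = p[:, 0] < 0
        if neg.any():
            p[neg, 0] = -p[neg, 0]
            p[neg, 3] += np.pi
        # wrap phase to (-pi, pi]
        p[:, 3] = np.angle(np.exp(1j * p[:, 3]))
        return p

    def guess(self, x, spec, w_init=0.0333):
        """Initial parameters from a batch of complex windows (B, M).

        The centre comes from the magnitude maximum; the complex amplitude
        and baselines are then solved exactly by linear least squares at the
        initial (f0, gamma), so the nonlinear iteration starts close.
        """
        B, M = spec.shape
        mag = np.abs(spec)
        imax = np.argmax(mag, axis=1)
        f0 = x[imax]
        self.xc = 0.5 * (x[0] + x[-1])
        u = (x[None, :] - f0[:, None]) / w_init
        den = 1.0 / (1.0 + u * u)
        labs = den
        ldisp = u * den
        xb = np.broadcast_to(x - self.xc, (B, M))
        zeros = np.zeros((B, M))
        ones = np.ones((B, M))
        # columns: Re/Im stacked for [a, b, r0, r1, i0, i1] where the complex
        # peak amplitude is a + i b
        phi = np.stack(
            [
                np.concatenate([labs, ldisp], axis=1),
                np.concatenate([-ldisp, labs], axis=1),
                np.concatenate([ones, zeros], axis=1),
                np.concatenate([xb, zeros], axis=1),
                np.concatenate([zeros, ones], axis=1),
                np.concatenate([zeros, xb], axis=1),
            ],
            axis=2,
        )
        y = np.concatenate([spec.real, spec.imag], axis=1)
        c = _batched_lstsq(phi, y)
        p0 = np.zeros((B, 8))
        p0[:, 0] = np.hypot(c[:, 0], c[:, 1])
        p0[:, 1] = f0
        p0[:, 2] = w_init
        p0[:, 3] = np.arctan2(c[:, 1], c[:, 0])
        p0[:, 4:8] = c[:, 2:6]
        return p0
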