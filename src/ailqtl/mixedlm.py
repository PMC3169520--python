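"""Maximum-likelihood linear mixed model with family-structured variance components.

The scan model's random part is four mutually independent variance
components — family, family x sex, family x diet, family x sex x diet —
plus residual noise.  Writing gamma_k = sigma_k^2 / sigma_e^2, the marginal
covariance is

    Cov(y) = sigma_e^2 * ( I + sum_k gamma_k Z_k Z_k' )

which is block diagonal by family: within a family of size m the block is
I + g1*J + g2*S + g3*D + g4*C, where J is all-ones and S, D, C indicate
shared sex, shared diet and shared sex-by-diet cell.  Both the fixed
coefficients and sigma_e^2 profile out analytically, so the likelihood is
optimized over the four non-negative ratios only.  Families of equal size
are batched, making a single fit fast enough for genome scans with
thousands of positions (each position refits all variance components, as
the likelihood-ratio test contrasts fixed effects under full ML).

A full scan needs tens of thousands of these fits; statsmodels' MixedLM
fits the identical model and is used as an independent cross-check in the
test suite rather than as the scan engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VCFit:
    """One fitted model: profiled-ML estimates and likelihood."""

    loglik: float
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    gamma: np.ndarray  # variance ratios (family, fam_sex, fam_diet, fam_sex_diet)
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    @property
    def variance_components(self) -> np.ndarray:
        """Absolute variances (4 components, then residual)."""
        return np.append(self.gamma * self.sigma2, self.sigma2)


class FamilyVarianceModel:
    """Precomputed family/cohort structure for repeated ML fits.

    Parameters are per-animal family, sex and diet labels (any hashables).
    The row order given here is the row order expected by :meth:`fit`.
    """

    N_COMPONENTS = 4
    COMPONENT_NAMES = ("family", "family_sex", "family_diet", "family_sex_diet")

    def __init__(self, family, sex, diet):
        family = np.asarray(family)
        sex = np.asarray(sex)
        diet = np.asarray(diet)
        self.n = len(family)
        if not (len(sex) == len(diet) == self.n):
            raise ValueError("family/sex/diet lengths differ")
        fam_codes = _codes(family)
        if len(np.unique(fam_codes)) < 2:
            raise ValueError("need >= 2 families to separate family variance")
        order = np.argsort(fam_codes, kind="stable")
        self.order = order
        f = fam_codes[order]
        s = _codes(sex)[order]
        d = _codes(diet)[order]
        # family boundaries in the sorted order
        starts = np.flatnonzero(np.r_[True, f[1:] != f[:-1]])
        ends = np.r_[starts[1:], len(f)]
        sizes = ends - starts
        self.groups = []  # (row_slices, K) per distinct family size
        for m in np.unique(sizes):
            which = np.flatnonzero(sizes == m)
            rows = np.concatenate([np.arange(starts[i], ends[i]) for i in which])
            nf = len(which)
            ss = s[rows].reshape(nf, m)
            dd = d[rows].reshape(nf, m)
            k = np.empty((nf, self.N_COMPONENTS, m, m))
            k[:, 0] = 1.0
            k[:, 1] = (ss[:, :, None] == ss[:, None, :]).astype(float)
            k[:, 2] = (dd[:, :, None] == dd[:, None, :]).astype(float)
            k[:, 3] = k[:, 1] * k[:, 2]
            eye = np.eye(m)
            self.groups.append((rows, int(m), k, eye))

    # -- likelihood -------------------------------------------------------

    def _prepare(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or len(X) != self.n or len(y) != self.n:
            raise ValueError("X must be (n, p) and y (n,) matching the model rows")
        Xo, yo = X[self.order], y[self.order]
        parts = []
        for rows, m, k, eye in self.groups:
            nf = len(rows) // m
            b = np.concatenate([Xo[rows].reshape(nf, m, -1),
                                yo[rows].reshape(nf, m, 1)], axis=2)
            parts.append((b, k, eye))
        return parts, X.shape[1]

    def _profiled(self, gamma: np.ndarray, parts, p: int):
        """Profiled quantities at fixed variance ratios.

        Returns (nll, beta, XtViX_inv, sigma2); nll is -loglik.
        """
        pp = p + 1
        gram = np.zeros((pp, pp))
        logdet = 0.0
        for b, k, eye in parts:
            v = eye + np.einsum("k,fkij->fij", gamma, k)
            try:
                cf = np.linalg.cholesky(v)
            except np.linalg.LinAlgError:
                return np.inf, None, None, None
            logdet += 2.0 * float(np.log(np.einsum("fii->fi", cf)).sum())
            w = np.linalg.solve(v, b)
            gram += np.einsum("fmp,fmq->pq", b, w)
        xtvix = gram[:p, :p]
        xtviy = gram[:p, p]
        ytviy = gram[p, p]
        try:
            c = np.linalg.cholesky(xtvix)
        except np.linalg.LinAlgError:
            # rank-deficient fixed design: least-squares fallback
            beta, *_ = np.linalg.lstsq(xtvix, xtviy, rcond=None)
            xtvix_inv = np.linalg.pinv(xtvix)
        else:
            beta = np.linalg.solve(xtvix, xtviy)
            xtvix_inv = np.linalg.inv(xtvix)
        rss = max(float(ytviy - xtviy @ beta), 1e-300)
        sigma2 = rss / self.n
        nll = 0.5 * (self.n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
        return nll, beta, xtvix_inv, sigma2

    def nll(self, gamma, X, y) -> float:
        """-loglik at fixed variance ratios (for diagnostics and tests)."""
        parts, p = self._prepare(X, y)
        return self._profiled(np.asarray(gamma, float), parts, p)[0]

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, start: np.ndarray | None = None,
            gamma: np.ndarray | None = None, extra_starts: int = 0) -> VCFit:
        """ML fit.  ``gamma`` fixes the ratios (GLS at known structure);
        otherwise they are estimated from ``start`` (default 0.1 each).
        ``extra_starts`` adds perturbed restarts for hard likelihoods."""
        parts, p = self._prepare(X, y)
        if gamma is not None:
            g = np.asarray(gamma, float)
            nll, beta, xtvix_inv, sigma2 = self._profiled(g, parts, p)
            return VCFit(-nll, beta, sigma2 * xtvix_inv, sigma2, g, True)

        def objective(g):
            return self._profiled(g, parts, p)[0]

        starts = [np.full(self.N_COMPONENTS, 0.1) if start is None
                  else np.clip(np.asarray(start, float), 0.0, None)]
        rng = np.random.default_rng(0)
        for _ in range(extra_starts):
            starts.append(rng.uniform(0.0, 1.0, self.N_COMPONENTS))
        best = None
        for g0 in starts:
            res = optimize.minimize(
                objective, g0, method="L-BFGS-B",
                bounds=[(0.0, 1e4)] * self.N_COMPONENTS,
                options={"maxiter": 200, "eps": 1e-6, "ftol": 1e-11},
            )
            if best is None or res.fun < best.fun:
                best = res
        # the optimizer never returns a point worse than its start, so a fit
        # warm-started at a nested model's gamma-hat cannot lose likelihood
        nll, beta, xtvix_inv, sigma2 = self._profiled(best.x, parts, p)
        return VCFit(-nll, beta, sigma2 * xtvix_inv, sigma2, best.x,
                     bool(best.success))


def _codes(values) -> np.ndarray:
    uniq, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes


def lr_chisq(full: VCFit, null: VCFit) -> float:
    """Likelihood-ratio chi-square, clamped at 0 against numerical noise."""
    return max(2.0 * (full.loglik - null.loglik), 0.0)
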