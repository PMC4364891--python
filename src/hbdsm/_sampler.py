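"""Adaptive Metropolis-within-Gibbs sampler for the joint hierarchical model.

One `_Chain` samples the joint posterior of the observational process
(half-normal distances with log-linear strip widths, group sizes), the
trackline detection probability g(0), and the ecological process (Poisson
group counts with a log-polynomial habitat response), including the three
normal random-effect vectors (per-sighting eps0, per-cell eps1 and eps2) and
their standard deviations.

Proposal machinery:

* coefficient blocks (alpha; omega; theta) use multivariate normal proposals
  whose covariance is adapted Haario-style from the chain history during
  burn-in, with a Robbins-Monro global scale targeting ~28% acceptance;
* positive / bounded scalars (lambda_s, sigmas, g0, vartheta) use random-walk
  proposals on log / logit scales with the appropriate Jacobian, scale
  adapted toward ~44% acceptance;
* random-effect vectors are updated with element-wise independent random-walk
  proposals accepted in parallel (each element's likelihood term is local).

All adaptation is frozen at the end of burn-in, so the retained draws come
from a fixed, valid Markov kernel.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .detection import WHALE_LIKE

_LOG2 = np.log(2.0)
_LOG2PI = np.log(2.0 * np.pi)

_TARGET_SCALAR = 0.44
_TARGET_BLOCK = 0.28


class _AdaptiveScalar:
    """Robbins-Monro step-size adaptation for a scalar random-walk proposal."""

    def __init__(self, scale: float):
        self.log_scale = np.log(scale)
        self.t = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def adapt(self, accepted: float, target: float) -> None:
        self.t += 1
        self.log_scale += min(0.25, 2.0 * self.t ** -0.6) * (accepted - target)


class _AdaptiveBlock:
    """Haario-style adaptive multivariate normal proposal."""

    def __init__(self, dim: int, init_scale: float):
        self.dim = dim
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self.chol = np.eye(dim) * init_scale
        self.tuner = _AdaptiveScalar(1.0)

    def record(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)

    def refresh(self) -> None:
        if self.count < 50:
            return
        cov = self.m2 / (self.count - 1)
        cov = (2.38 ** 2 / self.dim) * (cov + 1e-10 * np.eye(self.dim))
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            pass

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return x + self.tuner.scale * (self.chol @ rng.standard_normal(self.dim))


class _Chain:
    """A single MCMC chain over the joint model, with cached likelihood parts."""

    def __init__(self, data: dict, spec: dict, seed_seq: np.random.SeedSequence):
        self.rng = np.random.default_rng(seed_seq)
        self.d = data
        self.spec = spec
        self.form = spec["species_form"]
        self.hform = spec["habitat_form"]
        self.priors = spec["priors"]
        self.sigma_e1_fixed = spec.get("sigma_e1_fixed")
        self.sigma_e2_fixed = spec.get("sigma_e2_fixed")
        self.ns = len(data["x"])
        self.nc = len(data["L"])
        self._precompute()
        self._init_state()
        self._init_proposals()
        self._refresh_all()

    # -- setup ---------------------------------------------------------------

    def _precompute(self) -> None:
        d = self.d
        self.log_L = np.log(d["L"])
        self.gammaln_n = special.gammaln(d["n"] + 1.0)
        self.sqrt_n = np.sqrt(d["n"])
        s = d["s"]
        if self.form == WHALE_LIKE:
            self.sum_s = float(np.sum(s))
            self.sum_gammaln_s = float(np.sum(special.gammaln(s + 1.0)))
        else:
            ls = np.log(s)
            self.sum_log_s = float(np.sum(ls))
            self.sum_ls = float(np.sum(ls))
            self.sum_ls2 = float(np.sum(ls ** 2))
        # sighting-level design matrix for log w_j
        self.X_s = np.column_stack([np.ones(self.ns), d["b"], d["scov"]])

    def _init_state(self) -> None:
        d, rng = self.d, self.rng
        jit = lambda sd: rng.normal(0.0, sd)
        sigma_hat = float(np.sqrt(np.mean(d["x"] ** 2))) or 0.1
        w_hat = sigma_hat * np.sqrt(np.pi / 2.0)
        self.alpha = np.array([np.log(w_hat) + jit(0.1), jit(0.02), jit(0.02)])
        if self.form == WHALE_LIKE:
            self.lam_s = max(float(np.mean(d["s"])) * np.exp(jit(0.05)), 0.1)
        else:
            ls = np.log(d["s"])
            self.mu_s = float(np.mean(ls)) + jit(0.05)
            self.sig_s = max(float(np.std(ls)), 0.05) * np.exp(jit(0.05))
        g0p = self.priors["g0"]
        self.g0 = float(np.clip(g0p.mean + jit(0.5 * g0p.sd), 1e-4, 1.0 - 1e-4))
        self.sig_e0 = 0.2 * np.exp(jit(0.2))
        if self.sigma_e1_fixed is not None:
            self.sig_e1 = max(float(self.sigma_e1_fixed), 1e-9)
        else:
            self.sig_e1 = 0.1 * np.exp(jit(0.2))
        if self.sigma_e2_fixed is not None:
            self.sig_e2 = max(float(self.sigma_e2_fixed), 1e-9)
        else:
            self.sig_e2 = 0.3 * np.exp(jit(0.2))
        self.eps0 = np.zeros(self.ns)
        self.eps1 = np.zeros(self.nc)
        self.eps2 = np.zeros(self.nc)
        # crude density intercept from the total count
        w_cells = np.exp(self.alpha[0] + self.alpha[1] * d["B"]
                         + self.alpha[2] * self._cov_mean())
        denom = np.sum(2.0 * w_cells * d["L"] * self.g0 / self._mean_size())
        rate = max(float(np.sum(d["n"])), 0.5) / max(denom, 1e-12)
        ic = np.log(rate)
        self.omega = np.array([ic + jit(0.1), jit(0.5), -1.0 + jit(0.5)])
        self.theta = np.array([ic + jit(0.1), jit(0.5), -1.0 + jit(0.5), jit(0.5)])
        self.vartheta = float(np.clip(0.5 + jit(0.05), 0.01, 0.99))

    def _init_proposals(self) -> None:
        self.p_alpha = _AdaptiveBlock(3, 0.02)
        self.p_omega = _AdaptiveBlock(3, 0.05)
        self.p_theta = _AdaptiveBlock(4, 0.05)
        self.p_gs = _AdaptiveScalar(0.05)
        self.p_gs2 = _AdaptiveScalar(0.05)
        self.p_g0 = _AdaptiveScalar(0.2)
        self.p_vt = _AdaptiveScalar(0.5)
        self.p_sig = {k: _AdaptiveScalar(0.2) for k in ("e0", "e1", "e2")}
        self.p_eps0 = _AdaptiveScalar(0.3)
        self.p_eps1 = _AdaptiveScalar(0.3)
        self.p_eps2 = _AdaptiveScalar(0.3)
        self.adapting = True

    # -- model pieces --------------------------------------------------------

    def _cov_mean(self, lam_s=None, mu_s=None, sig_s=None) -> float:
        """Mean group size on the detection-covariate scale."""
        if self.form == WHALE_LIKE:
            return float(self.lam_s if lam_s is None else lam_s)
        mu = self.mu_s if mu_s is None else mu_s
        sig = self.sig_s if sig_s is None else sig_s
        return float(mu + 0.5 * sig ** 2)

    def _log_mean_size(self, lam_s=None, mu_s=None, sig_s=None) -> float:
        if self.form == WHALE_LIKE:
            return float(np.log(self.lam_s if lam_s is None else lam_s))
        return self._cov_mean(mu_s=mu_s, sig_s=sig_s)

    def _mean_size(self) -> float:
        return float(np.exp(self._log_mean_size()))

    def _dist_ll(self, alpha=None, eps0=None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        e = self.eps0 if eps0 is None else eps0
        log_w = self.X_s @ a + e
        log_sig = log_w + 0.5 * np.log(2.0 / np.pi)
        with np.errstate(over="ignore"):
            return (_LOG2 - 0.5 * _LOG2PI - log_sig
                    - 0.5 * (self.d["x"] * np.exp(-log_sig)) ** 2)

    def _gs_ll(self, lam_s=None, mu_s=None, sig_s=None) -> float:
        if self.form == WHALE_LIKE:
            lam = float(self.lam_s if lam_s is None else lam_s)
            ll = (self.sum_s * np.log(lam) - self.ns * lam
                  - self.sum_gammaln_s)
            if self.spec.get("zero_truncated", True):
                ll -= self.ns * np.log(-np.expm1(-lam))
            return ll
        mu = float(self.mu_s if mu_s is None else mu_s)
        sig = float(self.sig_s if sig_s is None else sig_s)
        ss = (self.sum_ls2 - 2.0 * mu * self.sum_ls + self.ns * mu ** 2)
        return (-self.sum_log_s - self.ns * np.log(sig)
                - 0.5 * self.ns * _LOG2PI - 0.5 * ss / sig ** 2)

    def _log_wi(self, alpha=None, cov=None, eps1=None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        c = self._cov_mean() if cov is None else cov
        e = self.eps1 if eps1 is None else eps1
        return a[0] + a[1] * self.d["B"] + a[2] * c + e

    def _log_dens(self, omega=None, theta=None, vartheta=None) -> np.ndarray:
        """log population density per cell, excluding eps2."""
        z = self.d["z"]
        if self.hform in ("poly2", "average"):
            w0, w1, w2 = self.omega if omega is None else omega
            p2 = w0 + w1 * z + w2 * z ** 2
        if self.hform in ("poly3", "average"):
            t0, t1, t2, t3 = self.theta if theta is None else theta
            p3 = t0 + t1 * z + t2 * z ** 2 + t3 * z ** 3
        if self.hform == "poly2":
            return p2
        if self.hform == "poly3":
            return p3
        vt = float(self.vartheta if vartheta is None else vartheta)
        return np.logaddexp(np.log(vt) + p2, np.log1p(-vt) + p3)

    def _log_lam(self, log_wi=None, log_dens=None, eps2=None, g0=None,
                 log_S=None) -> np.ndarray:
        lw = self.c_log_wi if log_wi is None else log_wi
        ld = self.c_log_dens if log_dens is None else log_dens
        e2 = self.eps2 if eps2 is None else eps2
        g = self.g0 if g0 is None else g0
        ls = self._log_mean_size() if log_S is None else log_S
        return _LOG2 + self.log_L + lw + ld + e2 + np.log(g) - ls

    def _count_ll(self, log_lam) -> np.ndarray:
        with np.errstate(over="ignore"):
            return (self.d["n"] * log_lam - np.exp(log_lam) - self.gammaln_n)

    def _refresh_all(self) -> None:
        self.c_dist_ll = self._dist_ll()
        self.c_gs_ll = self._gs_ll()
        self.c_log_wi = self._log_wi()
        self.c_log_dens = self._log_dens()
        self.c_log_lam = self._log_lam()
        self.c_count_ll = self._count_ll(self.c_log_lam)

    # -- priors --------------------------------------------------------------

    def _coef_prior(self, v) -> float:
        sd = self.priors["coef_sd"]
        return float(-0.5 * np.sum((np.asarray(v) / sd) ** 2))

    # -- updates -------------------------------------------------------------

    def _accept(self, logr: float) -> bool:
        return bool(np.log(self.rng.uniform()) < logr)

    def update_alpha(self) -> None:
        prop = self.p_alpha.propose(self.alpha, self.rng)
        new_dist = self._dist_ll(alpha=prop)
        new_log_wi = self._log_wi(alpha=prop)
        new_log_lam = self._log_lam(log_wi=new_log_wi)
        new_count = self._count_ll(new_log_lam)
        logr = (np.sum(new_dist) - np.sum(self.c_dist_ll)
                + np.sum(new_count) - np.sum(self.c_count_ll)
                + self._coef_prior(prop) - self._coef_prior(self.alpha))
        acc = self._accept(logr)
        if acc:
            self.alpha = prop
            self.c_dist_ll = new_dist
            self.c_log_wi = new_log_wi
            self.c_log_lam = new_log_lam
            self.c_count_ll = new_count
        if self.adapting:
            self.p_alpha.tuner.adapt(acc, _TARGET_BLOCK)
            self.p_alpha.record(self.alpha)

    def _try_gs(self, *, lam_s=None, mu_s=None, sig_s=None,
                extra_logr: float = 0.0) -> bool:
        new_gs = self._gs_ll(lam_s=lam_s, mu_s=mu_s, sig_s=sig_s)
        cov = self._cov_mean(lam_s=lam_s, mu_s=mu_s, sig_s=sig_s)
        log_S = (np.log(lam_s) if self.form == WHALE_LIKE
                 else self._cov_mean(mu_s=mu_s, sig_s=sig_s))
        new_log_wi = self._log_wi(cov=cov)
        new_log_lam = self._log_lam(log_wi=new_log_wi, log_S=log_S)
        new_count = self._count_ll(new_log_lam)
        logr = (new_gs - self.c_gs_ll
                + np.sum(new_count) - np.sum(self.c_count_ll) + extra_logr)
        if self._accept(logr):
            if self.form == WHALE_LIKE:
                self.lam_s = float(lam_s)
            else:
                self.mu_s, self.sig_s = float(mu_s), float(sig_s)
            self.c_gs_ll = new_gs
            self.c_log_wi = new_log_wi
            self.c_log_lam = new_log_lam
            self.c_count_ll = new_count
            return True
        return False

    def update_groupsize(self) -> None:
        if self.form == WHALE_LIKE:
            prop = self.lam_s * np.exp(self.p_gs.scale * self.rng.standard_normal())
            if 0.0 < prop < self.priors["lambda_s_upper"]:
                # log-scale RW: Jacobian log(prop) - log(cur); flat prior
                jac = np.log(prop) - np.log(self.lam_s)
                acc = self._try_gs(lam_s=prop, extra_logr=jac)
            else:
                acc = False
            if self.adapting:
                self.p_gs.adapt(acc, _TARGET_SCALAR)
        else:
            mu_prop = self.mu_s + self.p_gs.scale * self.rng.standard_normal()
            pr = (-0.5 * (mu_prop / self.priors["coef_sd"]) ** 2
                  + 0.5 * (self.mu_s / self.priors["coef_sd"]) ** 2)
            acc = self._try_gs(mu_s=mu_prop, sig_s=self.sig_s, extra_logr=pr)
            if self.adapting:
                self.p_gs.adapt(acc, _TARGET_SCALAR)
            sig_prop = self.sig_s * np.exp(self.p_gs2.scale * self.rng.standard_normal())
            acc2 = False
            if 0.0 < sig_prop < self.priors["sigma_upper"]:
                jac = np.log(sig_prop) - np.log(self.sig_s)
                acc2 = self._try_gs(mu_s=self.mu_s, sig_s=sig_prop, extra_logr=jac)
            if self.adapting:
                self.p_gs2.adapt(acc2, _TARGET_SCALAR)

    def update_g0(self) -> None:
        logit = np.log(self.g0) - np.log1p(-self.g0)
        prop_logit = logit + self.p_g0.scale * self.rng.standard_normal()
        prop = 1.0 / (1.0 + np.exp(-prop_logit))
        g0p = self.priors["g0"]
        new_log_lam = self._log_lam(g0=prop)
        new_count = self._count_ll(new_log_lam)
        logr = (np.sum(new_count) - np.sum(self.c_count_ll)
                + float(g0p.logpdf(prop)) - float(g0p.logpdf(self.g0))
                + np.log(prop) + np.log1p(-prop)
                - np.log(self.g0) - np.log1p(-self.g0))
        acc = self._accept(logr)
        if acc:
            self.g0 = float(prop)
            self.c_log_lam = new_log_lam
            self.c_count_ll = new_count
        if self.adapting:
            self.p_g0.adapt(acc, _TARGET_SCALAR)

    def _try_habitat(self, **kw) -> bool:
        extra_logr = kw.pop("extra_logr", 0.0)
        new_log_dens = self._log_dens(**kw)
        new_log_lam = self._log_lam(log_dens=new_log_dens)
        new_count = self._count_ll(new_log_lam)
        pr = 0.0
        if "omega" in kw:
            pr += self._coef_prior(kw["omega"]) - self._coef_prior(self.omega)
        if "theta" in kw:
            pr += self._coef_prior(kw["theta"]) - self._coef_prior(self.theta)
        logr = np.sum(new_count) - np.sum(self.c_count_ll) + pr + extra_logr
        if self._accept(logr):
            if "omega" in kw:
                self.omega = np.asarray(kw["omega"], dtype=float)
            if "theta" in kw:
                self.theta = np.asarray(kw["theta"], dtype=float)
            if "vartheta" in kw:
                self.vartheta = float(kw["vartheta"])
            self.c_log_dens = new_log_dens
            self.c_log_lam = new_log_lam
            self.c_count_ll = new_count
            return True
        return False

    def update_habitat(self) -> None:
        if self.hform in ("poly2", "average"):
            prop = self.p_omega.propose(self.omega, self.rng)
            acc = self._try_habitat(omega=prop)
            if self.adapting:
                self.p_omega.tuner.adapt(acc, _TARGET_BLOCK)
                self.p_omega.record(self.omega)
        if self.hform in ("poly3", "average"):
            prop = self.p_theta.propose(self.theta, self.rng)
            acc = self._try_habitat(theta=prop)
            if self.adapting:
                self.p_theta.tuner.adapt(acc, _TARGET_BLOCK)
                self.p_theta.record(self.theta)
        if self.hform == "average":
            logit = np.log(self.vartheta) - np.log1p(-self.vartheta)
            pl = logit + self.p_vt.scale * self.rng.standard_normal()
            prop = 1.0 / (1.0 + np.exp(-pl))
            jac = (np.log(prop) + np.log1p(-prop)
                   - np.log(self.vartheta) - np.log1p(-self.vartheta))
            acc = self._try_habitat(vartheta=prop, extra_logr=jac)
            if self.adapting:
                self.p_vt.adapt(acc, _TARGET_SCALAR)

    def _update_sigma(self, name: str, eps: np.ndarray) -> None:
        cur = getattr(self, f"sig_{name}")
        tuner = self.p_sig[name]
        prop = cur * np.exp(tuner.scale * self.rng.standard_normal())
        acc = False
        if 0.0 < prop < self.priors["sigma_upper"]:
            n = len(eps)
            ss = float(np.sum(eps ** 2))
            logr = (-n * np.log(prop) - 0.5 * ss / prop ** 2
                    + n * np.log(cur) + 0.5 * ss / cur ** 2
                    + np.log(prop) - np.log(cur))  # log-scale Jacobian
            acc = self._accept(logr)
            if acc:
                setattr(self, f"sig_{name}", float(prop))
        if self.adapting:
            tuner.adapt(acc, _TARGET_SCALAR)

    def update_eps0(self) -> None:
        delta = self.p_eps0.scale * self.rng.standard_normal(self.ns)
        prop = self.eps0 + delta
        new_dist = self._dist_ll(eps0=prop)
        logr = (new_dist - self.c_dist_ll
                - 0.5 * (prop ** 2 - self.eps0 ** 2) / self.sig_e0 ** 2)
        acc = np.log(self.rng.uniform(size=self.ns)) < logr
        self.eps0 = np.where(acc, prop, self.eps0)
        self.c_dist_ll = np.where(acc, new_dist, self.c_dist_ll)
        if self.adapting:
            self.p_eps0.adapt(float(np.mean(acc)), _TARGET_SCALAR)
        self._update_sigma("e0", self.eps0)

    def _update_cell_eps(self, which: str) -> None:
        tuner = self.p_eps1 if which == "eps1" else self.p_eps2
        cur = getattr(self, which)
        sig = self.sig_e1 if which == "eps1" else self.sig_e2
        delta = tuner.scale * self.rng.standard_normal(self.nc)
        prop = cur + delta
        new_log_lam = self.c_log_lam + delta
        new_count = self._count_ll(new_log_lam)
        logr = (new_count - self.c_count_ll
                - 0.5 * (prop ** 2 - cur ** 2) / sig ** 2)
        acc = np.log(self.rng.uniform(size=self.nc)) < logr
        setattr(self, which, np.where(acc, prop, cur))
        self.c_log_lam = np.where(acc, new_log_lam, self.c_log_lam)
        self.c_count_ll = np.where(acc, new_count, self.c_count_ll)
        if which == "eps1":
            self.c_log_wi = self.c_log_wi + np.where(acc, delta, 0.0)
        if self.adapting:
            tuner.adapt(float(np.mean(acc)), _TARGET_SCALAR)

    def update_eps1(self) -> None:
        if self.sigma_e1_fixed is not None:
            if self.sigma_e1_fixed > 0:
                self._update_cell_eps("eps1")
            return
        self._update_cell_eps("eps1")
        self._update_sigma("e1", self.eps1)

    def update_eps2(self) -> None:
        if self.sigma_e2_fixed is not None:
            if self.sigma_e2_fixed > 0:
                self._update_cell_eps("eps2")
            return
        self._update_cell_eps("eps2")
        self._update_sigma("e2", self.eps2)

    def scale_move(self, which: str) -> None:
        """Joint rescaling of a residual SD and its whole effect vector.

        Proposes (sigma, eps) -> (c*sigma, c*eps) with log c ~ Normal.  The
        hierarchical prior term is invariant up to the Jacobian (net +log c),
        so only the likelihood decides; this traverses the funnel between a
        small SD with small effects and a large SD with large effects, which
        element-wise updates cross very slowly.
        """
        if which == "e1" and self.sigma_e1_fixed is not None:
            return
        c = float(np.exp(0.3 * self.rng.standard_normal()))
        if which == "e0":
            sig_new = self.sig_e0 * c
            if not 0.0 < sig_new < self.priors["sigma_upper"]:
                return
            new_eps = self.eps0 * c
            new_dist = self._dist_ll(eps0=new_eps)
            logr = np.sum(new_dist) - np.sum(self.c_dist_ll) + np.log(c)
            if self._accept(logr):
                self.sig_e0, self.eps0, self.c_dist_ll = sig_new, new_eps, new_dist
            return
        if which == "e2" and self.sigma_e2_fixed is not None:
            return
        sig = self.sig_e1 if which == "e1" else self.sig_e2
        eps = self.eps1 if which == "e1" else self.eps2
        sig_new = sig * c
        if not 0.0 < sig_new < self.priors["sigma_upper"]:
            return
        delta = (c - 1.0) * eps
        new_log_lam = self.c_log_lam + delta
        new_count = self._count_ll(new_log_lam)
        logr = np.sum(new_count) - np.sum(self.c_count_ll) + np.log(c)
        if self._accept(logr):
            if which == "e1":
                self.sig_e1, self.eps1 = sig_new, eps * c
                self.c_log_wi = self.c_log_wi + delta
            else:
                self.sig_e2, self.eps2 = sig_new, eps * c
            self.c_log_lam = new_log_lam
            self.c_count_ll = new_count

    def rebalance_cell_effects(self) -> None:
        """Gibbs update of the eps1/eps2 split given their sum.

        The two per-cell residuals enter log(lambda) only through their sum,
        so the likelihood fixes s_i = eps1_i + eps2_i while the priors give
        eps1_i | s_i ~ Normal(s_i*v1/(v1+v2), v1*v2/(v1+v2)).  Sampling the
        split exactly (lambda unchanged) decouples the two residual SDs.
        """
        if self.sigma_e1_fixed is not None or self.sigma_e2_fixed is not None:
            return
        v1, v2 = self.sig_e1 ** 2, self.sig_e2 ** 2
        total = self.eps1 + self.eps2
        mean = total * v1 / (v1 + v2)
        sd = np.sqrt(v1 * v2 / (v1 + v2))
        new_eps1 = mean + sd * self.rng.standard_normal(self.nc)
        shift = new_eps1 - self.eps1
        self.eps1 = new_eps1
        self.eps2 = total - new_eps1
        self.c_log_wi = self.c_log_wi + shift

    # -- iteration -----------------------------------------------------------

    def step(self) -> None:
        self.update_alpha()
        self.update_groupsize()
        self.update_g0()
        for _ in range(3):
            self.update_habitat()
        self.update_eps0()
        self.update_eps1()
        self.update_eps2()
        for which in ("e0", "e1", "e2"):
            self.scale_move(which)
        self.rebalance_cell_effects()

    def refresh_blocks(self) -> None:
        self.p_alpha.refresh()
        self.p_omega.refresh()
        self.p_theta.refresh()

    def freeze(self) -> None:
        self.adapting = False

    # -- outputs -------------------------------------------------------------

    def scalars(self) -> dict:
        out = {
            "alpha0": self.alpha[0], "alpha1": self.alpha[1],
            "alpha2": self.alpha[2],
            "g0": self.g0,
            "sigma_eps0": self.sig_e0, "sigma_eps1": self.sig_e1,
        }
        if self.form == WHALE_LIKE:
            out["lambda_s"] = self.lam_s
        else:
            out["mu_s"] = self.mu_s
            out["sigma_s"] = self.sig_s
            out["mean_group_size"] = float(np.exp(self.mu_s + 0.5 * self.sig_s ** 2))
        if self.hform in ("poly2", "average"):
            out.update(omega0=self.omega[0], omega1=self.omega[1],
                       omega2=self.omega[2])
        if self.hform in ("poly3", "average"):
            out.update(theta0=self.theta[0], theta1=self.theta[1],
                       theta2=self.theta[2], theta3=self.theta[3])
        if self.hform == "average":
            out["vartheta"] = self.vartheta
        if self.sigma_e2_fixed is None:
            out["sigma_eps2"] = self.sig_e2
        return {k: float(v) for k, v in out.items()}

    def deviance(self) -> float:
        return float(-2.0 * (np.sum(self.c_dist_ll) + self.c_gs_ll
                             + np.sum(self.c_count_ll)))

    def lam(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.c_log_lam)

    def discrepancies(self, kind: str) -> tuple:
        """Observed and replicated goodness-of-fit discrepancies for counts."""
        lam = self.lam()
        n_rep = self.rng.poisson(np.clip(lam, 0.0, 1e12))
        if kind == "freeman_tukey":
            t_obs = float(np.sum((self.sqrt_n - np.sqrt(lam)) ** 2))
            t_rep = float(np.sum((np.sqrt(n_rep) - np.sqrt(lam)) ** 2))
        else:  # raw sums of squares
            t_obs = float(np.sum((self.d["n"] - lam) ** 2))
            t_rep = float(np.sum((n_rep - lam) ** 2))
        return t_obs, t_rep
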