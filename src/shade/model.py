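"""Hierarchical Bayesian logistic model for directional spatial interaction.

The target cell type in each image is modeled as an inhomogeneous Poisson
process whose log conditional intensity is

    log lambda(v) = beta0_m + z(v)' beta + sum_k q_Ak(v)' delta_Ak(m),

approximated by Bernoulli logistic regression over observed target cells
and homogeneous dummy points (see :mod:`shade.quadrature`).  Interaction
coefficients are pooled across three levels — for each source type k and
basis index p:

    psi(g, p)   ~ N(0, sigma_cohort^2)          cohort level
    gamma(n, p) ~ N(psi(g(n), p), sigma_patient^2)   patient level
    delta(m, p) ~ N(gamma(n(m), p), sigma_image^2)   image level

Intercepts are per image (baseline density varies by image; SICs are
deviations from it) and covariate coefficients are shared across images.
Sampling uses non-centered parameterizations of all three levels and
adaptive HMC (:mod:`shade.hmc`); a flat per-image variant without pooling
is provided as an ablation baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import hmc, summaries
from .basis import BasisSystem
from .patterns import HierarchyMap
from .quadrature import LogisticDataset, build_logistic_dataset

__all__ = [
    "PriorConfig",
    "SHADEModel",
    "SHADEResults",
    "FlatSICModel",
    "FlatResults",
    "log_intensity",
]


@dataclass(frozen=True)
class PriorConfig:
    """Prior scales (all on the log-intensity scale, where |SIC| rarely
    exceeds ~2): half-Normal hyperpriors on the level standard deviations,
    Normal(0, scale^2) on intercepts and covariate coefficients, and
    independent Normal(0, flat_scale^2) on coefficients of the flat model."""

    sigma_cohort_scale: float = 1.0
    sigma_patient_scale: float = 1.0
    sigma_image_scale: float = 1.0
    intercept_scale: float = 5.0
    covariate_scale: float = 5.0
    flat_scale: float = 2.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def log_intensity(beta0, beta, delta, dataset: LogisticDataset, row: int) -> float:
    """Log conditional intensity at one design row:
    beta0 + z(v)'beta + sum_k q_Ak(v)'delta_Ak.

    ``delta`` maps source label -> length-P coefficient vector.  The
    logistic linear predictor of this row is the returned value plus the
    dataset offset (-log lambda_dummy).
    """
    beta = np.asarray(beta, float)
    z = dataset.Z[row]
    if z.shape[0] != beta.shape[0]:
        raise ValueError("covariate coefficient length mismatch")
    val = float(beta0) + float(z @ beta)
    for k in dataset.source_labels:
        q = dataset.features[k][row]
        d = np.asarray(delta[k], float)
        if d.shape[0] != q.shape[0]:
            raise ValueError(f"coefficient length mismatch for source {k!r}")
        val += float(q @ d)
    return val


class _Stacked:
    """Row-stacked design over all images, with per-row image index."""

    def __init__(self, datasets, image_ids):
        order = {m: i for i, m in enumerate(image_ids)}
        parts_q, parts_z, parts_y, parts_off, parts_idx = [], [], [], [], []
        for ds in datasets:
            q = np.hstack([ds.features[k] for k in ds.source_labels])
            parts_q.append(q)
            parts_z.append(ds.Z)
            parts_y.append(ds.y)
            parts_off.append(np.full(ds.n, ds.offset))
            parts_idx.append(np.full(ds.n, order[ds.image_id], dtype=int))
        self.Q = np.vstack(parts_q)
        self.Z = np.vstack(parts_z)
        self.y = np.concatenate(parts_y).astype(float)
        self.offset = np.concatenate(parts_off)
        self.img = np.concatenate(parts_idx)
        # rows are stacked image by image in image_ids order
        counts = np.array([q.shape[0] for q in parts_q])
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.counts = counts


class SHADEModel:
    """Three-level hierarchical SIC model over a study of images.

    Parameters
    ----------
    datasets : list of LogisticDataset
        One design per image (same target type, source labels, and basis).
    hierarchy : HierarchyMap
    basis : BasisSystem
    priors : PriorConfig
    standardize : bool
        Standardize continuous covariate columns across the study
        (columns taking only values {0, 1} are left as is).
    """

    def __init__(self, datasets, hierarchy: HierarchyMap, basis: BasisSystem,
                 priors: PriorConfig | None = None, standardize: bool = True):
        if not datasets:
            raise ValueError("need at least one dataset")
        self.datasets = list(datasets)
        self.hierarchy = hierarchy
        self.basis = basis
        self.priors = priors or PriorConfig()
        self.source_labels = tuple(self.datasets[0].source_labels)
        for ds in self.datasets:
            if tuple(ds.source_labels) != self.source_labels:
                raise ValueError("all datasets must share the same source labels")
            hierarchy.cohort(ds.image_id)  # raises on unmapped images

        self.image_ids = [ds.image_id for ds in self.datasets]
        self.patient_ids = sorted({hierarchy.patient(m) for m in self.image_ids})
        self.cohort_ids = sorted({hierarchy.cohort(m) for m in self.image_ids})
        pat_index = {n: i for i, n in enumerate(self.patient_ids)}
        coh_index = {g: i for i, g in enumerate(self.cohort_ids)}
        self.pat_of_img = np.array(
            [pat_index[hierarchy.patient(m)] for m in self.image_ids]
        )
        self.coh_of_pat = np.array(
            [coh_index[hierarchy.patient_to_cohort[n]] for n in self.patient_ids]
        )

        self.K = len(self.source_labels)
        self.P = basis.P
        self.KP = self.K * self.P
        self.G = len(self.cohort_ids)
        self.N = len(self.patient_ids)
        self.M = len(self.image_ids)
        self.J = self.datasets[0].Z.shape[1]

        self._stack = _Stacked(self.datasets, self.image_ids)
        if standardize and self.J:
            Z = self._stack.Z
            self._z_loc = np.zeros(self.J)
            self._z_scale = np.ones(self.J)
            for j in range(self.J):
                col = Z[:, j]
                if not np.isin(np.unique(col), (0.0, 1.0)).all():
                    self._z_loc[j] = col.mean()
                    sd = col.std()
                    self._z_scale[j] = sd if sd > 0 else 1.0
            self._stack.Z = (Z - self._z_loc) / self._z_scale

        kp = self.KP
        self._sl_psi = slice(0, self.G * kp)
        self._sl_gam = slice(self.G * kp, (self.G + self.N) * kp)
        self._sl_del = slice((self.G + self.N) * kp, (self.G + self.N + self.M) * kp)
        base = (self.G + self.N + self.M) * kp
        self._sl_b0 = slice(base, base + self.M)
        self._sl_beta = slice(base + self.M, base + self.M + self.J)
        self._sl_lsig = slice(base + self.M + self.J, base + self.M + self.J + 3)
        self.n_params = base + self.M + self.J + 3

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_patterns(cls, patterns, hierarchy, target, sources, basis=None,
                      priors=None, extra_covariates=None, covariate_names=(),
                      lambda_dummy=None, seed=0):
        """Build logistic designs from raw patterns and assemble the model.

        Dummy points are drawn per image with seeds derived from ``seed``;
        ``lambda_dummy=None`` uses 4x the observed target density per image.
        """
        from .quadrature import sample_dummy_points

        basis = basis or BasisSystem()
        rng = np.random.default_rng(seed)
        datasets = []
        for pat in patterns:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            quad = None
            if lambda_dummy is not None:
                quad = sample_dummy_points(pat.window, lambda_dummy, seed=sub_seed)
            datasets.append(
                build_logistic_dataset(
                    pat, target, sources, basis, quadrature=quad,
                    extra_covariates=extra_covariates,
                    covariate_names=covariate_names, seed=sub_seed,
                )
            )
        return cls(datasets, hierarchy, basis, priors=priors)

    @classmethod
    def from_dataframe(cls, df, target, sources, basis=None, priors=None,
                       schema=None, windows=None, seed=0, **kwargs):
        """Assemble directly from a cell table DataFrame (or CSV path)."""
        import io

        from .patterns import load_cell_table

        if isinstance(df, pd.DataFrame):
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            buf.seek(0)
            patterns, hierarchy = load_cell_table(buf, schema=schema, windows=windows)
        else:
            patterns, hierarchy = load_cell_table(df, schema=schema, windows=windows)
        return cls.from_patterns(patterns, hierarchy, target, sources,
                                 basis=basis, priors=priors, seed=seed, **kwargs)

    # -- posterior -------------------------------------------------------

    def _unpack(self, theta):
        kp = self.KP
        psi_t = theta[self._sl_psi].reshape(self.G, kp)
        gam_t = theta[self._sl_gam].reshape(self.N, kp)
        del_t = theta[self._sl_del].reshape(self.M, kp)
        beta0 = theta[self._sl_b0]
        beta = theta[self._sl_beta]
        sig = np.exp(theta[self._sl_lsig])  # (cohort, patient, image)
        return psi_t, gam_t, del_t, beta0, beta, sig

    def _natural(self, theta):
        """Map unconstrained parameters to (psi, gamma, delta, beta0, beta, sig)."""
        psi_t, gam_t, del_t, beta0, beta, sig = self._unpack(theta)
        psi = sig[0] * psi_t
        gam = psi[self.coh_of_pat] + sig[1] * gam_t
        dlt = gam[self.pat_of_img] + sig[2] * del_t
        return psi, gam, dlt, beta0, beta, sig

    def log_posterior(self, theta):
        return self.log_posterior_grad(np.asarray(theta, float))[0]

    def log_posterior_grad(self, theta):
        """Unnormalized log posterior and gradient (analytic)."""
        pr = self.priors
        psi_t, gam_t, del_t, beta0, beta, sig = self._unpack(theta)
        psi = sig[0] * psi_t
        gam = psi[self.coh_of_pat] + sig[1] * gam_t
        dlt = gam[self.pat_of_img] + sig[2] * del_t

        st = self._stack
        dlt_rows = np.repeat(dlt, st.counts, axis=0)
        eta = beta0[st.img] + st.offset + np.einsum("ij,ij->i", st.Q, dlt_rows)
        if self.J:
            eta = eta + st.Z @ beta
        loglik = float(np.sum(st.y * eta) - np.sum(np.logaddexp(0.0, eta)))
        r = st.y - expit(eta)

        scales = np.array([pr.sigma_cohort_scale, pr.sigma_patient_scale,
                           pr.sigma_image_scale])
        logp = loglik
        logp -= 0.5 * (np.sum(psi_t**2) + np.sum(gam_t**2) + np.sum(del_t**2))
        logp -= 0.5 * np.sum(beta0**2) / pr.intercept_scale**2
        if self.J:
            logp -= 0.5 * np.sum(beta**2) / pr.covariate_scale**2
        # half-Normal(scale) on sigma, with log-transform Jacobian log(sigma)
        logp += float(np.sum(-0.5 * (sig / scales) ** 2) + np.sum(theta[self._sl_lsig]))

        grad = np.empty_like(theta)
        if st.counts.min() > 0:
            g_dlt = np.add.reduceat(st.Q * r[:, None], st.starts, axis=0)
            g_b0 = np.add.reduceat(r, st.starts)
        else:  # an image with zero rows breaks reduceat segment boundaries
            g_dlt = np.zeros((self.M, self.KP))
            np.add.at(g_dlt, st.img, st.Q * r[:, None])
            g_b0 = np.zeros(self.M)
            np.add.at(g_b0, st.img, r)
        g_gam = np.zeros((self.N, self.KP))
        np.add.at(g_gam, self.pat_of_img, g_dlt)
        g_psi = np.zeros((self.G, self.KP))
        np.add.at(g_psi, self.coh_of_pat, g_gam)

        grad[self._sl_psi] = (sig[0] * g_psi - psi_t).ravel()
        grad[self._sl_gam] = (sig[1] * g_gam - gam_t).ravel()
        grad[self._sl_del] = (sig[2] * g_dlt - del_t).ravel()
        grad[self._sl_b0] = g_b0 - beta0 / pr.intercept_scale**2
        if self.J:
            grad[self._sl_beta] = st.Z.T @ r - beta / pr.covariate_scale**2
        g_lsig = np.empty(3)
        g_lsig[0] = sig[0] * np.sum(g_psi * psi_t)
        g_lsig[1] = sig[1] * np.sum(g_gam * gam_t)
        g_lsig[2] = sig[2] * np.sum(g_dlt * del_t)
        g_lsig += -((sig / scales) ** 2) + 1.0
        grad[self._sl_lsig] = g_lsig
        return logp, grad

    def _initial_point(self):
        theta = np.zeros(self.n_params)
        # initialize intercepts near the observed log target density
        b0 = np.array(
            [np.log(max(ds.n_target, 0.5)
                    / (ds.n - ds.n_target + 0.5) * ds.lambda_dummy)
             for ds in self.datasets]
        )
        theta[self._sl_b0] = b0
        theta[self._sl_lsig] = np.log(0.5)
        return theta

    def fit(self, draws=1000, warmup=1000, chains=4, seed=0, target_accept=0.8,
            **hmc_kwargs) -> "SHADEResults":
        """Sample the joint posterior with adaptive HMC.

        Returns a :class:`SHADEResults` carrying draws of all levels,
        variance components, and sampler diagnostics.  Chains whose
        split-R-hat exceeds 1.05 on any SIC coefficient are flagged in
        the diagnostics (not fatal).
        """
        hmc_kwargs.setdefault("path_length", 1.5)
        raw, stats = hmc.sample_posterior(
            self.log_posterior_grad, self._initial_point(),
            n_warmup=warmup, n_draws=draws, chains=chains, seed=seed,
            target_accept=target_accept, **hmc_kwargs,
        )
        return SHADEResults(self, raw, stats)


class SHADEResults:
    """Posterior draws and summaries of a fitted hierarchical SIC model."""

    def __init__(self, model: SHADEModel, raw_draws, chain_stats):
        self.model = model
        self.raw = raw_draws  # (chains, draws, dim), unconstrained
        self.chain_stats = chain_stats
        C, S, _ = raw_draws.shape
        m = model
        psi = np.empty((C, S, m.G, m.KP))
        gam = np.empty((C, S, m.N, m.KP))
        dlt = np.empty((C, S, m.M, m.KP))
        beta0 = np.empty((C, S, m.M))
        beta = np.empty((C, S, m.J))
        sig = np.empty((C, S, 3))
        for c in range(C):
            for s in range(S):
                p, g, d, b0, b, sg = m._natural(raw_draws[c, s])
                psi[c, s], gam[c, s], dlt[c, s] = p, g, d
                beta0[c, s], beta[c, s], sig[c, s] = b0, b, sg
        shape4 = (C, S, -1, m.K, m.P)
        self.posterior = {
            "psi": psi.reshape(shape4),
            "gamma": gam.reshape(shape4),
            "delta": dlt.reshape(shape4),
            "beta0": beta0,
            "beta": beta,
            "sigma": sig,
        }
        self._diag = None

    # -- indexing helpers ------------------------------------------------

    _LEVEL_KEY = {"cohort": ("psi", "cohort_ids"),
                  "patient": ("gamma", "patient_ids"),
                  "image": ("delta", "image_ids")}

    def _unit_index(self, level, unit):
        key, ids_attr = self._LEVEL_KEY[level]
        ids = getattr(self.model, ids_attr)
        if unit is None:
            if len(ids) != 1:
                raise ValueError(f"level {level!r} has several units; specify one")
            return key, 0
        if unit not in ids:
            raise KeyError(f"unknown {level} unit {unit!r}")
        return key, ids.index(unit)

    def coefficient_draws(self, level, unit=None, source=None) -> np.ndarray:
        """Flattened (n_draws_total, P) coefficient draws for one unit/source."""
        key, i = self._unit_index(level, unit)
        src = source if source is not None else self.model.source_labels[0]
        if src not in self.model.source_labels:
            raise KeyError(f"unknown source label {src!r}")
        k = self.model.source_labels.index(src)
        arr = self.posterior[key][:, :, i, k, :]
        return arr.reshape(-1, self.model.P)

    def sic_draws(self, level="cohort", unit=None, source=None, grid=None) -> np.ndarray:
        """(n_draws_total, len(grid)) matrix of SIC curves, one row per draw."""
        grid = self._grid(grid)
        coefs = self.coefficient_draws(level, unit, source)
        return coefs @ self.model.basis.design(grid).T

    def _grid(self, grid, reporting=False):
        b = self.model.basis
        if grid is None:
            lo = b.r_min if reporting else 0.0
            grid = np.arange(lo, b.r_max + 0.5, 1.0)
        return np.asarray(grid, float)

    # -- summaries -------------------------------------------------------

    def credible_band(self, level="cohort", unit=None, source=None, grid=None,
                      prob=0.95, reporting=True) -> summaries.CredibleBand:
        """Simultaneous credible band of the SIC at one hierarchy unit.

        ``reporting=True`` restricts the default grid to [r_min, r_max]."""
        grid = self._grid(grid, reporting=reporting)
        draws = self.sic_draws(level, unit, source, grid)
        src = source if source is not None else self.model.source_labels[0]
        return summaries.simultaneous_band(
            draws, grid, level=prob, level_tag=level, source=src,
            target=self.model.datasets[0].target_label,
        )

    def detect(self, level="image", unit=None, source=None, interval=(0.0, 75.0),
               prob=0.95):
        band = self.credible_band(level, unit, source,
                                  grid=np.arange(interval[0], interval[1] + 0.5, 1.0),
                                  prob=prob, reporting=False)
        return summaries.detect_interaction(band, interval)

    def heterogeneity(self, grid=None) -> pd.DataFrame:
        grid = self._grid(grid, reporting=True)
        return summaries.heterogeneity_mad(self, self.model.basis, grid)

    def diagnostics(self) -> dict:
        """Sampler health: split-R-hat and bulk ESS over SIC coefficients
        (via arviz), divergence counts, acceptance rates."""
        if self._diag is None:
            import arviz as az

            data = {k: self.posterior[k] for k in ("psi", "gamma", "delta")}
            ds = az.convert_to_dataset(data)
            rhat = az.rhat(ds)
            ess = az.ess(ds)
            max_rhat = float(max(rhat[k].max() for k in data))
            min_ess = float(min(ess[k].min() for k in data))
            self._diag = {
                "max_rhat_sic": max_rhat,
                "min_ess_sic": min_ess,
                "divergences": int(sum(s["divergences"] for s in self.chain_stats)),
                "accept_rates": [s["accept_rate"] for s in self.chain_stats],
                "step_sizes": [s["step_size"] for s in self.chain_stats],
                "converged": bool(max_rhat <= 1.05),
            }
        return self._diag

    def summary(self, interval=(25.0, 150.0)) -> pd.DataFrame:
        """Per-source cohort-level summary table: peak location/magnitude,
        persistence, strength, detection verdict, and variance components."""
        rows = []
        for g in self.model.cohort_ids:
            for src in self.model.source_labels:
                lo = max(interval[0], self.model.basis.r_min)
                grid = np.arange(lo, min(interval[1], self.model.basis.r_max) + 0.5, 1.0)
                draws = self.sic_draws("cohort", g, src, grid)
                band = summaries.simultaneous_band(draws, grid, level_tag="cohort",
                                                  source=src)
                det = summaries.detect_interaction(band, (grid[0], grid[-1]))
                meas = summaries.summary_measures(draws, band, (grid[0], grid[-1]))
                rows.append({
                    "cohort": g, "source": src,
                    "target": self.model.datasets[0].target_label,
                    "peak_distance_um": meas.peak_location,
                    "peak_sic": meas.peak_magnitude,
                    "peak_fold_change": float(np.exp(meas.peak_magnitude)),
                    "persistence": meas.persistence,
                    "strength": meas.strength,
                    "detected": det["detected"],
                    "sign": det["sign"],
                })
        # prioritization convention: strongest pairs first
        df = pd.DataFrame(rows).sort_values(
            "strength", ascending=False, ignore_index=True)
        sig = self.posterior["sigma"].reshape(-1, 3)
        df.attrs["sigma_posterior_mean"] = {
            "cohort": float(sig[:, 0].mean()),
            "patient": float(sig[:, 1].mean()),
            "image": float(sig[:, 2].mean()),
        }
        return df

    def plot_sic(self, level="cohort", unit=None, source=None, ax=None,
                 prob=0.95, color="C0"):
        """Plot one SIC's posterior mean and simultaneous band."""
        return self.credible_band(level, unit, source, prob=prob).plot(
            ax=ax, color=color)

    # -- persistence -----------------------------------------------------

    def save(self, draws_path, diagnostics_path=None):
        """Columnar draws file (chain, draw, parameter, value) + JSON sidecar."""
        m = self.model
        recs = []
        names = []
        for key in ("psi", "gamma", "delta"):
            ids = {"psi": m.cohort_ids, "gamma": m.patient_ids,
                   "delta": m.image_ids}[key]
            for i, u in enumerate(ids):
                for k, src in enumerate(m.source_labels):
                    for p in range(m.P):
                        names.append((key, f"{key}[{u},{src},{p}]", (i, k, p)))
        C, S = self.raw.shape[:2]
        for c in range(C):
            for key, name, idx in names:
                arr = self.posterior[key][c, :, idx[0], idx[1], idx[2]]
                recs.append(pd.DataFrame(
                    {"chain": c, "draw": np.arange(S), "parameter": name,
                     "value": arr}))
        for c in range(C):
            for j, mid in enumerate(m.image_ids):
                recs.append(pd.DataFrame(
                    {"chain": c, "draw": np.arange(S),
                     "parameter": f"beta0[{mid}]",
                     "value": self.posterior["beta0"][c, :, j]}))
            for j, sname in enumerate(("cohort", "patient", "image")):
                recs.append(pd.DataFrame(
                    {"chain": c, "draw": np.arange(S),
                     "parameter": f"sigma_{sname}",
                     "value": self.posterior["sigma"][c, :, j]}))
        pd.concat(recs, ignore_index=True).to_csv(draws_path, index=False)
        if diagnostics_path is not None:
            with open(diagnostics_path, "w") as fh:
                json.dump(self.diagnostics(), fh, indent=2)


class FlatSICModel:
    """Per-image SIC model without hierarchical pooling (ablation baseline).

    Same Bernoulli likelihood as :class:`SHADEModel`, with independent
    weakly-informative Normal(0, flat_scale^2) priors on the interaction
    coefficients of each image.
    """

    def __init__(self, dataset: LogisticDataset, basis: BasisSystem,
                 priors: PriorConfig | None = None):
        self.dataset = dataset
        self.basis = basis
        self.priors = priors or PriorConfig()
        self.source_labels = tuple(dataset.source_labels)
        self.K = len(self.source_labels)
        self.P = basis.P
        self.J = dataset.Z.shape[1]
        self._X = dataset.design()  # (n, J + K*P)
        self.n_params = 1 + self.J + self.K * self.P

    def log_posterior_grad(self, theta):
        pr = self.priors
        beta0, rest = theta[0], theta[1:]
        eta = beta0 + self.dataset.offset + self._X @ rest
        y = self.dataset.y.astype(float)
        logp = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
        r = y - expit(eta)
        prior_prec = np.concatenate([
            np.full(self.J, 1.0 / pr.covariate_scale**2),
            np.full(self.K * self.P, 1.0 / pr.flat_scale**2),
        ])
        logp -= 0.5 * beta0**2 / pr.intercept_scale**2
        logp -= 0.5 * float(np.sum(prior_prec * rest**2))
        grad = np.empty_like(theta)
        grad[0] = np.sum(r) - beta0 / pr.intercept_scale**2
        grad[1:] = self._X.T @ r - prior_prec * rest
        return logp, grad

    def log_posterior(self, theta):
        return self.log_posterior_grad(np.asarray(theta, float))[0]

    def fit(self, draws=1000, warmup=1000, chains=2, seed=0, **hmc_kwargs):
        ds = self.dataset
        init = np.zeros(self.n_params)
        init[0] = np.log(max(ds.n_target, 0.5) / (ds.n - ds.n_target + 0.5)
                         * ds.lambda_dummy)
        raw, stats = hmc.sample_posterior(
            self.log_posterior_grad, init, n_warmup=warmup, n_draws=draws,
            chains=chains, seed=seed, **hmc_kwargs)
        return FlatResults(self, raw, stats)


class FlatResults:
    """Posterior draws of one flat per-image fit."""

    def __init__(self, model: FlatSICModel, raw_draws, chain_stats):
        self.model = model
        self.raw = raw_draws
        self.chain_stats = chain_stats
        flat = raw_draws.reshape(-1, raw_draws.shape[-1])
        self.beta0 = flat[:, 0]
        self.beta = flat[:, 1:1 + model.J]
        self.delta = flat[:, 1 + model.J:].reshape(-1, model.K, model.P)

    def coefficient_draws(self, source=None) -> np.ndarray:
        src = source if source is not None else self.model.source_labels[0]
        k = self.model.source_labels.index(src)
        return self.delta[:, k, :]

    def sic_draws(self, source=None, grid=None) -> np.ndarray:
        b = self.model.basis
        if grid is None:
            grid = np.arange(b.r_min, b.r_max + 0.5, 1.0)
        return self.coefficient_draws(source) @ b.design(np.asarray(grid, float)).T

    def credible_band(self, source=None, grid=None, prob=0.95):
        b = self.model.basis
        if grid is None:
            grid = np.arange(b.r_min, b.r_max + 0.5, 1.0)
        grid = np.asarray(grid, float)
        src = source if source is not None else self.model.source_labels[0]
        return summaries.simultaneous_band(
            self.sic_draws(src, grid), grid, level=prob, level_tag="image",
            source=src, target=self.model.dataset.target_label)

    def detect(self, source=None, interval=(0.0, 75.0), prob=0.95):
        grid = np.arange(interval[0], interval[1] + 0.5, 1.0)
        band = self.credible_band(source, grid, prob)
        return summaries.detect_interaction(band, interval)
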