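"""Parametric empirical-Bayes ComBat harmonization of a feature table.

The model for feature f of a case in batch i is

    x_if = alpha_f + gamma_if + delta_if * eps,   eps ~ N(0, sigma_f^2)

Location (gamma) and scale (delta) batch effects are estimated per
batch and feature, shrunk across features toward batch-level priors
(normal for gamma, inverse-gamma for delta^2) by the standard
empirical-Bayes fixed-point iteration, and removed:

    x*_if = sigma_f * (z_if - gamma*_if) / delta*_if + alpha_f

with z the standardized data.  Only the parametric variant is
implemented, without covariate protection by default: fitting is meant
to happen on training folds only, with held-out cases transformed by
the training-fold model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

NON_FEATURE_COLUMNS = ("case_id", "batch", "label")


@dataclasses.dataclass
class ComBatModel:
    """Fitted harmonization model; apply with :meth:`transform`."""

    feature_names: list[str]
    batch_levels: list
    protected: bool
    grand_mean: np.ndarray  # per feature
    pooled_scale: np.ndarray  # per feature, sqrt of pooled variance
    gamma_star: np.ndarray  # (n_batches, n_features)
    delta_star: np.ndarray  # (n_batches, n_features), scale (not squared)
    gamma_bar: np.ndarray
    tau_sq: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    n_iter: np.ndarray

    # ------------------------------------------------------------------
    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        batch_column: str = "batch",
        feature_columns: list[str] | None = None,
        tol: float = 1e-4,
        max_iter: int = 100,
        ddof: int = 0,
        protect: str | None = None,
    ) -> "ComBatModel":
        """Estimate batch location/scale effects from a feature table.

        Requires >= 2 cases per batch and nonzero pooled variance for
        every feature.  ``ddof`` controls the divisor of the per-batch
        raw variance estimates; the default 0 makes a single-batch fit
        an exact identity (gamma* = 0, delta* = 1).

        ``protect`` names a biological covariate column (typically the
        class label) to adjust for when *estimating* the batch effects:
        without it, any class-batch association leaks biological signal
        into the batch means and harmonization removes it.  The
        covariate enters estimation only — :meth:`transform` never
        needs it, so held-out cases can be transformed without labels.
        Beware that protecting the label makes the fitted batch
        parameters depend on training labels.
        """
        feats = feature_columns or [c for c in table.columns if c not in NON_FEATURE_COLUMNS]
        X = table[feats].to_numpy(dtype=np.float64)  # cases x features
        batches = table[batch_column].to_numpy()
        levels = sorted(pd.unique(batches).tolist())
        groups = [np.flatnonzero(batches == b) for b in levels]
        for b, g in zip(levels, groups):
            if len(g) < 2:
                raise ValueError(f"batch {b!r} has {len(g)} case(s); need >= 2")

        n = X.shape[0]
        props = np.array([len(g) / n for g in groups])
        batch_idx = np.array([levels.index(b) for b in batches])
        if protect is None:
            batch_means = np.stack([X[g].mean(axis=0) for g in groups])  # (B, F)
            grand_mean = props @ batch_means
            cov_effect = np.zeros_like(X)
            resid = X - batch_means[batch_idx]
        else:
            # per-feature OLS on [batch one-hots, centred covariate]:
            # the covariate term absorbs class composition differences
            # so the batch coefficients estimate pure batch effects
            cov = table[protect].to_numpy(dtype=np.float64)
            cov = cov - cov.mean()
            D = np.column_stack([np.eye(len(levels))[batch_idx], cov])
            B, *_ = np.linalg.lstsq(D, X, rcond=None)
            batch_means = B[: len(levels)]
            grand_mean = props @ batch_means
            cov_effect = np.outer(cov, np.ones(X.shape[1])) * B[-1]
            resid = X - D @ B
        pooled_var = (resid**2).mean(axis=0)
        zero = np.flatnonzero(pooled_var <= 0)
        if zero.size:
            raise ValueError(f"zero pooled variance for feature(s): {[feats[i] for i in zero]}")
        pooled_scale = np.sqrt(pooled_var)

        Z = (X - grand_mean - cov_effect) / pooled_scale
        gamma_hat = np.stack([Z[g].mean(axis=0) for g in groups])
        delta_hat_sq = np.stack([Z[g].var(axis=0, ddof=ddof) for g in groups])

        gamma_bar = gamma_hat.mean(axis=1)
        tau_sq = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat_sq.mean(axis=1)
        s2 = delta_hat_sq.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_prior = np.where(s2 > 0, (2 * s2 + m**2) / s2, np.inf)
            b_prior = np.where(s2 > 0, (m * s2 + m**3) / s2, np.inf)

        gamma_star = np.empty_like(gamma_hat)
        delta_star_sq = np.empty_like(delta_hat_sq)
        n_iter = np.zeros(len(levels), dtype=int)
        for bi, g in enumerate(groups):
            n_b = len(g)
            g_hat = gamma_hat[bi]
            d_hat = delta_hat_sq[bi]
            if not np.isfinite(a_prior[bi]) or tau_sq[bi] <= 0:
                # degenerate priors (e.g. a single feature or identical
                # batch variances): fall back to the raw estimates
                gamma_star[bi] = g_hat
                delta_star_sq[bi] = d_hat
                continue
            g_star = g_hat.copy()
            d_star = d_hat.copy()
            ssq = ((Z[g] - g_star) ** 2).sum(axis=0)
            for it in range(max_iter):
                g_new = (n_b * tau_sq[bi] * g_hat + d_star * gamma_bar[bi]) / (
                    n_b * tau_sq[bi] + d_star
                )
                ssq = ((Z[g] - g_new) ** 2).sum(axis=0)
                d_new = (b_prior[bi] + 0.5 * ssq) / (n_b / 2.0 + a_prior[bi] - 1.0)
                change = max(
                    np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max()
                )
                g_star, d_star = g_new, d_new
                if change < tol:
                    break
            n_iter[bi] = it + 1
            gamma_star[bi] = g_star
            delta_star_sq[bi] = d_star

        if np.any(delta_star_sq <= 0):
            raise RuntimeError("non-positive adjusted scale; degenerate input")
        return cls(
            feature_names=list(feats),
            batch_levels=levels,
            protected=protect is not None,
            grand_mean=grand_mean,
            pooled_scale=pooled_scale,
            gamma_star=gamma_star,
            delta_star=np.sqrt(delta_star_sq),
            gamma_bar=gamma_bar,
            tau_sq=tau_sq,
            a_prior=a_prior,
            b_prior=b_prior,
            n_iter=n_iter,
        )

    # ------------------------------------------------------------------
    def transform(self, table: pd.DataFrame, batch_column: str = "batch") -> pd.DataFrame:
        """Remove the fitted batch effects; non-feature columns pass through.

        Raises on batch labels that were not seen at fit time (no silent
        extrapolation).
        """
        batches = table[batch_column].to_numpy()
        unseen = set(pd.unique(batches)) - set(self.batch_levels)
        if unseen:
            raise ValueError(f"unseen batch label(s): {sorted(unseen)!r}")
        X = table[self.feature_names].to_numpy(dtype=np.float64)
        Z = (X - self.grand_mean) / self.pooled_scale
        idx = np.array([self.batch_levels.index(b) for b in batches])
        Zc = (Z - self.gamma_star[idx]) / self.delta_star[idx]
        Xc = Zc * self.pooled_scale + self.grand_mean
        out = table.copy()
        out[self.feature_names] = Xc
        return out

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "feature_names": self.feature_names,
            "batch_levels": [str(b) for b in self.batch_levels],
            "protected": self.protected,
            **{
                k: getattr(self, k).tolist()
                for k in (
                    "grand_mean",
                    "pooled_scale",
                    "gamma_star",
                    "delta_star",
                    "gamma_bar",
                    "tau_sq",
                    "a_prior",
                    "b_prior",
                    "n_iter",
                )
            },
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def harmonize(
    table: pd.DataFrame, batch_column: str = "batch", **fit_kw
) -> tuple[pd.DataFrame, ComBatModel]:
    """Fit-and-apply convenience wrapper for a single table."""
    model = ComBatModel.fit(table, batch_column=batch_column, **fit_kw)
    return model.transform(table, batch_column=batch_column), model
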