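"""Within-biotype normalization and NB quasi-likelihood differential expression.

Counts are modeled per feature with a negative-binomial log-linear model
(variance mu + phi * mu^2) whose offset is the log of the total reads
assigned to the feature's biotype in that sample — i.e. features are
compared on their share *within* their own biotype, so global shifts in
biotype composition between disease states do not masquerade as
feature-level differential expression.

Testing follows the quasi-likelihood F-test scheme: per-feature NB
dispersions are estimated by adjusted profile likelihood (Cox–Reid) and
shrunk toward the common estimate with ``prior_df`` weight; a feature-level
quasi-dispersion (residual deviance / residual df) is shrunk the same way;
the contrast is tested with an F statistic whose denominator df gains the
prior df.  Fold changes are reported on normalized group means with a
prior count so features absent from one group get large but finite values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .countmatrix import CountMatrix, SampleTable

logger = logging.getLogger(__name__)

CONTRASTS = ("PreOp_vs_HC", "PreOp_vs_PostOp")

_MU_FLOOR = 1e-8
_MU_CEIL = 1e12


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """A two-group contrast, optionally blocked on subject.

    ``PreOp_vs_HC`` compares patients at diagnosis with healthy controls
    (independent groups).  ``PreOp_vs_PostOp`` compares paired samples from
    the same patients; with ``paired=True`` (default) a subject indicator
    absorbs the shared patient effect.
    """

    contrast: str
    paired: bool = True

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise DesignError(f"unknown contrast {self.contrast!r}; valid: {CONTRASTS}")
        if self.contrast == "PreOp_vs_HC" and self.paired:
            raise DesignError("PreOp_vs_HC has disjoint subjects; paired is not valid")

    @property
    def group_a(self) -> str:
        return "PreOp"

    @property
    def group_b(self) -> str:
        return "HC" if self.contrast == "PreOp_vs_HC" else "PostOp"


def build_design_matrix(
    samples: SampleTable, design: DesignSpec
) -> tuple[list[str], np.ndarray, int]:
    """Return (ordered sample ids, design matrix X, contrast column index)."""
    ids_a = samples.samples_in_group(design.group_a)
    ids_b = samples.samples_in_group(design.group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise DesignError(
            f"each group needs >=2 samples; got {len(ids_a)} {design.group_a}, "
            f"{len(ids_b)} {design.group_b}"
        )
    sample_ids = ids_b + ids_a
    is_a = np.array([0] * len(ids_b) + [1] * len(ids_a), dtype=float)
    cols = [np.ones(len(sample_ids))]
    if design.paired:
        subjects = samples.subjects_for(sample_ids).to_numpy()
        if set(samples.subjects_for(ids_a)) != set(samples.subjects_for(ids_b)):
            raise DesignError("paired design requires both groups to share subjects")
        uniq = sorted(set(subjects))
        for s in uniq[1:]:  # first subject absorbed by intercept
            cols.append((subjects == s).astype(float))
    cols.append(is_a)
    X = np.column_stack(cols)
    return sample_ids, X, X.shape[1] - 1


# ---------------------------------------------------------------------------
# normalization


def normalize_within_biotype(cm: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each feature by its biotype's per-sample total, times 1e6.

    Returns ``(normalized, biotype_totals)``.  ``normalized[f, s]`` is the
    feature's reads per million reads of its own biotype ("biotype-CPM");
    features whose biotype has zero reads in a sample become NaN (missing)
    there, with a logged warning.  ``biotype_totals`` (biotype x sample)
    feeds the GLM offsets downstream.
    """
    totals = cm.biotype_totals()
    denom = totals.loc[cm.biotypes.to_numpy()].to_numpy(dtype=float)
    zero = denom == 0
    if zero.any():
        n_pairs = int((totals.to_numpy() == 0).sum())
        logger.warning(
            "%d (biotype, sample) pairs have zero assigned reads; their features "
            "are set to missing in those samples",
            n_pairs,
        )
        denom[zero] = np.nan
    normalized = pd.DataFrame(
        cm.counts.to_numpy(dtype=float) / denom * 1e6,
        index=cm.counts.index,
        columns=cm.counts.columns,
    )
    return normalized, totals


def prefilter_features(
    cm: CountMatrix, sample_ids, min_count: int = 1, min_samples: int = 3
) -> pd.Index:
    """Features with >= ``min_count`` reads in >= ``min_samples`` of the
    contrast's samples."""
    sub = cm.counts[list(sample_ids)]
    keep = (sub >= min_count).sum(axis=1) >= min_samples
    return cm.counts.index[keep]


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across features)


def _nb_deviance(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per-feature residual deviance; Poisson limit at phi == 0."""
    mu = np.clip(mu, _MU_FLOOR, None)
    phi = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(Y > 0, Y * np.log(np.where(Y > 0, Y, 1.0) / mu), 0.0)
        pois = 2.0 * (ylogy - (Y - mu))
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
        nb = 2.0 * (ylogy - (Y + r) * np.log((Y + r) / (mu + r)))
    d = np.where(phi > 0, nb, pois)
    return np.sum(np.where(M, d, 0.0), axis=1)


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per-feature NB log-likelihood (Poisson at phi == 0)."""
    mu = np.clip(mu, _MU_FLOOR, None)
    phi = phi[:, None]
    pois = Y * np.log(mu) - mu - special.gammaln(Y + 1.0)
    safe_phi = np.where(phi > 0, phi, 1.0)
    r = 1.0 / safe_phi
    nb = (
        special.gammaln(Y + r)
        - special.gammaln(r)
        - special.gammaln(Y + 1.0)
        + r * np.log(r / (r + mu))
        + Y * np.log(mu / (r + mu))
    )
    ll = np.where(phi > 0, nb, pois)
    return np.sum(np.where(M, ll, 0.0), axis=1)


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    M: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-scoring IRLS for NB log-linear models, batched over features.

    Returns (beta, mu, deviance, converged).  ``M`` masks out missing
    observations (zero biotype total).  A tiny ridge keeps the normal
    equations solvable for degenerate features.
    """
    G, S = Y.shape
    p = X.shape[1]
    mu = np.clip(np.where(M, Y, 0.0) + 0.5, _MU_FLOOR, _MU_CEIL)
    eta = np.log(mu)
    if beta0 is not None:
        eta = beta0 @ X.T + offset
        mu = np.clip(np.exp(np.clip(eta, -500, 60)), _MU_FLOOR, _MU_CEIL)
    beta = np.zeros((G, p)) if beta0 is None else beta0.copy()
    dev = _nb_deviance(Y, mu, phi, M)
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-8 * np.eye(p)
    for _ in range(max_iter):
        W = np.where(M, mu / (1.0 + phi[:, None] * mu), 0.0)
        z = (eta - offset) + (Y - mu) / mu
        XW = W[:, :, None] * X[None, :, :]  # G x S x p
        A = np.matmul(X.T[None, :, :], XW) + ridge  # G x p x p
        b = np.matmul(XW.transpose(0, 2, 1), np.where(M, z, 0.0)[:, :, None])[..., 0]
        try:
            new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge should prevent
            new_beta = np.linalg.lstsq(A.reshape(-1, p), b.reshape(-1, 1), rcond=None)[0]
        beta = np.where(converged[:, None], beta, new_beta)
        eta = beta @ X.T + offset
        mu = np.clip(np.exp(np.clip(eta, -500, 60)), _MU_FLOOR, _MU_CEIL)
        new_dev = _nb_deviance(Y, mu, phi, M)
        delta = np.abs(new_dev - dev) / (np.abs(dev) + 1.0)
        converged = converged | (delta < tol)
        dev = new_dev
        if converged.all():
            break
    return beta, mu, dev, converged


def _adjusted_profile_loglik(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi_val: float,
    M: np.ndarray,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cox–Reid adjusted profile log-likelihood at a single dispersion."""
    G = Y.shape[0]
    phi = np.full(G, phi_val)
    beta, mu, _, _ = _irls_nb(Y, X, offset, phi, M, beta0=beta0, max_iter=25, tol=1e-6)
    ll = _nb_loglik(Y, mu, phi, M)
    W = np.where(M, mu / (1.0 + phi[:, None] * mu), 0.0)
    XW = W[:, :, None] * X[None, :, :]
    A = np.matmul(X.T[None, :, :], XW) + 1e-10 * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet, beta


def fit_dispersions(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    M: np.ndarray | None = None,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Empirical-Bayes NB dispersion estimates, one per feature.

    The Cox–Reid adjusted profile likelihood is evaluated on a log-spaced
    dispersion grid; each feature maximizes its own APL plus the
    across-feature mean APL weighted by ``prior_df / residual df`` — the
    moderation that pulls noisy per-feature estimates toward the common
    dispersion.  The grid argmax is refined by parabolic interpolation in
    log-dispersion.  Estimates are floored at 1e-6.
    """
    G, S = Y.shape
    if M is None:
        M = np.ones_like(Y, dtype=bool)
    resid_df = np.maximum(M.sum(axis=1) - X.shape[1], 1)
    if grid is None:
        grid = np.logspace(-6, 1, 22)
    apl = np.empty((G, len(grid)))
    beta_warm = None
    for k, phi_val in enumerate(grid):
        apl[:, k], beta_warm = _adjusted_profile_loglik(
            Y, X, offset, float(phi_val), M, beta0=beta_warm
        )
    weight = prior_df / resid_df
    score = apl + weight[:, None] * apl.mean(axis=0)[None, :]
    k_hat = np.argmax(score, axis=1)
    log_grid = np.log(grid)
    phi_hat = np.empty(G)
    for g in range(G):
        k = k_hat[g]
        if 0 < k < len(grid) - 1:
            y0, y1, y2 = score[g, k - 1], score[g, k], score[g, k + 1]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
            shift = np.clip(shift, -1.0, 1.0)
            step = log_grid[k + 1] - log_grid[k]
            phi_hat[g] = np.exp(log_grid[k] + shift * step)
        else:
            phi_hat[g] = grid[k]
    return np.maximum(phi_hat, 1e-6)


def ql_f_test(
    Y: np.ndarray,
    X: np.ndarray,
    contrast_idx: int,
    offset: np.ndarray,
    dispersions: np.ndarray,
    M: np.ndarray | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Quasi-likelihood F-test of one design column, batched over features.

    Returns a DataFrame with columns ``coef`` (contrast coefficient, natural
    log scale), ``F``, ``p``, ``resid_df``, ``converged``.  Non-convergent
    fits are flagged and given p = 1.
    """
    G, S = Y.shape
    if M is None:
        M = np.ones_like(Y, dtype=bool)
    X0 = np.delete(X, contrast_idx, axis=1)
    beta_full, _, dev_full, conv_full = _irls_nb(Y, X, offset, dispersions, M)
    _, _, dev_red, conv_red = _irls_nb(Y, X0, offset, dispersions, M)
    resid_df = np.maximum(M.sum(axis=1) - X.shape[1], 1).astype(float)
    s2 = np.maximum(dev_full / resid_df, 1e-10)
    s2_mean = float(np.mean(s2))
    s2_shrunk = (prior_df * s2_mean + resid_df * s2) / (prior_df + resid_df)
    drop = np.maximum(dev_red - dev_full, 0.0)
    F = drop / s2_shrunk
    p = stats.f.sf(F, 1.0, resid_df + prior_df)
    converged = conv_full & conv_red
    p = np.where(converged, p, 1.0)
    return pd.DataFrame(
        {
            "coef": beta_full[:, contrast_idx],
            "F": F,
            "p": p,
            "resid_df": resid_df,
            "converged": converged,
        }
    )


# ---------------------------------------------------------------------------
# multiple testing and significance calls


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_significant(
    results: pd.DataFrame, alpha: float = 0.05, min_abs_lfc: float = 1.0
) -> pd.DataFrame:
    """Features with adjusted p <= alpha and |log2FC| strictly > min_abs_lfc.

    Adds a ``direction`` column (``up``/``down`` by the sign of log2FC).
    """
    if results.empty:
        out = results.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    mask = (results["adj_p"] <= alpha) & (results["log2FC"].abs() > min_abs_lfc)
    out = results.loc[mask].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# top-level per-contrast run


def run_de(
    cm: CountMatrix,
    samples: SampleTable,
    design: DesignSpec,
    prior_df: float = 10.0,
    prior_count: float = 2.0,
    min_count: int = 1,
    min_samples: int = 3,
    bh_per_biotype: bool = True,
) -> pd.DataFrame:
    """Full differential-expression run for one contrast.

    Per biotype: prefilter low-abundance features, fit NB GLMs with the
    log biotype-total offset, estimate and shrink dispersions, apply the
    quasi-likelihood F-test, and BH-adjust (within the biotype's test
    family by default, globally with ``bh_per_biotype=False``).

    Returns a DataFrame with ``feature_id``, ``biotype``, ``log2FC`` (prior
    count ``prior_count`` on normalized group means), ``mean_norm_a``/``_b``,
    ``p``, ``adj_p`` and bookkeeping columns.
    """
    sample_ids, X, contrast_idx = build_design_matrix(samples, design)
    keep = prefilter_features(cm, sample_ids, min_count=min_count, min_samples=min_samples)
    if len(keep) == 0:
        return pd.DataFrame(
            columns=["feature_id", "biotype", "log2FC", "mean_norm_a", "mean_norm_b", "p", "adj_p"]
        ).set_index("feature_id")
    sub = cm.subset_features(keep).subset_samples(sample_ids)
    normalized, totals = normalize_within_biotype(sub)
    ids_a = samples.samples_in_group(design.group_a)
    ids_b = samples.samples_in_group(design.group_b)

    frames = []
    for biotype, feats in sub.counts.groupby(sub.biotypes).groups.items():
        feats = pd.Index(feats)
        Y = sub.counts.loc[feats].to_numpy(dtype=float)
        tot = totals.loc[biotype].to_numpy(dtype=float)
        M = np.broadcast_to(tot > 0, Y.shape).copy()
        offset = np.broadcast_to(
            np.log(np.where(tot > 0, tot, 1.0)), Y.shape
        ).astype(float)
        phi = fit_dispersions(Y, X, offset, M, prior_df=prior_df)
        res = ql_f_test(Y, X, contrast_idx, offset, phi, M, prior_df=prior_df)
        mean_a = normalized.loc[feats, ids_a].mean(axis=1, skipna=True).to_numpy()
        mean_b = normalized.loc[feats, ids_b].mean(axis=1, skipna=True).to_numpy()
        log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
        frame = pd.DataFrame(
            {
                "feature_id": feats,
                "biotype": biotype,
                "log2FC": log2fc,
                "mean_norm_a": mean_a,
                "mean_norm_b": mean_b,
                "dispersion": phi,
                "F": res["F"].to_numpy(),
                "p": res["p"].to_numpy(),
                "converged": res["converged"].to_numpy(),
            }
        )
        if bh_per_biotype:
            frame["adj_p"] = bh_adjust(frame["p"].to_numpy())
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if not bh_per_biotype:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out.set_index("feature_id")
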