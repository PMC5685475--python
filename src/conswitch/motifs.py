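"""Elastic-net regression of accessibility change on motif content.

The response is the per-peak log2 fold change of accessibility; the
predictors are per-motif hit counts plus three composition covariates
(peak width, G+C base count, CpG dinucleotide count).  The objective is

    (1/2n) * ||y - Xb||^2 + lambda * (alpha * ||b||_1
                                      + (1 - alpha)/2 * ||b||_2^2)

with alpha the L1/L2 mixing and lambda the overall penalty — the glmnet
parameterization.  Predictors are standardized before penalization and
coefficients reported on the original scale.  alpha and lambda are
chosen by a grid search: alpha in 0..1 step 0.1; per alpha a log-spaced
lambda path with 5-fold cross-validated MSE; global CV minimum wins,
ties to the larger (sparser) lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path

from .pwm import DEFAULT_CUTOFF, PWMModel, count_hits

ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
COVARIATES = ("width_bp", "gc_count", "cpg_count")
LAMBDA_PATH_LENGTH = 100
LAMBDA_DECADES = 4.0
_RIDGE_ALPHA_FLOOR = 1e-3  # glmnet-style stand-in for alpha=0 in lambda_max


@dataclass
class DesignMatrix:
    """Peaks x (motif counts + covariates) with accessibility response."""

    X: pd.DataFrame
    y: np.ndarray
    motif_columns: list[str]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X.to_numpy())):
            raise ValueError("non-finite design entries")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate design column names")


@dataclass
class ElasticNetFit:
    beta: pd.Series          # original predictor scale
    intercept: float
    alpha: float
    lam: float
    cv_mse: pd.DataFrame | None = None
    dropped_columns: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.beta.index].to_numpy() @ self.beta.to_numpy()


def count_cpg(sequence: str) -> int:
    return sequence.upper().count("CG")


def build_design(peaks: pd.DataFrame, genome: dict[str, str],
                 pwms: list[PWMModel], response: np.ndarray,
                 cutoff: float = DEFAULT_CUTOFF,
                 max_n_fraction: float = 0.5) -> DesignMatrix:
    """Assemble the motif design matrix for a set of peaks.

    Motif columns are both-strand hit counts per PWM; covariates are
    peak width, G+C base count and CpG dinucleotide count.  Peaks whose
    sequence is more than ``max_n_fraction`` ambiguous bases are
    excluded (counted in ``n_excluded``).
    """
    if not pwms:
        raise ValueError("empty PWM list")
    from .atac import extract_peak_sequences
    seqs = extract_peak_sequences(peaks, genome)
    n_frac = np.array([
        (sum(1 for c in s.upper() if c not in "ACGT") / len(s)) if s else 1.0
        for s in seqs])
    keep = n_frac <= max_n_fraction
    seqs_kept = [s for s, k in zip(seqs, keep) if k]

    cols: dict[str, np.ndarray] = {}
    for pwm in pwms:
        cols[pwm.motif_id] = np.array(
            [count_hits(s, pwm, cutoff) for s in seqs_kept], dtype=float)
    cols["width_bp"] = peaks.loc[keep, "width_bp"].to_numpy(dtype=float)
    cols["gc_count"] = np.array(
        [s.upper().count("G") + s.upper().count("C") for s in seqs_kept],
        dtype=float)
    cols["cpg_count"] = np.array([count_cpg(s) for s in seqs_kept],
                                 dtype=float)
    X = pd.DataFrame(cols, index=peaks.index[keep])
    return DesignMatrix(X, np.asarray(response, dtype=float)[keep],
                        [p.motif_id for p in pwms],
                        n_excluded=int((~keep).sum()))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                         np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = (X[:, ok] - mean[ok]) / sd[ok]
    return Z, mean, sd, ok


def elastic_net_fit(design: DesignMatrix, alpha: float, lam: float,
                    tol: float = 1e-10, max_iter: int = 100_000,
                    ) -> ElasticNetFit:
    """Fit at fixed (alpha, lambda); deterministic given inputs.

    Zero-variance columns are dropped with a warning and reported in
    ``dropped_columns``; coefficients come back on the original scale.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 rows")
    Z, mean, sd, ok = _standardize(X)
    dropped = list(design.X.columns[~ok])
    if dropped:
        import warnings
        warnings.warn(f"zero-variance columns dropped: {dropped}",
                      stacklevel=2)
    yc = y - y.mean()

    if lam == 0.0:
        beta_std, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    elif alpha == 0.0:
        # ridge closed form on the standardized problem
        p = Z.shape[1]
        A = Z.T @ Z / n + lam * np.eye(p)
        beta_std = np.linalg.solve(A, Z.T @ yc / n)
    else:
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                           tol=tol, max_iter=max_iter)
        model.fit(Z, yc)
        beta_std = model.coef_
    beta = np.zeros(X.shape[1])
    beta[ok] = beta_std / sd[ok]
    intercept = float(y.mean() - mean @ beta)
    return ElasticNetFit(pd.Series(beta, index=design.X.columns),
                         intercept, alpha, lam, dropped_columns=dropped)


def _lambda_path(Z: np.ndarray, yc: np.ndarray, alpha: float,
                 n_points: int, decades: float) -> np.ndarray:
    n = len(yc)
    denom = max(alpha, _RIDGE_ALPHA_FLOOR)
    lam_max = np.max(np.abs(Z.T @ yc)) / (n * denom)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades,
                       n_points)


def grid_search(design: DesignMatrix, alphas=ALPHA_GRID, n_folds: int = 5,
                lambda_path_length: int = LAMBDA_PATH_LENGTH,
                seed: int = 0) -> ElasticNetFit:
    """CV grid search over (alpha, lambda); refits the winner on all data.

    Folds come from one seeded shuffle and are identical across every
    grid point.  Ties in CV MSE go to the larger lambda at the same
    alpha (the sparser model).
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    n = len(y)
    if n < n_folds:
        raise ValueError("fewer rows than folds")
    Z, mean, sd, ok = _standardize(X)
    yc = y - y.mean()

    rng = np.random.default_rng(seed)
    fold_of = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(fold_of)

    records = []
    for alpha in alphas:
        lams = _lambda_path(Z, yc, alpha, lambda_path_length, LAMBDA_DECADES)
        sq_err = np.zeros(len(lams))
        for f in range(n_folds):
            tr = fold_of != f
            te = ~tr
            if alpha == 0.0:
                p = Z.shape[1]
                G = Z[tr].T @ Z[tr] / tr.sum()
                b = Z[tr].T @ yc[tr] / tr.sum()
                coefs = np.stack([
                    np.linalg.solve(G + lam * np.eye(p), b) for lam in lams],
                    axis=1)
            else:
                # enet_path expects decreasing alphas (lambdas)
                _, coefs, _ = enet_path(Z[tr], yc[tr], l1_ratio=alpha,
                                        alphas=lams)
            pred = Z[te] @ coefs  # (n_te, n_lams)
            sq_err += ((yc[te][:, None] - pred) ** 2).sum(axis=0)
        mse = sq_err / n
        for lam, m in zip(lams, mse):
            records.append({"alpha": alpha, "lambda": lam, "cv_mse": m})
    cv = pd.DataFrame(records)
    # global minimum; ties -> larger lambda
    best = cv.sort_values(["cv_mse", "lambda"],
                          ascending=[True, False]).iloc[0]
    fit = elastic_net_fit(design, float(best["alpha"]), float(best["lambda"]))
    fit.cv_mse = cv
    return fit


def rank_contributions(fit: ElasticNetFit) -> pd.DataFrame:
    """Predictors ordered by |beta| descending; zero-beta predictors
    omitted; covariates flagged apart from motifs."""
    nonzero = fit.beta[fit.beta != 0.0]
    order = nonzero.abs().sort_values(ascending=False).index
    return pd.DataFrame({
        "predictor": order,
        "beta": nonzero.loc[order].to_numpy(),
        "is_covariate": [p in COVARIATES for p in order],
    }).reset_index(drop=True)
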