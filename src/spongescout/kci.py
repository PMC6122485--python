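"""Kernel (conditional) independence tests with simulated empirical nulls.

The unconditional statistic is T_UI = (1/n) Tr(Kx~ Ky~) for double-centered
Gaussian kernel matrices; its null is approximated by the weighted
chi-squared form (1/n^2) sum_ij lam_x,i lam_y,j z_ij^2 using the truncated
eigenvalues of the centered kernels.

The conditional statistic residualizes the kernels of (X,Z) and Y against Z
with a kernel-ridge residual operator R_Z = eps (Kz~ + eps I)^-1 and uses
T_CI = (1/n) Tr(R Kxz~ R . R Ky~ R); the null weights are eigenvalues of the
Gram matrix of elementwise products of the scaled eigenvectors of the two
residualized kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy import stats

DEFAULT_ALPHA = 0.01


@dataclass
class KernelConfig:
    """Settings for the kernel independence tests."""

    sigma_rule: str = "median"          # kernel-width heuristic
    n_null_draws: int = 1000            # Monte-Carlo null samples
    eig_threshold: float = 1e-5         # relative eigenvalue truncation
    ridge_epsilon: float = 1e-3         # ridge for the conditioning operator
    alpha: float = DEFAULT_ALPHA
    null_mode: str = "montecarlo"       # "montecarlo" (reference) or "gamma"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_null_draws < 100:
            raise ValueError("n_null_draws must be >= 100")
        if not 0.0 < self.eig_threshold < 1.0:
            raise ValueError("eig_threshold must be in (0, 1)")
        if self.ridge_epsilon <= 0:
            raise ValueError("ridge_epsilon must be > 0")
        if self.null_mode not in ("montecarlo", "gamma"):
            raise ValueError("null_mode must be 'montecarlo' or 'gamma'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class KciResult:
    statistic: float
    p_value: float
    n_eigs_used: int
    null_draws_used: int
    degenerate: bool = field(default=False)

    def reject_at(self, alpha: float) -> bool:
        return self.p_value < alpha


def gaussian_kernel(x: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix K[i,j] = exp(-||x_i - x_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    sq = squareform(pdist(x, "sqeuclidean"))
    return np.exp(-sq / (2.0 * sigma**2))


def median_sigma(x: np.ndarray) -> float:
    """Median pairwise Euclidean distance (zero distances excluded)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d = pdist(x, "euclidean")
    d = d[d > 0]
    if d.size == 0:
        return 1.0   # constant input; kernel degenerates to all-ones anyway
    return float(np.median(d))


def centralize(k: np.ndarray) -> np.ndarray:
    """Double-center: H K H with H = I - (1/n) 11^T."""
    k = np.asarray(k, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("kernel matrix must be square")
    row = k.mean(axis=0, keepdims=True)
    col = k.mean(axis=1, keepdims=True)
    return k - row - col + k.mean()


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def _centered_kernel(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Standardized input -> centered Gaussian kernel; flags degeneracy."""
    v = np.asarray(v, dtype=float)
    flat = v if v.ndim > 1 else v[:, None]
    degenerate = bool(np.all(np.ptp(flat, axis=0) == 0))
    z = np.column_stack([_standardize(c) for c in flat.T])
    k = gaussian_kernel(z, median_sigma(z))
    return centralize(k), degenerate

def _trunc_eigs(k: np.ndarray, rel_threshold: float) -> np.ndarray:
    """Non-negative eigenvalues above rel_threshold * max, descending."""
    w = np.linalg.eigvalsh(k)[::-1]
    w = w[w > 0]
    if w.size == 0:
        return w
    return w[w > rel_threshold * w[0]]


def _empirical_p(stat: float, null: np.ndarray) -> float:
    return float((1 + np.sum(null >= stat)) / (1 + null.size))


def _gamma_p(stat: float, mean: float, var: float) -> float:
    if mean <= 0 or var <= 0:
        return 1.0
    shape = mean**2 / var
    scale = var / mean
    return float(stats.gamma.sf(stat, a=shape, scale=scale))


def kci_u(x, y, cfg: KernelConfig | None = None,
          rng: np.random.Generator | None = None) -> KciResult:
    """Unconditional kernel independence test of X vs Y."""
    cfg = cfg or KernelConfig()
    rng = rng if rng is not None else cfg.rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    n = x.shape[0]
    if n < 20:
        raise ValueError("need n >= 20 samples")

    kx, deg_x = _centered_kernel(x)
    ky, deg_y = _centered_kernel(y)
    if deg_x or deg_y:
        return KciResult(0.0, 1.0, 0, 0, degenerate=True)

    stat = float(np.sum(kx * ky) / n)
    lx = _trunc_eigs(kx, cfg.eig_threshold)
    ly = _trunc_eigs(ky, cfg.eig_threshold)
    w = np.outer(lx, ly).ravel() / n**2
    if cfg.null_mode == "gamma":
        mean, var = w.sum(), 2.0 * np.sum(w**2)
        return KciResult(stat, _gamma_p(stat, mean, var),
                         lx.size * ly.size, 0)
    null = w @ rng.chisquare(1.0, size=(w.size, cfg.n_null_draws))
    return KciResult(stat, _empirical_p(stat, null),
                     lx.size * ly.size, cfg.n_null_draws)


def kci_c(x, y, z, cfg: KernelConfig | None = None,
          rng: np.random.Generator | None = None) -> KciResult:
    """Conditional independence test of X vs Y given Z."""
    cfg = cfg or KernelConfig()
    rng = rng if rng is not None else cfg.rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape[0] == y.shape[0] == z.shape[0]):
        raise ValueError("x, y, z must have equal length")
    n = x.shape[0]
    if n < 20:
        raise ValueError("need n >= 20 samples")

    # augmented X: conditioning set appended so residualization cannot
    # remove a genuine X effect spuriously
    xz = np.column_stack([_standardize(x), _standardize(z)])
    kxz, deg_x = _centered_kernel(xz)
    ky, deg_y = _centered_kernel(y)
    kz, _ = _centered_kernel(z)
    if deg_x or deg_y:
        return KciResult(0.0, 1.0, 0, 0, degenerate=True)

    eps = cfg.ridge_epsilon
    rz = eps * np.linalg.inv(kz + eps * np.eye(n))
    kx_res = rz @ kxz @ rz.T
    ky_res = rz @ ky @ rz.T
    stat = float(np.sum(kx_res * ky_res) / n)

    wx, vx = np.linalg.eigh(kx_res)
    wy, vy = np.linalg.eigh(ky_res)
    ix = wx > cfg.eig_threshold * max(wx.max(), 0) if wx.max() > 0 else wx > 0
    iy = wy > cfg.eig_threshold * max(wy.max(), 0) if wy.max() > 0 else wy > 0
    phix = vx[:, ix] * np.sqrt(wx[ix])          # n x kx
    phiy = vy[:, iy] * np.sqrt(wy[iy])          # n x ky
    kx_n, ky_n = phix.shape[1], phiy.shape[1]
    if kx_n == 0 or ky_n == 0:
        return KciResult(stat, 1.0, 0, 0, degenerate=True)

    # feature matrix of elementwise eigenvector products; null weights are
    # eigenvalues of its (smaller-side) Gram matrix
    w_feat = (phix[:, :, None] * phiy[:, None, :]).reshape(n, kx_n * ky_n)
    if w_feat.shape[1] > n:
        gram = w_feat @ w_feat.T
    else:
        gram = w_feat.T @ w_feat
    lam = _trunc_eigs(gram, cfg.eig_threshold) / n
    if lam.size == 0:
        return KciResult(stat, 1.0, 0, 0, degenerate=True)
    if cfg.null_mode == "gamma":
        mean, var = lam.sum(), 2.0 * np.sum(lam**2)
        return KciResult(stat, _gamma_p(stat, mean, var), lam.size, 0)
    null = lam @ rng.chisquare(1.0, size=(lam.size, cfg.n_null_draws))
    return KciResult(stat, _empirical_p(stat, null), lam.size,
                     cfg.n_null_draws)


def confirm_triplets(candidates, m, cfg: KernelConfig | None = None):
    """KCI confirmation stage of the screen output.

    For each distinct lncRNA:mRNA pair among threshold-passing candidates,
    runs the unconditional test and keeps dependent pairs (p < alpha); for
    the surviving triplets runs the conditional test and keeps those NOT
    rejected (conditional independence plausible).  Returns the retained
    candidates with KCI fields attached (as dicts).
    """
    cfg = cfg or KernelConfig()
    rng = cfg.rng()
    vals = m.values

    passing = [c for c in candidates if c.passes_threshold]
    pair_results: dict[tuple[str, str], KciResult] = {}
    for c in passing:
        key = (c.lncrna, c.mrna)
        if key not in pair_results:
            pair_results[key] = kci_u(
                vals.loc[c.lncrna].to_numpy(),
                vals.loc[c.mrna].to_numpy(),
                cfg, rng,
            )

    confirmed = []
    for c in passing:
        u_res = pair_results[(c.lncrna, c.mrna)]
        if not u_res.reject_at(cfg.alpha):
            continue   # pair not demonstrably dependent
        c_res = kci_c(
            vals.loc[c.lncrna].to_numpy(),
            vals.loc[c.mrna].to_numpy(),
            vals.loc[c.mirna].to_numpy(),
            cfg, rng,
        )
        if c_res.reject_at(cfg.alpha):
            continue   # conditional independence rejected -> not a sponge
        rec = c.to_dict()
        rec.update(
            kci_u_stat=u_res.statistic, kci_u_p=u_res.p_value,
            kci_c_stat=c_res.statistic, kci_c_p=c_res.p_value,
            decision="retained",
        )
        confirmed.append(rec)
    return confirmed
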